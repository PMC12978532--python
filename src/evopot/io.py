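"""Genotype containers, VCF reading/writing, and hard site filters.

The analysis substrate is a :class:`GenotypeTable`: a sites x samples matrix
of diploid genotypes encoded as alternate-allele dosage (0, 1, 2; -1 for
missing), with per-site metadata and optional per-call read depth.  Filters
follow the conventional resequencing recipe for a multi-sample SNP panel:
depth-mask low-confidence calls, then drop sites with excess missingness,
rare minor alleles, or non-biallelic alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("evopot")

MISSING = -1

_SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed into a biallelic SNP table."""


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNV: 1-based position, single-nucleotide alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )


@dataclass
class FilterConfig:
    """Hard site filters: missingness, minor-allele frequency, depth.

    A genotype whose depth is below ``min_depth`` is set to missing before
    the missingness test; sites are never dropped on depth directly.  The
    MAF rule is strict ("below"), so a site at exactly ``min_maf`` is kept.
    """

    max_missing_fraction: float = 0.25
    min_maf: float = 0.05
    min_depth: int = 3
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class GenotypeTable:
    """Diploid genotype matrix with per-site metadata.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions,
        strictly increasing within a chromosome).
    samples
        Ordered sample identifiers (columns of the matrix).
    genotypes
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages; ``-1``
        encodes a missing call.
    depth
        Optional ``(n_sites, n_samples)`` integer read-depth array.
    """

    sites: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if list(self.sites.columns[:4]) != _SITE_COLUMNS:
            missing = set(_SITE_COLUMNS) - set(self.sites.columns)
            if missing:
                raise ValueError(f"sites frame lacks columns {sorted(missing)}")
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth matrix shape mismatch")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def sample_genotypes(self, sample: str) -> np.ndarray:
        return self.genotypes[:, self.sample_index(sample)]

    def take_sites(self, mask_or_index) -> "GenotypeTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            sites=self.sites.iloc[idx],
            samples=list(self.samples),
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def take_samples(self, samples: Sequence[str]) -> "GenotypeTable":
        cols = [self.sample_index(s) for s in samples]
        return GenotypeTable(
            sites=self.sites,
            samples=list(samples),
            genotypes=self.genotypes[:, cols],
            depth=None if self.depth is None else self.depth[:, cols],
        )

    # -- per-site summaries ------------------------------------------------
    def alt_frequency(self) -> np.ndarray:
        """Alt-allele frequency per site over non-missing calls (NaN if none)."""
        gt = self.genotypes
        called = gt != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)


@dataclass
class LineageMap:
    """Sample -> lineage labels, with an optional outgroup flag per sample."""

    lineage_of: dict[str, str]
    outgroup: set[str] = field(default_factory=set)

    def samples_of(self, lineage: str) -> list[str]:
        return [s for s, l in self.lineage_of.items() if l == lineage]

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.lineage_of.values():
            seen.setdefault(l, None)
        return list(seen)

    def validate_against(self, table: GenotypeTable) -> None:
        unlabeled = [s for s in table.samples if s not in self.lineage_of]
        if unlabeled:
            raise ValueError(f"samples without lineage label: {unlabeled}")


def read_lineage_map(path: str | Path) -> LineageMap:
    """Read a tab-separated ``sample<TAB>lineage[<TAB>is_outgroup]`` table."""
    lineage_of: dict[str, str] = {}
    outgroup: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed lineage-map line: {line!r}")
        lineage_of[parts[0]] = parts[1]
        if len(parts) > 2 and parts[2].strip().lower() in {"1", "true", "yes"}:
            outgroup.add(parts[0])
    return LineageMap(lineage_of, outgroup)


def write_lineage_map(lmap: LineageMap, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{s}\t{l}\t{1 if s in lmap.outgroup else 0}"
        for s, l in lmap.lineage_of.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region: tuple[str, int, int] | str | None = None,
    multiallelic: str = "skip",
) -> GenotypeTable:
    """Read a VCF 4.x into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    region
        Either a chromosome name or ``(chrom, start, end)`` with a 1-based
        inclusive interval; only overlapping records are kept.
    multiallelic
        ``"skip"`` drops multi-allelic records (the default, matching a
        biallelic-only panel); ``"error"`` raises.

    Missing calls are preserved as missing.  Indels and records without a
    GT field raise :class:`VcfFormatError`.
    """
    from cyvcf2 import VCF

    if multiallelic not in {"skip", "error"}:
        raise ValueError("multiallelic must be 'skip' or 'error'")
    chrom_sel = start = end = None
    if isinstance(region, str):
        chrom_sel = region
    elif region is not None:
        chrom_sel, start, end = region

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[tuple[str, int, str, str]] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    has_dp = "DP" in {f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"}
    for v in vcf:
        if chrom_sel is not None and v.CHROM != chrom_sel:
            continue
        if start is not None and not (start <= v.POS <= end):
            continue
        if len(v.ALT) != 1:
            if multiallelic == "error":
                raise VcfFormatError(
                    f"multi-allelic record at {v.CHROM}:{v.POS}"
                )
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # indels are out of scope
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = v.genotype.array()[:, :2]
        if g.shape[1] < 2:
            raise VcfFormatError(f"no diploid GT at {v.CHROM}:{v.POS}")
        dosage = np.where((g < 0).any(axis=1), MISSING, (g > 0).sum(axis=1))
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gts.append(dosage.astype(np.int8))
        if has_dp:
            d = v.format("DP")
            if d is None:
                d = np.zeros(len(samples), dtype=np.int32)
            dps.append(np.maximum(np.asarray(d).reshape(-1), 0))
    sites = pd.DataFrame(rows, columns=_SITE_COLUMNS)
    genotypes = (
        np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    )
    depth = np.vstack(dps) if (has_dp and dps) else None
    logger.info("read %d sites x %d samples from %s", len(sites), len(samples), path)
    return GenotypeTable(sites, samples, genotypes, depth)


def write_vcf(table: GenotypeTable, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 (GT, and DP when the table carries depth)."""
    path = Path(path)
    has_dp = table.depth is not None
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_dp:
        header.append(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
    for chrom in table.sites["chrom"].unique():
        length = int(table.sites.loc[table.sites["chrom"] == chrom, "pos"].max()) + 1000
        header.append(f"##contig=<ID={chrom},length={length}>")
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = header
    fmt = "GT:DP" if has_dp else "GT"
    for i, row in enumerate(table.sites.itertuples(index=False)):
        calls = []
        for j in range(table.n_samples):
            s = gt_str[int(table.genotypes[i, j])]
            if has_dp:
                s += f":{int(table.depth[i, j])}"
            calls.append(s)
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def filter_sites(table: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    """Apply hard site filters, preserving site order.

    Order of operations: (1) genotypes with depth below ``min_depth`` become
    missing; (2) sites with missing fraction above ``max_missing_fraction``
    are dropped; (3) sites with minor-allele frequency strictly below
    ``min_maf`` (computed over non-missing calls) are dropped; (4) with
    ``biallelic_only``, monomorphic and non-SNV sites are dropped.
    Idempotent: a second application is the identity.
    """
    if cfg is None:
        cfg = FilterConfig()
    gt = table.genotypes.copy()
    depth = table.depth
    if depth is not None and cfg.min_depth > 0:
        gt[depth < cfg.min_depth] = MISSING

    masked = GenotypeTable(table.sites, table.samples, gt, depth)
    keep = masked.missing_fraction() <= cfg.max_missing_fraction

    p = masked.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    keep &= ~np.isnan(p)
    # strict "below": a site at exactly min_maf passes
    keep &= ~(maf < cfg.min_maf)

    if cfg.biallelic_only:
        snv = np.array(
            [len(r) == 1 and len(a) == 1 and r != a
             for r, a in zip(table.sites["ref"], table.sites["alt"])]
        )
        keep &= snv
    out = masked.take_sites(keep)
    logger.info("filter_sites: %d -> %d sites", table.n_sites, out.n_sites)
    return out
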