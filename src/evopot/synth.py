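"""Synthetic data with known truth: structured genotype panels, planted
runs of homozygosity, coding variants of prescribed effect class, and
piecewise demographic trajectories.

The genotype generator draws lineage allele frequencies under the
Balding–Nichols model — Beta-distributed around an ancestral frequency p
with variance F p(1-p) — which makes the target differentiation parameter F
equal the expected Weir–Cockerham Fst, so downstream estimators can be
tested against an analytic truth rather than another implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import DemographicTrajectory
from .genes import Gene, GeneSet, revcomp, translate
from .io import MISSING, GenotypeTable, LineageMap
from .load import AMINO_ACIDS

BASES = "ACGT"


@dataclass
class SynthSpec:
    """Parameters of a structured multi-lineage genotype panel.

    ``target_fst`` may be a single value shared by all lineages or one
    value per lineage; ``freq_dist`` selects the ancestral allele-frequency
    law, ``"uniform"`` on [0.05, 0.95] or ``"beta"`` (Beta(0.8, 0.8)
    clipped away from fixation).
    """

    n_lineages: int = 2
    samples_per_lineage: Sequence[int] = (25, 25)
    target_fst: float | Sequence[float] = 0.2
    n_sites: int = 20_000
    freq_dist: str = "uniform"
    seed: int = 0
    outgroup: bool = True
    snp_spacing_bp: int = 2_000
    lineage_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.samples_per_lineage) != self.n_lineages:
            raise ValueError("need one sample size per lineage")
        if any(n < 1 for n in self.samples_per_lineage):
            raise ValueError("sample sizes must be >= 1")
        fsts = self.fst_per_lineage()
        if any(not 0 <= f < 1 for f in fsts):
            raise ValueError("target_fst must lie in [0, 1)")

    def fst_per_lineage(self) -> list[float]:
        if np.isscalar(self.target_fst):
            return [float(self.target_fst)] * self.n_lineages
        if len(self.target_fst) != self.n_lineages:
            raise ValueError("need one target_fst per lineage")
        return [float(f) for f in self.target_fst]

    def names(self) -> list[str]:
        if self.lineage_names is not None:
            return list(self.lineage_names)
        return [f"L{i}" for i in range(self.n_lineages)]


@dataclass
class TruthTable:
    """What the generator planted, for use as a test oracle."""

    ancestral_freq: np.ndarray | None = None          # per-site ancestral p
    lineage_freqs: pd.DataFrame | None = None         # site x lineage drawn freqs
    expected_fst: dict[tuple[str, str], float] = field(default_factory=dict)
    roh_intervals: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (sample, chrom, start, end) 1-based inclusive
    effect_classes: pd.DataFrame | None = None        # site pos -> planted class


def _ancestral_freqs(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.freq_dist == "uniform":
        return rng.uniform(0.05, 0.95, spec.n_sites)
    if spec.freq_dist == "beta":
        return np.clip(rng.beta(0.8, 0.8, spec.n_sites), 0.02, 0.98)
    raise ValueError(f"unknown freq_dist {spec.freq_dist!r}")


def _site_frame(n_sites: int, rng: np.random.Generator,
                spacing: int, chrom: str = "1") -> pd.DataFrame:
    gaps = rng.integers(1, 2 * spacing, n_sites)
    pos = np.cumsum(gaps)
    ref_idx = rng.integers(0, 4, n_sites)
    alt_shift = rng.integers(1, 4, n_sites)
    ref = np.array(list(BASES))[ref_idx]
    alt = np.array(list(BASES))[(ref_idx + alt_shift) % 4]
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})


def simulate_structured_genotypes(
    spec: SynthSpec,
) -> tuple[GenotypeTable, LineageMap, TruthTable]:
    """Draw a multi-lineage diploid panel under the Balding–Nichols model.

    Per site and lineage, the allele frequency is Beta with mean equal to
    the ancestral frequency p and variance F p(1-p); diploid genotypes are
    Binomial(2, p_lineage).  With ``outgroup=True`` an extra sample fixed
    homozygous for the ancestral allele (encoded as REF) is appended for
    polarization.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p_anc = _ancestral_freqs(spec, rng)
    sites = _site_frame(spec.n_sites, rng, spec.snp_spacing_bp)

    names = spec.names()
    fsts = spec.fst_per_lineage()
    samples: list[str] = []
    lineage_of: dict[str, str] = {}
    cols: list[np.ndarray] = []
    lineage_freqs = {}
    for name, F, n in zip(names, fsts, spec.samples_per_lineage):
        if F == 0:
            p_l = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_l = rng.beta(a, b)
        lineage_freqs[name] = p_l
        g = rng.binomial(2, p_l[:, None], size=(spec.n_sites, n)).astype(np.int8)
        cols.append(g)
        for k in range(n):
            sid = f"{name}_{k}"
            samples.append(sid)
            lineage_of[sid] = name
    genotypes = np.hstack(cols)
    outgroup: set[str] = set()
    if spec.outgroup:
        og = np.zeros((spec.n_sites, 1), dtype=np.int8)  # hom ancestral = REF
        genotypes = np.hstack([genotypes, og])
        samples.append("outgroup")
        lineage_of["outgroup"] = "outgroup"
        outgroup.add("outgroup")

    table = GenotypeTable(sites, samples, genotypes)
    lmap = LineageMap(lineage_of, outgroup)
    truth = TruthTable(
        ancestral_freq=p_anc,
        lineage_freqs=pd.DataFrame(lineage_freqs),
        expected_fst={
            (a, b): (fa + fb) / 2
            for i, (a, fa) in enumerate(zip(names, fsts))
            for b, fb in list(zip(names, fsts))[i + 1:]
        },
    )
    return table, lmap, truth


def inject_roh(
    table: GenotypeTable,
    sample: str,
    region: tuple[str, int, int],
    seed: int = 0,
    truth: TruthTable | None = None,
) -> tuple[GenotypeTable, TruthTable]:
    """Force one sample homozygous across a region (an identity-by-descent
    tract), preserving missing calls; the planted interval is recorded in
    the truth table.
    """
    chrom, start, end = region
    rng = np.random.default_rng(seed)
    j = table.sample_index(sample)
    mask = (
        (table.sites["chrom"] == chrom)
        & (table.sites["pos"] >= start)
        & (table.sites["pos"] <= end)
    ).to_numpy()
    if not mask.any():
        import warnings

        warnings.warn(f"inject_roh: no sites in {chrom}:{start}-{end}; no-op")
        return table, truth or TruthTable()
    gt = table.genotypes.copy()
    col = gt[mask, j]
    # draw one haplotype per site: hets collapse to 0 or 2 at random
    draw = rng.integers(0, 2, mask.sum()) * 2
    new = np.where(col == 1, draw, col)
    new = np.where(col == MISSING, MISSING, new)
    gt[mask, j] = new.astype(np.int8)
    out = GenotypeTable(table.sites, list(table.samples), gt, table.depth)
    truth = truth or TruthTable()
    truth.roh_intervals.append((sample, chrom, int(start), int(end)))
    return out, truth


# ---------------------------------------------------------------------------
# Coding-variant fixtures
# ---------------------------------------------------------------------------


def make_gene_set(
    n_genes: int = 3,
    n_codons: int = 60,
    n_exons: int = 2,
    chrom: str = "1",
    seed: int = 0,
    intron_length: int = 500,
    start_pos: int = 1_000,
) -> GeneSet:
    """Random multi-exon gene models with internally consistent CDS.

    Generates open reading frames (ATG ... stop-free body ... stop) split
    into ``n_exons`` CDS intervals separated by introns; alternating genes
    are placed on the minus strand to exercise strand handling.
    """
    rng = np.random.default_rng(seed)
    genes = []
    cursor = start_pos
    body_aas = AMINO_ACIDS.replace("M", "").replace("W", "")
    codon_of = _codon_table_by_aa()
    for gi in range(n_genes):
        aas = ["M"] + [body_aas[i] for i in rng.integers(0, len(body_aas), n_codons - 2)]
        cds = "".join(codon_of[a][rng.integers(0, len(codon_of[a]))] for a in aas)
        cds += ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        strand = "+" if gi % 2 == 0 else "-"
        L = len(cds)
        cuts = sorted(rng.choice(np.arange(3, L - 3, 3), size=n_exons - 1, replace=False))
        pieces = np.diff([0, *cuts, L])
        exons = []
        pos = cursor
        for plen in pieces:
            exons.append((pos, pos + int(plen)))
            pos += int(plen) + intron_length
        cursor = pos + 2_000
        # genomic intervals run left->right; for minus-strand genes the CDS
        # maps to them reverse-complemented
        genes.append(Gene(f"gene{gi}", chrom, strand, exons, cds))
    return GeneSet(genes)


def _codon_table_by_aa() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                codon = b1 + b2 + b3
                aa = translate(codon)
                table.setdefault(aa, []).append(codon)
    return table


def _consequence(codon: str, within: int, new_base: str) -> str:
    new_codon = codon[:within] + new_base + codon[within + 1:]
    aa0, aa1 = translate(codon), translate(new_codon)
    if aa0 == aa1:
        return "synonymous"
    if aa1 == "*":
        return "LOF"
    if aa0 == "*":
        return "other"
    return "missense"


def generate_coding_variants(
    genes: GeneSet,
    class_counts: dict[str, int],
    seed: int = 0,
    n_ingroup: int = 10,
    max_tries: int = 10_000,
) -> tuple[GenotypeTable, TruthTable]:
    """Plant coding SNVs whose derived-allele consequence is exactly the
    requested class.

    The ancestral allele is the reference (CDS) base; the derived allele is
    chosen so that substituting it into the codon yields the requested
    consequence, verified by translation.  Ingroup genotypes are drawn with
    a hom-ancestral majority (so polarization resolves every site) and an
    outgroup sample carries the ancestral allele homozygous.
    """
    rng = np.random.default_rng(seed)
    wanted = []
    for cls, k in class_counts.items():
        if cls not in {"LOF", "missense", "synonymous"}:
            raise ValueError(f"unsupported class {cls!r}")
        wanted += [cls] * int(k)
    rng.shuffle(wanted)

    used_pos: set[tuple[str, int]] = set()
    rows = []  # chrom, pos, ref, alt, class, gene
    for cls in wanted:
        placed = False
        for _ in range(max_tries):
            gene = genes.genes[rng.integers(0, len(genes.genes))]
            off = int(rng.integers(0, len(gene.cds) - 3))  # keep stop codon intact
            codon, within = gene.codon_at(off)
            base = gene.cds[off]
            candidates = [b for b in BASES if b != base]
            rng.shuffle(candidates)
            alt_c = next(
                (b for b in candidates if _consequence(codon, within, b) == cls), None
            )
            if alt_c is None:
                continue
            pos1 = _genomic_position(gene, off)
            if (gene.chrom, pos1) in used_pos:
                continue
            used_pos.add((gene.chrom, pos1))
            if gene.strand == "+":
                ref_g, alt_g = base, alt_c
            else:
                ref_g, alt_g = revcomp(base), revcomp(alt_c)
            rows.append((gene.chrom, pos1, ref_g, alt_g, cls, gene.gene_id))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {cls} variant after {max_tries} tries"
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    sites = pd.DataFrame(
        [r[:4] for r in rows], columns=["chrom", "pos", "ref", "alt"]
    )
    n_sites = len(rows)
    # genotypes: hom-ancestral majority (> 50%), remainder het / hom-derived
    g = np.zeros((n_sites, n_ingroup), dtype=np.int8)
    for i in range(n_sites):
        n_hom_anc = int(rng.integers(n_ingroup // 2 + 1, n_ingroup + 1))
        rest = n_ingroup - n_hom_anc
        others = rng.choice([1, 2], size=rest)
        col = np.concatenate([np.zeros(n_hom_anc, dtype=int), others])
        rng.shuffle(col)
        g[i] = col
    og = np.zeros((n_sites, 1), dtype=np.int8)
    samples = [f"s{k}" for k in range(n_ingroup)] + ["outgroup"]
    table = GenotypeTable(sites, samples, np.hstack([g, og]))
    truth = TruthTable(
        effect_classes=pd.DataFrame(
            [(r[0], r[1], r[4], r[5]) for r in rows],
            columns=["chrom", "pos", "class", "gene"],
        )
    )
    return table, truth


def _genomic_position(gene: Gene, cds_offset: int) -> int:
    """Inverse of :meth:`Gene.cds_offset`: CDS offset -> 1-based position."""
    fwd = cds_offset if gene.strand == "+" else len(gene.cds) - 1 - cds_offset
    off = 0
    for a, b in gene.exons:
        if fwd < off + (b - a):
            return a + (fwd - off) + 1
        off += b - a
    raise IndexError("CDS offset outside gene")


# ---------------------------------------------------------------------------
# Demographic trajectory fixtures
# ---------------------------------------------------------------------------

#: printed endpoint pairs of the four pangolin lineages' recent-history
#: reconstructions: (Ne at decline onset, Ne at present, onset generation,
#: end generation); the span covered is the last 100 generations.
TRAJECTORY_ENDPOINTS: dict[str, tuple[float, float, int, int]] = {
    "CongoBasin": (160_753, 8_677, -73, 0),
    "CameroonGabon": (41_939, 5_069, -58, 0),
    "WestAfrica": (10_473, 923, -100, -14),
    "Nigeria": (6_420, 5_183, -100, 0),
}


def make_trajectory_fixture(lineage: str) -> DemographicTrajectory:
    """Piecewise-linear 101-point Ne trajectory for a named lineage.

    Built from the published endpoint pairs: Ne is constant at the
    pre-decline value before the decline onset, declines linearly on the
    natural scale to the endpoint, and is constant after the decline ends.
    """
    if lineage not in TRAJECTORY_ENDPOINTS:
        raise KeyError(
            f"unknown lineage {lineage!r}; expected one of "
            f"{sorted(TRAJECTORY_ENDPOINTS)}"
        )
    ne_start, ne_end, g_start, g_end = TRAJECTORY_ENDPOINTS[lineage]
    gens = np.arange(-100, 1)
    ne = np.empty_like(gens, dtype=float)
    for i, g in enumerate(gens):
        if g <= g_start:
            ne[i] = ne_start
        elif g >= g_end:
            ne[i] = ne_end
        else:
            frac = (g - g_start) / (g_end - g_start)
            ne[i] = ne_start + frac * (ne_end - ne_start)
    return DemographicTrajectory(gens, ne)
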