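"""Diversity, inbreeding, LD, differentiation and introgression statistics.

Implements the standard panel of conservation-genomic summaries on a
:class:`~evopot.io.GenotypeTable`:

* individual heterozygosity He = n_het / callable sites;
* a PLINK-style sliding-window run-of-homozygosity caller and the genomic
  inbreeding coefficient F_ROH = total ROH length / autosomal length;
* LD decay as binned mean r^2 of genotype-dosage correlation (composite LD,
  appropriate for unphased genotypes);
* windowed Weir–Cockerham Fst with the weighted "ratio of sums" estimator;
* the ABBA–BABA D statistic and the f4-ratio with block-jackknife errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeTable

# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


def individual_heterozygosity(
    table: GenotypeTable, sample: str, callable_sites: int
) -> float:
    """He for one individual: heterozygous sites over callable sites.

    ``callable_sites`` is the denominator of confidently genotyped sites
    (genome-wide callable positions, or the SNP-panel size — an explicit
    choice the caller makes).  Missing genotypes never count as heterozygous.
    """
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    n_het = int((table.sample_genotypes(sample) == 1).sum())
    if n_het > callable_sites:
        raise ValueError("callable_sites smaller than heterozygous count")
    return n_het / callable_sites


def lineage_mean_heterozygosity(values: Sequence[float]) -> float:
    """Arithmetic mean of per-individual He values within a lineage."""
    if len(values) == 0:
        raise ValueError("empty He list")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass
class ROHParams:
    """Sliding-window ROH caller settings (PLINK ``--homozyg`` dialect).

    The two explicitly set values are a 20-SNP scanning window and a 100-kb
    minimum segment length; the remaining knobs sit at the PLINK defaults
    (at most 1 heterozygote and 5 missing calls per window, segments split
    at inter-SNP gaps over 1 Mb, at least 20 SNPs per emitted segment).
    """

    window_snps: int = 20
    min_kb: float = 100.0
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps_per_segment: int = 20
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.min_kb <= 0:
            raise ValueError("min_kb must be positive")
        for name in ("window_snps", "max_het_per_window", "max_missing_per_window",
                     "min_snps_per_segment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class ROHSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_snps: int
    sample: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_roh(
    table: GenotypeTable, sample: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call runs of homozygosity for one sample.

    Windows of ``window_snps`` consecutive SNPs qualify when they contain at
    most ``max_het_per_window`` heterozygotes and ``max_missing_per_window``
    missing calls; a SNP covered by any qualifying window is in a run.
    Consecutive in-run SNPs are merged into segments, split where adjacent
    SNPs are more than ``max_gap_kb`` apart, and segments shorter than
    ``min_kb`` or with fewer than ``min_snps_per_segment`` SNPs are dropped.
    """
    if params is None:
        params = ROHParams()
    gt_all = table.sample_genotypes(sample)
    segments: list[ROHSegment] = []
    for chrom, sub in table.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        gt = gt_all[idx]
        n = len(pos)
        w = params.window_snps
        if n == 0:
            continue
        in_run = np.zeros(n, dtype=bool)
        if n >= w:
            het = (gt == 1).astype(int)
            mis = (gt == MISSING).astype(int)
            chet = np.concatenate([[0], np.cumsum(het)])
            cmis = np.concatenate([[0], np.cumsum(mis)])
            het_w = chet[w:] - chet[:-w]          # counts per window start
            mis_w = cmis[w:] - cmis[:-w]
            ok = (het_w <= params.max_het_per_window) & (
                mis_w <= params.max_missing_per_window
            )
            # mark all SNPs covered by a qualifying window
            delta = np.zeros(n + 1, dtype=int)
            starts = np.flatnonzero(ok)
            np.add.at(delta, starts, 1)
            np.add.at(delta, starts + w, -1)
            in_run = np.cumsum(delta[:-1]) > 0
        # split runs at large gaps and emit
        gap_bp = params.max_gap_kb * 1000.0
        i = 0
        while i < n:
            if not in_run[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and in_run[j + 1]
                and (pos[j + 1] - pos[j]) <= gap_bp
            ):
                j += 1
            length = pos[j] - pos[i] + 1
            n_snps = j - i + 1
            if length >= params.min_kb * 1000.0 and n_snps >= params.min_snps_per_segment:
                segments.append(
                    ROHSegment(str(chrom), int(pos[i]), int(pos[j]), n_snps, sample)
                )
            i = j + 1
    return segments


def froh(segments: Sequence[ROHSegment], l_auto: float) -> float:
    """Genomic inbreeding coefficient: total ROH length / autosomal length.

    ``l_auto`` is the total autosomal length covered by SNPs.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    return sum(s.length for s in segments) / l_auto


def roh_to_bed(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start - 1, s.end, s.sample, s.n_snps) for s in segments],
        columns=["chrom", "start", "end", "sample", "n_snps"],
    )


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDCurve:
    """Binned decay of mean r^2 with physical distance."""

    bin_edges: np.ndarray          # length n_bins + 1, bp
    mean_r2: np.ndarray            # length n_bins, NaN where empty
    n_pairs: np.ndarray            # length n_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs.astype(int),
            }
        )

    def half_decay_distance(self) -> float | None:
        """Distance at which mean r^2 first drops below half its initial value."""
        valid = ~np.isnan(self.mean_r2)
        if not valid.any():
            return None
        r0 = self.mean_r2[valid][0]
        for lo, r in zip(self.bin_edges[:-1][valid], self.mean_r2[valid]):
            if r <= r0 / 2:
                return float(lo)
        return None


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return np.nan  # monomorphic in the shared calls: skip
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return r * r


def ld_decay(
    table: GenotypeTable,
    samples: Sequence[str] | None = None,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
    maf_min: float = 0.05,
) -> LDCurve:
    """Pairwise dosage r^2 against physical distance, binned.

    Considers every intra-chromosome site pair within ``max_dist``; sites
    with minor-allele frequency below ``maf_min`` in the chosen sample set
    are excluded, and pairs monomorphic in their shared non-missing samples
    are skipped rather than propagated as NaN.
    """
    sub = table if samples is None else table.take_samples(list(samples))
    if sub.n_samples < 2:
        raise ValueError("LD decay needs at least two samples")
    p = sub.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1 - p)
    usable = ~np.isnan(p) & (maf >= maf_min)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom, sites in sub.sites.groupby("chrom", sort=False):
        idx = sites.index.to_numpy()
        idx = idx[usable[idx]]
        pos = sub.sites["pos"].to_numpy()[idx]
        G = sub.genotypes[idx]
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                d = pos[b] - pos[a]
                r2 = _pair_r2(G[a], G[b])
                if np.isnan(r2):
                    continue
                k = min(int(d // bin_width), n_bins - 1)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDCurve(edges, mean, counts)


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    windows: pd.DataFrame          # chrom, start, end, n_sites, fst
    global_fst: float


def _wc_components(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two populations.

    Returns (a, a+b+c) arrays; sites with fewer than two called samples in
    either population get zero weight.
    """
    r = 2.0
    na = (ga != MISSING).sum(axis=1).astype(float)
    nb = (gb != MISSING).sum(axis=1).astype(float)
    valid = (na >= 2) & (nb >= 2)
    na = np.maximum(na, 1)
    nb = np.maximum(nb, 1)
    pa = np.where(ga != MISSING, ga, 0).sum(axis=1) / (2 * na)
    pb = np.where(gb != MISSING, gb, 0).sum(axis=1) / (2 * nb)
    ha = (ga == 1).sum(axis=1) / na
    hb = (gb == 1).sum(axis=1) / nb

    nbar = (na + nb) / r
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (na * ha + nb * hb) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    total = np.where(valid, a + b + c, 0.0)
    # monomorphic overall sites contribute zero to both sums
    mono = (pbar <= 0) | (pbar >= 1)
    a = np.where(mono, 0.0, a)
    total = np.where(mono, 0.0, total)
    return a, total


def windowed_fst(
    table: GenotypeTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    window: int = 50_000,
) -> FstResult:
    """Weighted Weir–Cockerham Fst in fixed physical windows.

    Per window and genome-wide, the estimate is the "ratio of sums"
    sum(a) / sum(a+b+c) over per-site variance components — the weighted
    estimator reported by the standard VCF tooling.
    """
    if len(pop_a) == 0 or len(pop_b) == 0:
        raise ValueError("both populations must be nonempty")
    ga = table.take_samples(list(pop_a)).genotypes
    gb = table.take_samples(list(pop_b)).genotypes
    a, total = _wc_components(ga, gb)

    rows = []
    for chrom, sub in table.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        w_id = (pos - 1) // window
        for w in np.unique(w_id):
            m = idx[w_id == w]
            sa, st = a[m].sum(), total[m].sum()
            rows.append(
                (
                    str(chrom),
                    int(w * window + 1),
                    int((w + 1) * window),
                    len(m),
                    sa / st if st > 0 else np.nan,
                )
            )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])
    tot = total.sum()
    global_fst = float(a.sum() / tot) if tot > 0 else np.nan
    return FstResult(windows, global_fst)


# ---------------------------------------------------------------------------
# D statistic and f4-ratio
# ---------------------------------------------------------------------------


@dataclass
class DStatResult:
    d: float
    z: float
    n_blocks: int
    abba: float
    baba: float


def _pop_freqs(table: GenotypeTable, pops: Sequence[Sequence[str]]) -> list[np.ndarray]:
    return [table.take_samples(list(p)).alt_frequency() for p in pops]


def _jackknife_ratio(num: np.ndarray, den: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Delete-one-block jackknife for a ratio-of-sums statistic.

    Returns (estimate, standard error, number of blocks).
    """
    n = len(num)
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ZeroDivisionError("denominator sums to zero")
    est = total_num / total_den
    starts = np.arange(0, n, block_size)
    n_blocks = len(starts)
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    pseudo = np.empty(n_blocks)
    for i, s in enumerate(starts):
        e = min(s + block_size, n)
        dn = total_den - den[s:e].sum()
        pseudo[i] = (total_num - num[s:e].sum()) / dn if dn != 0 else est
    se = np.sqrt((n_blocks - 1) / n_blocks * ((pseudo - pseudo.mean()) ** 2).sum())
    return float(est), float(se), n_blocks


def _polarized_freqs(
    table: GenotypeTable, pops: Sequence[Sequence[str]], outgroup: Sequence[str]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Derived-allele frequencies oriented so the outgroup is ancestral.

    Sites where the outgroup is polymorphic or entirely missing are dropped.
    """
    freqs = _pop_freqs(table, pops)
    po = table.take_samples(list(outgroup)).alt_frequency()
    fixed = (po == 0) | (po == 1)
    keep = fixed & ~np.isnan(po)
    for f in freqs:
        keep &= ~np.isnan(f)
    flip = po == 1
    out = []
    for f in freqs:
        g = np.where(flip, 1 - f, f)
        out.append(g[keep])
    return out, keep


def d_statistic(
    table: GenotypeTable,
    p1: Sequence[str],
    p2: Sequence[str],
    p3: Sequence[str],
    outgroup: Sequence[str],
    block_size: int = 500,
) -> DStatResult:
    """Frequency-based ABBA–BABA D statistic with block-jackknife Z score.

    With derived-allele frequencies p1, p2, p3 (outgroup ancestral by
    construction), per-site ABBA = (1-p1) p2 p3 and BABA = p1 (1-p2) p3;
    D = sum(ABBA - BABA) / sum(ABBA + BABA).  Blocks are contiguous runs of
    ``block_size`` informative sites.
    """
    (f1, f2, f3), _ = _polarized_freqs(table, [p1, p2, p3], outgroup)
    abba = (1 - f1) * f2 * f3
    baba = f1 * (1 - f2) * f3
    num = abba - baba
    den = abba + baba
    d, se, n_blocks = _jackknife_ratio(num, den, block_size)
    z = d / se if se > 0 else np.inf if d != 0 else 0.0
    return DStatResult(d=d, z=float(z), n_blocks=n_blocks,
                       abba=float(abba.sum()), baba=float(baba.sum()))


@dataclass
class F4RatioResult:
    ratio: float
    se: float
    n_blocks: int


def f4_ratio(
    table: GenotypeTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    pop_x: Sequence[str],
    pop_c: Sequence[str],
    outgroup: Sequence[str],
    block_size: int = 500,
) -> F4RatioResult:
    """Admixture-fraction estimate f4(A,O; X,C) / f4(A,O; B,C).

    X is the putatively admixed population, B the surrogate for the donor
    (the unadmixed sister of the true donor), A a sister of B on the donor
    side, C the recipient-side reference, O the outgroup.  Under
    X = alpha B' + (1-alpha) C', the ratio estimates alpha.
    """
    (fa, fb, fx, fc), _ = _polarized_freqs(
        table, [pop_a, pop_b, pop_x, pop_c], outgroup
    )
    fo = np.zeros_like(fa)  # outgroup carries the ancestral allele
    num = (fa - fo) * (fx - fc)
    den = (fa - fo) * (fb - fc)
    ratio, se, n_blocks = _jackknife_ratio(num, den, block_size)
    if abs(den.sum()) < 1e-12:
        raise ZeroDivisionError("denominator f4 is numerically zero")
    return F4RatioResult(ratio=ratio, se=se, n_blocks=n_blocks)
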