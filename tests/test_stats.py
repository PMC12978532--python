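"""Heterozygosity, ROH/F_ROH, LD decay, Weir-Cockerham Fst, D and f4."""

import numpy as np
import pandas as pd
import pytest

from evopot import (
    GenotypeTable,
    ROHParams,
    call_roh,
    d_statistic,
    f4_ratio,
    froh,
    individual_heterozygosity,
    inject_roh,
    ld_decay,
    lineage_mean_heterozygosity,
    windowed_fst,
)
from evopot.io import MISSING
from evopot.stats import ROHSegment, _pair_r2

from .conftest import make_table

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------


def brute_he(gt_column, callable_sites):
    return sum(1 for g in gt_column if g == 1) / callable_sites


def brute_wc_fst(ga, gb):
    """Per-site Weir-Cockerham a/(a+b+c), ratio-of-sums, two populations,
    written scalar-by-scalar from the 1984 definitions."""
    num = den = 0.0
    for i in range(ga.shape[0]):
        xa = [g for g in ga[i] if g != MISSING]
        xb = [g for g in gb[i] if g != MISSING]
        na, nb = len(xa), len(xb)
        if na < 2 or nb < 2:
            continue
        pa = sum(xa) / (2 * na)
        pb = sum(xb) / (2 * nb)
        ha = sum(1 for g in xa if g == 1) / na
        hb = sum(1 for g in xb if g == 1) / nb
        r = 2
        nbar = (na + nb) / r
        nc = (r * nbar - (na * na + nb * nb) / (r * nbar)) / (r - 1)
        pbar = (na * pa + nb * pb) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def brute_d(table, p1, p2, p3, og):
    """Frequency D over polarized sites, one site at a time."""

    def freq(samples, i):
        calls = [table.genotypes[i, table.sample_index(s)] for s in samples]
        calls = [c for c in calls if c != MISSING]
        return sum(calls) / (2 * len(calls)) if calls else None

    num = den = 0.0
    for i in range(table.n_sites):
        fo = freq(og, i)
        if fo not in (0.0, 1.0):
            continue
        fs = [freq(p, i) for p in (p1, p2, p3)]
        if any(f is None for f in fs):
            continue
        f1, f2, f3 = fs
        if fo == 1.0:
            f1, f2, f3 = 1 - f1, 1 - f2, 1 - f3
        abba = (1 - f1) * f2 * f3
        baba = f1 * (1 - f2) * f3
        num += abba - baba
        den += abba + baba
    return num / den


# ---------------------------------------------------------------------------


class TestHeterozygosity:
    def test_formula(self):
        t = make_table([[1], [1], [1], [0], [2]])
        assert individual_heterozygosity(t, "s0", 1000) == pytest.approx(0.003)

    def test_all_homozygous_zero(self):
        t = make_table([[0], [2], [0]])
        assert individual_heterozygosity(t, "s0", 100) == 0

    def test_missing_not_counted(self):
        t = make_table([[MISSING], [1]])
        assert individual_heterozygosity(t, "s0", 10) == pytest.approx(0.1)

    def test_zero_denominator_rejected(self):
        t = make_table([[1]])
        with pytest.raises(ValueError):
            individual_heterozygosity(t, "s0", 0)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            g = rng.choice([-1, 0, 1, 2], size=(rng.integers(1, 50), 3))
            t = make_table(g)
            for s in t.samples:
                assert individual_heterozygosity(t, s, 500) == brute_he(
                    t.sample_genotypes(s), 500
                )

    def test_lineage_mean(self):
        vals = [0.0049, 0.0034, 0.0015, 0.0011]
        assert lineage_mean_heterozygosity(vals) == pytest.approx(0.0027, abs=5e-5)
        assert lineage_mean_heterozygosity([0.4]) == 0.4
        assert lineage_mean_heterozygosity(vals[::-1]) == lineage_mean_heterozygosity(vals)

    def test_balding_nichols_matches_generator_expectation(self, two_lineage_panel):
        table, lmap, truth = two_lineage_panel
        p = truth.lineage_freqs["L0"].to_numpy()
        expected = float(np.mean(2 * p * (1 - p)))
        hets = [
            individual_heterozygosity(table, s, table.n_sites)
            for s in lmap.samples_of("L0")
        ]
        assert np.mean(hets) == pytest.approx(expected, rel=0.02)


class TestROH:
    def test_injected_tract_recovered(self):
        rng = np.random.default_rng(0)
        # het-dense background: alternating hets
        g = rng.choice([0, 1, 2], size=(600, 1), p=[0.25, 0.5, 0.25])
        t = make_table(g, pos=np.arange(600) * 5000 + 1)
        start, end = t.sites["pos"][200], t.sites["pos"][200] + 150_000
        t2, truth = inject_roh(t, "s0", ("1", int(start), int(end)), seed=1)
        segs = call_roh(t2, "s0")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start <= start + 50_000 and seg.end >= end - 50_000
        assert seg.length >= 100_000 and seg.n_snps >= 20

    def test_fully_heterozygous_sample_empty(self):
        t = make_table(np.ones((100, 1)), pos=np.arange(100) * 3000 + 1)
        assert call_roh(t, "s0") == []

    def test_short_tract_rejected(self):
        # 50-kb homozygous tract in het background: below the 100-kb floor
        g = np.ones((300, 1), dtype=np.int8)
        pos = np.arange(300) * 2000 + 1
        g[100:126] = 0  # 26 snps spanning 50 kb
        t = make_table(g, pos=pos)
        assert call_roh(t, "s0") == []

    def test_missing_tolerance_per_window(self):
        g = np.zeros((120, 1), dtype=np.int8)
        pos = np.arange(120) * 2000 + 1
        g[10:30] = MISSING  # 20 consecutive missing: beyond the 5-missing cap
        t = make_table(g, pos=pos)
        segs = call_roh(t, "s0")
        # the run is still found but the heavily-missing stretch cannot be
        # covered by any qualifying window start inside it
        assert len(segs) >= 1

    def test_gap_splits_segments(self):
        g = np.zeros((80, 1), dtype=np.int8)
        pos = np.concatenate([np.arange(40) * 4000 + 1,
                              np.arange(40) * 4000 + 2_000_000])
        t = make_table(g, pos=pos)
        segs = call_roh(t, "s0", ROHParams(max_gap_kb=1000))
        assert len(segs) == 2

    def test_froh_formula(self):
        segs = [ROHSegment("1", 1, 1_000_000, 100, "s")]
        assert froh(segs, 1e9) == pytest.approx(0.001, rel=1e-3)
        assert froh([], 1e9) == 0.0
        two = [ROHSegment("1", 1, 200_000, 30, "s"),
               ROHSegment("2", 1, 300_000, 40, "s")]
        assert froh(two, 100e6) == pytest.approx(0.005, rel=1e-3)
        with pytest.raises(ValueError):
            froh(two, 0)


class TestLDDecay:
    def test_duplicated_column_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        g = np.vstack([col, col])  # two identical sites
        t = make_table(g, pos=[1000, 5000])
        curve = ld_decay(t, max_dist=10_000, bin_width=10_000, maf_min=0.0)
        assert curve.mean_r2[0] == pytest.approx(1.0)

    def test_pair_r2_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(1)
        x = rng.choice([0, 1, 2], 30)
        y = rng.choice([0, 1, 2], 30)
        expect = np.corrcoef(x, y)[0, 1] ** 2
        assert _pair_r2(x, y) == pytest.approx(expect)

    def test_monomorphic_pair_skipped(self):
        g = np.array([[1, 1, 1, 1], [0, 0, 0, 0]])
        t = make_table(g, pos=[100, 200])
        curve = ld_decay(t, max_dist=1000, bin_width=1000, maf_min=0.0)
        assert curve.n_pairs.sum() == 0

    def test_independent_sites_hit_sample_size_floor(self):
        """Unlinked Balding-Nichols sites: E[r2] ~ 1/n for n samples."""
        rng = np.random.default_rng(2)
        n = 20
        p = rng.uniform(0.2, 0.8, 400)
        g = rng.binomial(2, p[:, None], size=(400, n))
        t = make_table(g, pos=np.arange(400) * 100 + 1)
        curve = ld_decay(t, max_dist=50_000, bin_width=50_000, maf_min=0.05)
        total = np.nansum(curve.mean_r2 * curve.n_pairs) / curve.n_pairs.sum()
        assert total == pytest.approx(1 / n, rel=0.25)


class TestWindowedFst:
    def test_null_split_near_zero(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 2000)
        g = rng.binomial(2, p[:, None], size=(2000, 20)).astype(np.int8)
        t = make_table(g)
        res = windowed_fst(t, t.samples[:10], t.samples[10:])
        assert abs(res.global_fst) < 0.02

    def test_fixed_differences_give_one(self):
        g = np.hstack([np.zeros((50, 5)), np.full((50, 5), 2)]).astype(np.int8)
        t = make_table(g)
        res = windowed_fst(t, t.samples[:5], t.samples[5:])
        assert res.global_fst == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        g = rng.choice([-1, 0, 1, 2], size=(40, 12), p=[0.05, 0.45, 0.25, 0.25])
        t = make_table(g)
        a, b = t.samples[:6], t.samples[6:]
        res = windowed_fst(t, a, b)
        ga = t.genotypes[:, :6]
        gb = t.genotypes[:, 6:]
        assert res.global_fst == pytest.approx(brute_wc_fst(ga, gb), abs=1e-12)

    def test_balding_nichols_recovers_target(self, two_lineage_panel):
        table, lmap, truth = two_lineage_panel
        res = windowed_fst(table, lmap.samples_of("L0"), lmap.samples_of("L1"))
        assert res.global_fst == pytest.approx(0.4, abs=0.05)

    def test_window_bins_are_fixed_width(self, two_lineage_panel):
        table, lmap, _ = two_lineage_panel
        res = windowed_fst(table, lmap.samples_of("L0"), lmap.samples_of("L1"),
                           window=50_000)
        w = res.windows
        assert ((w["end"] - w["start"] + 1) == 50_000).all()


class TestDStatistic:
    def test_hand_built_abba3_baba1(self):
        g = np.array([
            [0, 2, 2, 0],
            [0, 2, 2, 0],
            [0, 2, 2, 0],
            [2, 0, 2, 0],
        ], dtype=np.int8)
        t = make_table(g, samples=["p1", "p2", "p3", "og"])
        res = d_statistic(t, ["p1"], ["p2"], ["p3"], ["og"], block_size=2)
        assert res.d == pytest.approx(0.5)
        assert res.abba == pytest.approx(3.0)
        assert res.baba == pytest.approx(1.0)

    def test_symmetric_null_small_z(self):
        rng = np.random.default_rng(6)
        p_anc = rng.uniform(0.1, 0.9, 5000)
        F = 0.2
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        f1 = rng.beta(a, b)
        f2 = rng.beta(a, b)
        f3 = rng.beta(a, b)
        g = np.hstack([
            rng.binomial(2, f1[:, None], (5000, 5)),
            rng.binomial(2, f2[:, None], (5000, 5)),
            rng.binomial(2, f3[:, None], (5000, 5)),
            np.zeros((5000, 1), dtype=int),
        ]).astype(np.int8)
        t = make_table(g, samples=[f"x{i}" for i in range(15)] + ["og"])
        res = d_statistic(t, [f"x{i}" for i in range(5)],
                          [f"x{i}" for i in range(5, 10)],
                          [f"x{i}" for i in range(10, 15)], ["og"])
        assert abs(res.d) < 0.05 and abs(res.z) < 3

    def test_directional_admixture_detected(self):
        rng = np.random.default_rng(7)
        n_sites = 4000
        p_anc = rng.uniform(0.1, 0.9, n_sites)
        F = 0.3
        a_, b_ = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        f1 = rng.beta(a_, b_)
        f2 = rng.beta(a_, b_)
        f3 = rng.beta(a_, b_)
        frac = 0.3
        f2_admixed = (1 - frac) * f2 + frac * f3
        g = np.hstack([
            rng.binomial(2, f1[:, None], (n_sites, 6)),
            rng.binomial(2, f2_admixed[:, None], (n_sites, 6)),
            rng.binomial(2, f3[:, None], (n_sites, 6)),
            np.zeros((n_sites, 1), dtype=int),
        ]).astype(np.int8)
        t = make_table(g, samples=[f"x{i}" for i in range(18)] + ["og"])
        res = d_statistic(t, [f"x{i}" for i in range(6)],
                          [f"x{i}" for i in range(6, 12)],
                          [f"x{i}" for i in range(12, 18)], ["og"])
        assert res.d > 0 and res.z > 3

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        g = rng.choice([0, 1, 2, -1], size=(50, 7), p=[0.4, 0.25, 0.25, 0.1])
        g[:, 6] = rng.choice([0, 2], size=50)  # homozygous outgroup
        t = make_table(g)
        d = d_statistic(t, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6"],
                        block_size=10).d
        expect = brute_d(t, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6"])
        assert d == pytest.approx(expect, abs=1e-12)

    def test_too_few_blocks_rejected(self):
        g = np.array([[0, 2, 2, 0]], dtype=np.int8)
        t = make_table(g, samples=["p1", "p2", "p3", "og"])
        with pytest.raises(ValueError):
            d_statistic(t, ["p1"], ["p2"], ["p3"], ["og"], block_size=10)


class TestF4Ratio:
    def _panel(self, frac, seed=10, n_sites=6000):
        """X = frac from B-side + (1-frac) from C-side."""
        rng = np.random.default_rng(seed)
        p_anc = rng.uniform(0.1, 0.9, n_sites)
        F = 0.3
        a_, b_ = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        fb_clade = rng.beta(a_, b_)
        fc_clade = rng.beta(a_, b_)
        Fs = 0.05
        def sub(f):
            return rng.beta(f * (1 - Fs) / Fs, (1 - f) * (1 - Fs) / Fs)
        fa, fb = sub(fb_clade), sub(fb_clade)
        fc = sub(fc_clade)
        fx = frac * sub(fb_clade) + (1 - frac) * sub(fc_clade)
        cols = []
        for f, n in ((fa, 6), (fb, 6), (fx, 6), (fc, 6)):
            cols.append(rng.binomial(2, f[:, None], (n_sites, n)))
        cols.append(np.zeros((n_sites, 1), dtype=int))
        g = np.hstack(cols).astype(np.int8)
        names = ([f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
                 + [f"x{i}" for i in range(6)] + [f"c{i}" for i in range(6)]
                 + ["og"])
        t = make_table(g, samples=names)
        pops = dict(
            pop_a=[f"a{i}" for i in range(6)],
            pop_b=[f"b{i}" for i in range(6)],
            pop_x=[f"x{i}" for i in range(6)],
            pop_c=[f"c{i}" for i in range(6)],
            outgroup=["og"],
        )
        return t, pops

    def test_no_admixture_near_zero(self):
        t, pops = self._panel(0.0)
        assert abs(f4_ratio(t, **pops).ratio) < 0.1

    def test_full_replacement_near_one(self):
        t, pops = self._panel(1.0)
        assert f4_ratio(t, **pops).ratio == pytest.approx(1.0, abs=0.1)

    def test_thirty_percent_recovered(self):
        t, pops = self._panel(0.3)
        assert f4_ratio(t, **pops).ratio == pytest.approx(0.3, abs=0.1)


class TestLineageRanking:
    """Drift-graded four-lineage panel: the most drifted lineage shows the
    lowest diversity and the highest genomic inbreeding — the qualitative
    conservation-priority ordering."""

    def test_he_and_froh_orderings(self, four_lineage_panel):
        table, lmap, _ = four_lineage_panel
        order = ["CongoBasin", "CameroonGabon", "WestAfrica", "Nigeria"]
        he = {}
        fr = {}
        span = float(table.sites["pos"].iloc[-1] - table.sites["pos"].iloc[0] + 1)
        for lin in order:
            samples = lmap.samples_of(lin)
            he[lin] = np.mean([
                individual_heterozygosity(table, s, table.n_sites)
                for s in samples
            ])
            fr[lin] = np.mean([
                froh(call_roh(table, s), span) for s in samples
            ])
        # diversity strictly decreasing with generator drift
        assert he["CongoBasin"] > he["CameroonGabon"] > he["WestAfrica"] > he["Nigeria"]
        # inbreeding highest in the most drifted lineage, lowest in the least
        assert fr["Nigeria"] >= fr["WestAfrica"] >= fr["CongoBasin"]
        assert fr["Nigeria"] > fr["CongoBasin"]


class TestLDOnSimulatedLinkage:
    """LD computed on forward-simulated genotypes with real recombination:
    r2 decays with physical distance."""

    def test_decay_curve_non_increasing(self):
        from evopot import CatastropheModel, DFEConfig, GenomeArchitecture, SimConfig
        from evopot.sim import init_population, run_generation, state_to_genotype_table

        arch = GenomeArchitecture(n_chromosomes=2, n_genes=100, gene_length=1500,
                                  intergene_recomb=2e-3)
        cfg = SimConfig(architecture=arch,
                        dfe=DFEConfig(neutral_only=True, mutation_rate=3e-6),
                        catastrophe=CatastropheModel(enabled=False))
        rng = np.random.default_rng(31)
        st = init_population(cfg, 60, rng)
        for _ in range(300):
            st = run_generation(st, cfg, 60)
        table = state_to_genotype_table(st)
        assert table.n_sites > 50
        curve = ld_decay(table, max_dist=75_000, bin_width=15_000, maf_min=0.1)
        valid = ~np.isnan(curve.mean_r2)
        r2 = curve.mean_r2[valid]
        assert len(r2) >= 3
        # close pairs in tighter LD than distant pairs
        assert r2[0] > r2[-1]
        # overall trend decreasing: no later bin exceeds the first
        assert (r2[1:] <= r2[0] + 0.05).all()
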