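"""Haplotype r², LD binning and Sved Ne estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_panel

from herdstat.ldne import (
    adjust_r2,
    ld_decay_table,
    ld_scan,
    ne_trajectory,
    pair_r2,
    sved_ne,
)
from herdstat.simdata import WFConfig, simulate_wright_fisher


def brute_force_r2(a, b):
    """Independent oracle: 2x2 haplotype contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    fAB = np.mean((a == 1) & (b == 1))
    fA, fB = a.mean(), b.mean()
    d = fAB - fA * fB
    return d * d / (fA * (1 - fA) * fB * (1 - fB))


class TestPairR2:
    def test_perfect_ld(self):
        a = np.array([1, 1, 0, 0])
        assert pair_r2(a, a.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_equilibrium(self):
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        assert pair_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_direct_counting_case(self):
        # counts AB=3, Ab=1, aB=1, ab=3 -> f(AB)=0.375, D=0.125, r2=0.25
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        assert pair_r2(a, b) == pytest.approx(0.25, abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pair_r2(np.array([1, 1, 1]), np.array([0, 1, 0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 51)
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        if a.min() == a.max() or b.min() == b.max():
            return
        assert pair_r2(a, b) == pytest.approx(brute_force_r2(a, b),
                                              abs=1e-12)

    def test_symmetric_and_relabel_invariant(self, rng):
        a = rng.integers(0, 2, size=30)
        b = rng.integers(0, 2, size=30)
        a[0], b[0], a[1], b[1] = 0, 0, 1, 1
        r = pair_r2(a, b)
        assert pair_r2(b, a) == pytest.approx(r, abs=1e-14)
        assert pair_r2(1 - a, b) == pytest.approx(r, abs=1e-12)
        assert pair_r2(a, 1 - b) == pytest.approx(r, abs=1e-12)


class TestLdScan:
    def test_pair_count_three_snps(self, rng):
        calls = rng.integers(0, 2, size=(20, 3)).astype(np.int8)
        calls[0] = 0
        calls[1] = 1
        panel = make_panel(calls, positions=[100, 200_000, 40_000_000])
        pairs = ld_scan(panel, maf_min=0.05)
        assert len(pairs) == 3

    def test_low_maf_locus_excluded(self, rng):
        calls = rng.integers(0, 2, size=(50, 3)).astype(np.int8)
        calls[:, 1] = 0
        calls[0, 1] = 1  # MAF 0.02
        calls[:2, 0] = [0, 1]
        calls[:2, 2] = [0, 1]
        panel = make_panel(calls, positions=[100, 200, 300])
        pairs = ld_scan(panel, maf_min=0.05)
        assert len(pairs) == 1
        assert set(pairs["i"]) == {0} and set(pairs["j"]) == {2}

    def test_distance_cap_and_cross_chromosome_exclusion(self, rng):
        calls = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        for j in range(4):
            calls[:2, j] = [0, 1]
        panel = make_panel(
            calls, chroms=["1", "1", "1", "2"],
            positions=[1, 30_000_000, 60_000_001, 100],
        )
        pairs = ld_scan(panel, maf_min=0.0)
        got = {(int(i), int(j)) for i, j in zip(pairs["i"], pairs["j"])}
        # (0,2) spans >50 Mb; SNP 3 is on another chromosome
        assert got == {(0, 1), (1, 2)}

    def test_matches_brute_force_enumeration(self, rng):
        calls = rng.integers(0, 2, size=(40, 20)).astype(np.int8)
        panel = make_panel(calls, positions=np.arange(1, 21) * 50_000)
        pairs = ld_scan(panel, maf_min=0.05)
        freqs = calls.mean(axis=0)
        ok = np.flatnonzero(np.minimum(freqs, 1 - freqs) >= 0.05)
        expected = {(int(i), int(j)) for k, i in enumerate(ok)
                    for j in ok[k + 1:]}
        got = {(int(i), int(j)) for i, j in zip(pairs["i"], pairs["j"])}
        assert got == expected
        for _, row in pairs.iterrows():
            assert row["r2"] == pytest.approx(
                brute_force_r2(calls[:, int(row["i"])],
                               calls[:, int(row["j"])]), abs=1e-12)


class TestDecayTable:
    def pairs_df(self, dists, r2s):
        import pandas as pd
        return pd.DataFrame({
            "i": range(len(dists)), "j": range(1, len(dists) + 1),
            "chrom": "1", "dist_bp": dists, "r2": r2s,
        })

    def test_single_pairs_in_bins(self):
        t = ld_decay_table(self.pairs_df([5000, 15000], [0.4, 0.2]))
        assert t.loc[0, "mean_r2"] == pytest.approx(0.4)
        assert t.loc[1, "mean_r2"] == pytest.approx(0.2)

    def test_mean_within_bin(self):
        t = ld_decay_table(self.pairs_df([1000, 2000], [0.1, 0.3]))
        assert t.loc[0, "mean_r2"] == pytest.approx(0.2)
        assert t.loc[0, "n_pairs"] == 2

    def test_boundary_half_open(self):
        t = ld_decay_table(self.pairs_df([10_000], [0.5]))
        assert t.loc[0, "n_pairs"] == 0
        assert t.loc[1, "n_pairs"] == 1

    def test_empty_bins_reported(self):
        t = ld_decay_table(self.pairs_df([5000], [0.5]))
        assert len(t) == 100
        assert (t["n_pairs"].iloc[1:] == 0).all()

    def test_adjusted_column(self):
        t = ld_decay_table(self.pairs_df([5000], [0.5]), n_diploids=25)
        assert t.loc[0, "mean_r2_adj"] == pytest.approx(0.5 - 1 / 50)


class TestFormulas:
    def test_adjust_r2_cases(self):
        assert adjust_r2(0.05, 20) == pytest.approx(0.025, abs=1e-15)
        assert adjust_r2(0.025, 20) == pytest.approx(0.0, abs=1e-15)
        assert adjust_r2(0.5, 100) == pytest.approx(0.495, abs=1e-15)

    def test_sved_cases(self):
        ne, t = sved_ne(0.05, 0.005)
        assert ne == pytest.approx(950.0, abs=1e-10)
        assert t == pytest.approx(100.0, abs=1e-10)
        assert sved_ne(1.0, 0.37)[0] == pytest.approx(0.0, abs=1e-12)
        assert sved_ne(0.5, 0.00025)[1] == pytest.approx(2000.0, abs=1e-10)

    def test_sved_strictly_decreasing_in_r2(self):
        r2s = np.linspace(0.01, 1.0, 50)
        nes = [sved_ne(r, 0.01)[0] for r in r2s]
        assert (np.diff(nes) < 0).all()

    def test_non_positive_r2_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            sved_ne(0.0, 0.01)


class TestTrajectory:
    def test_formula_chain_first_bin(self):
        # all pairs in bin 1: midpoint 12.5 kb -> c = 0.000125, t = 4000;
        # mean r2 = 0.1 -> Ne = 2000 * 9 = 18000
        rng = np.random.default_rng(0)
        n_hap = 400  # large N so the sample-size adjustment stays small
        calls = rng.integers(0, 2, size=(n_hap, 40)).astype(np.int8)
        panel = make_panel(calls, positions=np.arange(1, 41) * 300)
        traj = ne_trajectory(panel, "p1", relatedness_threshold=None)
        b = traj.bins[0]
        assert b.c == pytest.approx(0.000125)
        assert b.t == pytest.approx(4000.0)
        ne_direct, _ = sved_ne(b.mean_r2, 0.000125)
        assert b.ne == pytest.approx(ne_direct)
        # hand-check the formula chain on the stated numbers
        assert sved_ne(0.1, 0.000125)[0] == pytest.approx(18_000.0)

    def test_small_population_refused(self, rng):
        calls = rng.integers(0, 2, size=(38, 10)).astype(np.int8)
        panel = make_panel(calls, positions=np.arange(1, 11) * 1000)
        with pytest.raises(ValueError, match=">= 20"):
            ne_trajectory(panel, "p1", relatedness_threshold=None)

    def test_bin_layout(self):
        from herdstat.ldne import _trajectory_bins
        bins = _trajectory_bins()
        assert len(bins) == 80 + 25
        # short-range: 80 x 25 kb, c at midpoints
        assert bins[0][:2] == (0.0, 25_000.0)
        assert bins[79][:2] == (1_975_000.0, 2_000_000.0)
        # long-range: generation-indexed, t = 25 .. 1
        ts = [1.0 / (2.0 * c) for _, _, c in bins[80:]]
        np.testing.assert_allclose(ts, np.arange(25, 0, -1))
        assert bins[80][0] == pytest.approx(2_000_000.0)
        assert bins[-1][1] == pytest.approx(50_000_000.0)
        # t decreases as c increases over the whole layout
        cs = [c for _, _, c in bins]
        assert (np.diff(cs) > 0).all()

    def test_ne_adj_dominates_ne(self):
        wf = simulate_wright_fisher(WFConfig(
            ne=50, n_generations=100, n_loci=500, map_length_morgans=1.0,
            sample_size=30, seed=8,
        ))
        traj = ne_trajectory(wf, "wf", relatedness_threshold=None)
        for b in traj.bins:
            if b.ne is not None and b.ne_adj is not None:
                assert b.ne_adj >= b.ne - 1e-9

    def test_wf_bin_r2_tracks_sved_expectation(self):
        # E[r2] ~ 1/(1 + 4 Ne c) + 1/(2N) in drift-recombination
        # equilibrium; 100 generations suffice for the large-c range
        # checked here while leaving most loci polymorphic
        wf = simulate_wright_fisher(WFConfig(
            ne=50, n_generations=100, n_loci=1200, map_length_morgans=2.0,
            sample_size=50, seed=15,
        ))
        pairs = ld_scan(wf, maf_min=0.05)
        sel = pairs[(pairs.dist_bp > 20e6) & (pairs.dist_bp < 60e6)]
        assert len(sel) > 500
        c = sel["dist_bp"].mean() / 100e6
        expected = 1.0 / (1.0 + 4 * 50 * c) + 1.0 / (2 * 50)
        assert abs(sel["r2"].mean() - expected) < 0.25 * expected

    def test_monotone_decay_of_binned_r2(self):
        from scipy.stats import spearmanr
        wf = simulate_wright_fisher(WFConfig(
            ne=50, n_generations=100, n_loci=1500, map_length_morgans=1.0,
            sample_size=50, seed=23,
        ))
        pairs = ld_scan(wf, maf_min=0.05)
        bins = np.floor_divide(pairs["dist_bp"], 5_000_000)
        means = pairs.groupby(bins)["r2"].agg(["mean", "size"])
        means = means[means["size"] >= 1000]
        rho = spearmanr(means.index, means["mean"]).statistic
        assert rho < 0
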