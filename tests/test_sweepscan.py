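"""Tests for the CLR, DCMS and outlier/overlap layer."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciconia import popstats as ps
from ciconia import sweepscan as sw
from ciconia import synthgen as sg
from conftest import enumerate_sweep_pmf


class TestSweepSiteProb:
    def test_two_chromosome_enumeration(self):
        bg = ps.SFS(2, np.array([1.0]))  # all mass on frequency 1/2
        d = math.log(2.0)  # p_e = 1/2 at alpha=1
        assert sw.sweep_site_prob(1, 2, d, 1.0, bg, conditioned=False) == pytest.approx(
            0.375, abs=1e-12
        )

    @pytest.mark.parametrize("n,pe", [(2, 0.5), (3, 0.3), (4, 0.8)])
    def test_matches_configuration_enumeration(self, n, pe):
        bg = sg.neutral_sfs(n)
        pmf = enumerate_sweep_pmf(n, pe, bg)
        d = -math.log(1 - pe)  # alpha = 1
        for b in range(1, n):
            got = sw.sweep_site_prob(b, n, d, 1.0, bg, conditioned=False)
            assert got == pytest.approx(pmf[b], abs=1e-12)
            cond = sw.sweep_site_prob(b, n, d, 1.0, bg)
            assert cond == pytest.approx(pmf[b] / pmf[1:n].sum(), abs=1e-12)

    def test_full_escape_reduces_to_resampled_background(self, neutral_bg_20):
        # at p_e = 1 every lineage draws its allele at the background
        # frequency, so the model equals the binomially resampled spectrum
        # sum_k bg(k) Bin(b; n, k/n), renormalized over polymorphic classes
        from scipy.stats import binom

        n = 20
        b = np.arange(0, n + 1)
        smooth = np.zeros(n + 1)
        for k, w in zip(range(1, n), neutral_bg_20.probs):
            smooth += w * binom.pmf(b, n, k / n)
        expected = smooth[1:n] / smooth[1:n].sum()
        got = np.array(
            [sw.sweep_site_prob(bb, n, 1e12, 1.0, neutral_bg_20) for bb in range(1, n)]
        )
        assert np.allclose(got, expected, atol=1e-9)

    def test_conditioned_probs_sum_to_one(self, neutral_bg_20):
        total = sum(
            sw.sweep_site_prob(b, 20, 5_000, 1e-4, neutral_bg_20) for b in range(1, 20)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self, neutral_bg_20):
        with pytest.raises(ValueError):
            sw.sweep_site_prob(0, 20, 100, 1e-4, neutral_bg_20)
        with pytest.raises(ValueError):
            sw.sweep_site_prob(5, 20, 100, -1e-4, neutral_bg_20)


class TestClr:
    def test_huge_alpha_grid_collapses_to_zero(self, neutral_bg_20):
        # with p_e ~ 1 everywhere the sweep model cannot beat the background
        # it was resampled from, so the clipped ratio is 0 on neutral data
        sites = sg.sim_neutral_sites(20, 2000, 50_000, seed=0)
        lam = sw.clr_window(
            sites["pos"].to_numpy(), sites["x"].to_numpy(), 20, neutral_bg_20,
            test_positions=[25_000], alpha_grid=np.array([1.0]),
        )
        assert lam == pytest.approx(0.0, abs=1e-8)

    def test_translation_invariance(self, neutral_bg_20):
        sites = sg.sim_neutral_sites(20, 40, 50_000, seed=1)
        grid = sw.default_alpha_grid(12)
        a = sw.clr_window(
            sites["pos"].to_numpy(), sites["x"].to_numpy(), 20, neutral_bg_20,
            [10_000, 25_000], grid,
        )
        b = sw.clr_window(
            sites["pos"].to_numpy() + 1_000_000, sites["x"].to_numpy(), 20,
            neutral_bg_20, [1_010_000, 1_025_000], grid,
        )
        assert a == pytest.approx(b, rel=1e-12)
        assert a >= 0

    def test_sparse_window_is_missing(self, neutral_bg_20):
        windows = ps.make_windows({"scaf1": 50_000}, 50_000)
        sites = sg.sim_neutral_sites(20, 5, 50_000, seed=2)
        clr = sw.clr_scan(sites, windows, neutral_bg_20, min_segregating=10)
        assert np.isnan(clr[0])


class TestRankToPvalue:
    def test_hand_ranked_example(self):
        assert np.allclose(sw.rank_to_pvalue([5, 2, 9, 7]), [0.6, 0.8, 0.2, 0.4])

    def test_maximum_gets_smallest_positive_p(self):
        p = sw.rank_to_pvalue(np.arange(9.0))
        assert p.min() == pytest.approx(1 / 10)
        assert np.all(p > 0) and np.all(p < 1)

    def test_average_rank_on_ties(self):
        p = sw.rank_to_pvalue([1.0, 3.0, 3.0])
        assert p[1] == pytest.approx(1 - 2.5 / 4) and p[2] == pytest.approx(0.375)

    def test_uniform_multiset_for_distinct_values(self):
        m = 37
        rng = np.random.default_rng(0)
        p = sw.rank_to_pvalue(rng.permutation(m).astype(float))
        expected = {round(1 - r / (m + 1), 12) for r in range(1, m + 1)}
        assert {round(v, 12) for v in p} == expected

    def test_na_propagates_and_lower_direction(self):
        p = sw.rank_to_pvalue([1.0, np.nan, 3.0], higher_is_evidence=False)
        assert np.isnan(p[1]) and p[0] < p[2]

    def test_all_na_errors(self):
        with pytest.raises(ValueError):
            sw.rank_to_pvalue([np.nan, np.nan])


class TestDcms:
    def test_single_statistic_log_odds(self):
        scores, _ = sw.dcms(np.array([[0.1], [0.5], [0.9]]), corr=np.ones((1, 1)))
        assert scores[0] == pytest.approx(math.log(9), abs=1e-9)
        assert scores[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_statistic_hand_value(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        scores, _ = sw.dcms(np.array([[0.1, 0.2]]), corr=corr)
        assert scores[0] == pytest.approx((math.log(9) + math.log(4)) / 1.5, abs=1e-5)
        assert scores[0] == pytest.approx(2.38901, abs=1e-5)

    def test_na_row_gets_na_score(self):
        stats = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0], [np.nan, 1.0]])
        pvals = np.array([[0.2, 0.3], [0.4, 0.5], [0.6, 0.7], [np.nan, 0.1]])
        scores, corr = sw.dcms(pvals, stats)
        assert np.isnan(scores[3]) and not np.isnan(scores[:3]).any()
        assert corr.shape == (2, 2) and corr[0, 0] == 1.0

    def test_too_few_complete_rows(self):
        with pytest.raises(ValueError):
            sw.dcms(np.array([[0.1, 0.2], [0.3, 0.4]]), np.ones((2, 2)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(0.01, 0.98), st.floats(0.005, 0.015))
    def test_monotone_decreasing_in_each_p(self, p, eps):
        corr = np.array([[1.0, 0.3], [0.3, 1.0]])
        lo, _ = sw.dcms(np.array([[p, 0.4]]), corr=corr)
        hi, _ = sw.dcms(np.array([[p + eps, 0.4]]), corr=corr)
        assert hi[0] < lo[0]


class TestTopOutliers:
    def test_ceiling_rule_at_genome_scale(self):
        rng = np.random.default_rng(0)
        idx = sw.top_outliers(rng.normal(size=22_766), q=0.01)
        assert len(idx) == 228

    def test_small_m_takes_one(self):
        assert len(sw.top_outliers(np.arange(100.0), q=0.01)) == 1

    def test_all_equal_ties_first_in_order(self):
        with pytest.warns(UserWarning, match="tied"):
            idx = sw.top_outliers(np.ones(100), q=0.02)
        assert idx.tolist() == [0, 1]

    def test_na_excluded_from_m(self):
        scores = np.array([np.nan] * 50 + list(range(100)))
        idx = sw.top_outliers(scores, q=0.01)
        assert len(idx) == 1 and idx[0] == 149


class TestMergeRegions:
    def test_adjacent_merge(self):
        w = pd.DataFrame(
            {"scaffold": ["s"] * 3, "start": [0, 50_000, 200_000],
             "end": [50_000, 100_000, 250_000]}
        )
        regions = sw.merge_regions(w)
        assert len(regions) == 2
        assert regions.iloc[0]["n_windows"] == 2

    def test_single_window(self):
        w = pd.DataFrame({"scaffold": ["s"], "start": [0], "end": [50_000]})
        assert len(sw.merge_regions(w)) == 1

    def test_scaffold_boundary_not_adjacent(self):
        w = pd.DataFrame(
            {"scaffold": ["s1", "s2"], "start": [0, 0], "end": [50_000, 50_000]}
        )
        assert len(sw.merge_regions(w)) == 2

    def test_228_windows_31_adjacencies_give_197_regions(self):
        """228 outlier windows containing exactly 31 adjacent pairs merge into
        197 regions (228 - 31), the arithmetic of isolated-window dominance."""
        size = 50_000
        rows = []
        for r in range(197):
            base = r * 10 * size
            rows.append(("s", base, base + size))
            if r < 31:  # first 31 regions get a second, adjacent window
                rows.append(("s", base + size, base + 2 * size))
        w = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
        assert len(w) == 228
        regions = sw.merge_regions(w)
        assert len(regions) == 197


def brute_force_overlap_p(n_universe: int, k1: int, k2: int, k: int) -> float:
    """Exhaustive enumeration: fix the first set, enumerate all second sets."""
    universe = range(n_universe)
    set1 = set(range(k1))
    hits = total = 0
    for s2 in itertools.combinations(universe, k2):
        total += 1
        if len(set1.intersection(s2)) >= k:
            hits += 1
    return hits / total


class TestOverlapTest:
    def test_genome_scale_overlap_value(self):
        res = sw.overlap_test(22_766, (228, 228), 4)
        assert res.p_value == pytest.approx(0.196, abs=5e-4)

    def test_zero_intersection_certain(self):
        assert sw.overlap_test(100, (10, 10), 0).p_value == 1.0

    def test_small_enumeration_value(self):
        assert sw.overlap_test(10, (5, 4), 2).p_value == pytest.approx(
            155 / 210, abs=1e-12
        )

    @pytest.mark.parametrize(
        "n,k1,k2,k", [(8, 3, 4, 1), (10, 5, 4, 2), (12, 6, 5, 3), (11, 4, 4, 0)]
    )
    def test_matches_subset_enumeration(self, n, k1, k2, k):
        res = sw.overlap_test(n, (k1, k2), k)
        assert res.p_value == pytest.approx(brute_force_overlap_p(n, k1, k2, k), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sw.overlap_test(10, (5, 4), 5)
        with pytest.raises(ValueError):
            sw.overlap_test(10, (11, 4), 1)


class TestScanTable:
    def test_orientation_and_scores(self):
        rng = np.random.default_rng(3)
        m = 200
        wstats = pd.DataFrame(
            {
                "scaffold": "s",
                "start": np.arange(m) * 50_000,
                "end": (np.arange(m) + 1) * 50_000,
                "taj_d": rng.normal(size=m),
                "faywu_h": rng.normal(size=m),
            }
        )
        clr = rng.exponential(size=m)
        table = sw.scan_table(wstats, clr)
        # most negative D must get the smallest p_negd
        assert table.loc[table["taj_d"].idxmin(), "p_negd"] == table["p_negd"].min()
        assert table["dcms"].notna().all()
        assert table.attrs["spearman"].shape == (3, 3)
        flipped = sw.scan_table(wstats, clr, flip_h=True)
        assert np.allclose(flipped["p_h"], 1 - table["p_h"])
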