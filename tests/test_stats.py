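"""Rank-sum, FDR, Kruskal-Wallis, paired t and two-way ANOVA contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from midgutlam import bh_adjust, kruskal_pairwise, paired_t, \
    per_bin_compare, rank_sum_test, two_way_anova_tukey


class TestRankSum:
    def test_exact_small_sample(self):
        # all 6 labelings of {1,2,3,4} into groups of 2; U in {0,4} twice
        _, p = rank_sum_test((1, 2), (3, 4))
        assert p == pytest.approx(1.0 / 3.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.random(6), rng.random(9)
            assert rank_sum_test(a, b)[1] == pytest.approx(
                rank_sum_test(b, a)[1])

    def test_normal_close_to_exact(self):
        # continuity-corrected normal approximation tracks the exact
        # enumeration within 0.08 on small continuous samples
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.random(rng.integers(3, 6))
            b = rng.random(rng.integers(3, 6))
            _, pe = rank_sum_test(a, b, method="exact")
            _, pn = rank_sum_test(a, b, method="normal")
            assert abs(pe - pn) < 0.08

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.random(4), rng.random(5)
            u, p = rank_sum_test(a, b, method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_normal_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.integers(0, 6, 15).astype(float)
            b = rng.integers(0, 6, 12).astype(float)
            u, p = rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_fixture(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p),
                               multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    def test_monotone_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPerBinCompare:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        mat = rng.random((4, 30))
        res = per_bin_compare(mat, mat.copy())
        assert not res["significant"].any()

    def test_min_samples(self):
        mat = np.random.default_rng(0).random((2, 10))
        with pytest.raises(ValueError, match=">= 3 samples"):
            per_bin_compare(mat, mat)

    def test_missing_bin_rule(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 5))
        b = rng.random((4, 5))
        a[:3, 0] = np.nan  # missing in 3 of 4 > half -> unscorable
        a[:2, 1] = np.nan  # missing in half -> scorable
        res = per_bin_compare(a, b)
        assert np.isnan(res.loc[0, "p_adj"]) and not res.loc[0, "significant"]
        assert not np.isnan(res.loc[1, "p_adj"])


class TestKruskal:
    def test_h_fixture(self):
        res = kruskal_pairwise([(1, 2), (3, 4), (5, 6)])
        assert res["H"] == pytest.approx(4.571, abs=1e-3)
        assert len(res["pairwise"]) == 3

    def test_identical_groups_h_zero(self):
        res = kruskal_pairwise([(1, 2), (1, 2), (1, 2)])
        assert res["H"] == pytest.approx(0.0)

    def test_group_permutation_consistent(self):
        g = [(1.0, 2.0, 3.0), (2.5, 3.5, 4.0), (5.0, 6.0, 7.0)]
        r1 = kruskal_pairwise(g)
        r2 = kruskal_pairwise(g[::-1])
        assert r1["H"] == pytest.approx(r2["H"])
        p1 = sorted(r1["pairwise"]["p_raw"])
        p2 = sorted(r2["pairwise"]["p_raw"])
        assert np.allclose(p1, p2)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_pairwise([(1, 2), (3, 4)])


class TestPairedT:
    def test_fixture(self):
        t, p = paired_t((1, 2, 4), (2, 3, 3))
        assert t == pytest.approx(-0.5)

    def test_degenerate_differences(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t((1, 2, 3), (2, 3, 4))

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.random(8), rng.random(8)
        assert paired_t(x, y)[1] == pytest.approx(paired_t(y, x)[1])


class TestTwoWayAnova:
    def fixture(self):
        vals = [0, 2, 2, 4, 4, 6, 6, 8]
        fa = ["a1"] * 4 + ["a2"] * 4
        fb = ["b1", "b1", "b2", "b2"] * 2
        return vals, fa, fb

    def test_balanced_fixture(self):
        anova, _ = two_way_anova_tukey(*self.fixture())
        assert anova.loc["A", "sum_sq"] == pytest.approx(32.0)
        assert anova.loc["B", "sum_sq"] == pytest.approx(8.0)
        assert anova.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert anova.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert anova.loc["A", "F"] == pytest.approx(16.0)

    def test_location_invariance(self):
        vals, fa, fb = self.fixture()
        a1, _ = two_way_anova_tukey(vals, fa, fb)
        a2, _ = two_way_anova_tukey(np.asarray(vals) + 100.0, fa, fb)
        assert np.allclose(a1["F"].iloc[:3], a2["F"].iloc[:3])

    def test_identical_cell_means_tukey_zero(self):
        vals = [1.0, 3.0] * 4
        fa = ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]
        fb = ["b1", "b1", "b2", "b2"] * 2
        _, tukey = two_way_anova_tukey(vals, fa, fb)
        assert np.allclose(tukey["meandiff"].astype(float), 0.0)

    def test_empty_cell_errors(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova_tukey([1, 2, 3, 4], ["a1", "a1", "a2", "a2"],
                                ["b1", "b2", "b1", "b1"])
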