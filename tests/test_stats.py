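"""Core nonparametric tests against enumeration oracles and scipy."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoscreen import stats
from chemoscreen.errors import AnalysisError

from conftest import (
    oracle_bh,
    oracle_fisher_two_sided,
    oracle_friedman_exact,
    oracle_mann_whitney_exact,
    oracle_wilcoxon_exact,
)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((7, 1, 0, 3), 8 / 330),
            ((5, 0, 0, 5), 2 / 252),
            ((0, 3, 0, 5), 1.0),
        ],
    )
    def test_known_tables(self, table, expected):
        res = stats.fisher_exact_2x2(*table)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.exact

    def test_hpv_worked_example_rounds_to_printed_value(self):
        # 7/8 HPV-negative lines inducing vs 0/3 HPV-positive
        p = stats.fisher_exact_2x2(7, 1, 0, 3).p_value
        assert round(p, 2) == 0.02

    def test_matches_enumeration_oracle_on_small_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b + c + d == 0 or a + b + c + d > 30:
                continue
            res = stats.fisher_exact_2x2(a, b, c, d)
            assert res.p_value == pytest.approx(
                oracle_fisher_two_sided(a, b, c, d), rel=1e-10
            )

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            ours = stats.fisher_exact_2x2(a, b, c, d).p_value
            theirs = ss.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_odds_ratio_and_errors(self):
        assert stats.fisher_exact_2x2(2, 1, 1, 2).statistic == pytest.approx(4.0)
        assert math.isinf(stats.fisher_exact_2x2(3, 0, 1, 2).statistic)
        with pytest.raises(AnalysisError):
            stats.fisher_exact_2x2(0, 0, 0, 0)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2], [3, 4], 2 / 6),
            ([1, 2, 3], [4, 5, 6], 2 / 20),
        ],
    )
    def test_exact_examples(self, x, y, expected):
        res = stats.mann_whitney(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(expected)

    def test_identical_groups_give_p_one(self):
        res = stats.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 7, size=2)
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=m).tolist()
            res = stats.mann_whitney(x, y)
            assert res.exact
            assert res.p_value == pytest.approx(oracle_mann_whitney_exact(x, y))

    def test_approximation_close_to_exact_for_untied_moderate_n(self, rng):
        for _ in range(10):
            n = int(rng.integers(9, 13))
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=n).tolist()
            approx = stats.mann_whitney(x, y, exact_threshold=0).p_value
            exact = stats.mann_whitney(x, y, exact_threshold=15).p_value
            assert abs(approx - exact) < 0.01

    def test_degenerate_constant_data(self):
        res = stats.mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            stats.mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_diffs_five_pairs(self):
        res = stats.wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 32)

    def test_all_zero_diffs_degenerate(self):
        res = stats.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_magnitude_tied_opposite_signs(self):
        res = stats.wilcoxon_signed_rank([1.0, 0.0], [0.0, 1.0])
        assert res.p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = stats.wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(oracle_wilcoxon_exact(a - b))

    def test_approximation_close_to_exact(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 16))
            a, b = rng.normal(size=n), rng.normal(size=n)
            approx = stats.wilcoxon_signed_rank(a, b, exact_threshold=0).p_value
            exact = stats.wilcoxon_signed_rank(a, b, exact_threshold=16).p_value
            assert abs(approx - exact) < 0.01


class TestKruskalWallis:
    def test_hand_computed_untied_value(self):
        res = stats.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        expected = 12 / 42 * (2 * 1.5**2 + 2 * 3.5**2 + 2 * 5.5**2) - 21
        assert res.statistic == pytest.approx(expected)

    def test_all_equal_degenerates(self):
        res = stats.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_agree_with_mw_normal_approx(self, rng):
        x = rng.normal(size=10).tolist()
        y = rng.normal(size=12).tolist()
        kw = stats.kruskal_wallis([x, y])
        mw = stats.mann_whitney(x, y, exact_threshold=0, continuity_correction=False)
        assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 5, size=8).astype(float) for _ in range(3)]
        ours = stats.kruskal_wallis(groups)
        theirs = ss.kruskal(*groups)
        assert ours.statistic == pytest.approx(theirs.statistic)
        assert ours.p_value == pytest.approx(theirs.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(AnalysisError):
            stats.kruskal_wallis([[1.0, 2.0]])


class TestFriedman:
    def test_identical_rows_degenerate(self):
        res = stats.friedman([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_consistent_rankings_exact(self):
        res = stats.friedman([[1, 2, 3], [4, 5, 6], [0.1, 0.5, 0.9]])
        assert res.exact
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(oracle_friedman_exact([[1, 2, 3]] * 3))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            mat = rng.normal(size=(3, 3))
            res = stats.friedman(mat)
            assert res.p_value == pytest.approx(oracle_friedman_exact(mat))

    def test_column_permutation_invariance(self, rng):
        mat = rng.normal(size=(4, 3))
        p1 = stats.friedman(mat).p_value
        p2 = stats.friedman(mat[:, [2, 0, 1]]).p_value
        assert p1 == pytest.approx(p2)

    def test_large_sample_matches_scipy(self, rng):
        mat = rng.normal(size=(10, 4))
        res = stats.friedman(mat, exact_bound=0)
        theirs = ss.friedmanchisquare(*[mat[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(theirs.statistic)
        assert res.p_value == pytest.approx(theirs.pvalue)


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = stats.dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], [(0, 1)])
        assert res[0].z == pytest.approx(0.0)
        assert res[0].p_value == 1.0

    def test_extreme_pair_has_largest_z(self):
        res = stats.dunn_posthoc(
            [[1, 2], [3, 4], [5, 6]], [(0, 1), (1, 2), (0, 2)]
        )
        zs = {(r.group_i, r.group_j): abs(r.z) for r in res}
        assert zs[(0, 2)] == max(zs.values())
        ps = {(r.group_i, r.group_j): r.p_value for r in res}
        assert ps[(0, 2)] == min(ps.values())

    def test_multiplier_scales_with_requested_comparisons(self, rng):
        groups = [rng.normal(size=5).tolist() for _ in range(3)]
        one = stats.dunn_posthoc(groups, [(0, 2)])[0].p_value
        three = [
            r for r in stats.dunn_posthoc(groups, [(0, 1), (1, 2), (0, 2)])
            if (r.group_i, r.group_j) == (0, 2)
        ][0].p_value
        assert three == pytest.approx(min(one * 3, 1.0))

    def test_unknown_group_rejected(self):
        with pytest.raises(AnalysisError):
            stats.dunn_posthoc([[1.0], [2.0]], [(0, 5)])

    def test_paired_mode_symmetry(self, rng):
        conds = [rng.normal(size=6).tolist() for _ in range(3)]
        res = stats.dunn_posthoc(conds, [(0, 1), (1, 0)], paired=True)
        assert res[0].z == pytest.approx(-res[1].z)
        assert res[0].p_value == pytest.approx(res[1].p_value)


class TestPearson:
    def test_perfect_linearity(self):
        res = stats.pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_computed_example(self):
        res = stats.pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r_xy = stats.pearson(x, y).statistic
        assert stats.pearson(y, x).statistic == pytest.approx(r_xy)
        assert stats.pearson(3.0 * x + 2.0, y).statistic == pytest.approx(r_xy)
        assert stats.pearson(-2.0 * x, y).statistic == pytest.approx(-r_xy)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        ours = stats.pearson(x, y)
        theirs = ss.pearsonr(x, y)
        assert ours.statistic == pytest.approx(theirs.statistic)
        assert ours.p_value == pytest.approx(theirs.pvalue)

    def test_zero_variance_degenerate(self):
        res = stats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate

    def test_null_type_one_error_calibrated(self, rng):
        # Uniformity of p under the null at n = 12.
        hits = 0
        n_sim = 5000
        for _ in range(n_sim):
            x, y = rng.normal(size=12), rng.normal(size=12)
            if stats.pearson(x, y).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.07


class TestBH:
    def test_single_p_is_identity(self):
        res = stats.bh_fdr([0.037])
        assert res.q_values == (0.037,)

    def test_step_up_hand_example(self):
        res = stats.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert res.q_values == pytest.approx((0.04, 0.04, 0.04, 0.04))

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 20))
            p = rng.uniform(size=m).round(3).tolist()
            q = stats.bh_fdr(p).q_values
            assert np.allclose(q, oracle_bh(p))
            assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))

    def test_order_equivariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        q = np.array(stats.bh_fdr(p).q_values)
        q_perm = np.array(stats.bh_fdr(p[perm]).q_values)
        assert np.allclose(q[perm], q_perm)

    def test_invalid_p_rejected(self):
        with pytest.raises(AnalysisError):
            stats.bh_fdr([0.2, 1.3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
    y=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
)
def test_mann_whitney_label_symmetry(x, y):
    """Swapping the groups leaves the two-sided p unchanged."""
    p_xy = stats.mann_whitney(x, y).p_value
    p_yx = stats.mann_whitney(y, x).p_value
    assert p_xy == pytest.approx(p_yx)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_q_bounds(p):
    """q is in [p, 1] elementwise and monotone under sorting by p."""
    q = stats.bh_fdr(p).q_values
    assert all(pi - 1e-12 <= qi <= 1.0 for pi, qi in zip(p, q))
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.array(q)[order]
    assert np.all(np.diff(q_sorted) >= -1e-12)
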