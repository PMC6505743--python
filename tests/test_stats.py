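import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mewsaudit import contingency_test, median_iqr, percent, rank_sum_test, round_half_up
from mewsaudit.stats import quartiles


class TestMedianIqr:
    def test_odd_sample_tukey_hinges(self):
        med, iqr = median_iqr([1, 2, 3, 4, 5])
        assert med == 3
        assert quartiles([1, 2, 3, 4, 5]) == (2, 4)
        assert iqr == 2

    def test_exclusive_rule_differs_on_odd_samples(self):
        assert quartiles([1, 2, 3, 4, 5], "exclusive") == (1.5, 4.5)

    def test_singleton_and_constant(self):
        assert median_iqr([7]) == (7, 0)
        assert median_iqr([3.3] * 10)[1] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestRankSum:
    def test_identical_samples_degenerate(self):
        r = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert r.z_score == 0 and r.p_two_sided == 1

    def test_fully_separated_small_samples_exact(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0
        assert r.p_two_sided == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments
        r = rank_sum_test([1, 2], [3, 4])
        assert r.p_two_sided == pytest.approx(1 / 3)  # 2 of C(4,2)=6

    def test_u_statistics_sum_to_nx_ny(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=13), rng.normal(0.4, 1, size=9)
        r = rank_sum_test(x, y)
        r_swapped = rank_sum_test(y, x)
        assert r.u_statistic + r_swapped.u_statistic == 13 * 9
        assert r.p_two_sided == pytest.approx(r_swapped.p_two_sided)
        assert r.z_score == pytest.approx(-r_swapped.z_score)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(1, 1, size=15)
        base = rank_sum_test(x, y)
        for f in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
            t = rank_sum_test(f(x), f(y))
            assert t.u_statistic == base.u_statistic
            assert t.p_two_sided == pytest.approx(base.p_two_sided)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(10, 2, size=40))
        y = np.round(rng.normal(11, 2, size=35))
        ours = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.tie_correction_applied
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_path_matches_scipy_exact(self):
        x, y = [1.0, 4.0, 7.0, 9.0], [2.0, 3.0, 8.0, 11.0, 15.0]
        ours = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.exact
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def brute_force_exact_p(x, y):
    """Two-sided exact p by enumerating every rank assignment (oracle)."""
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    ranks = range(1, n + 1)

    def u_of(subset):
        return sum(subset) - n_x * (n_x + 1) / 2

    pooled_ranks = sps.rankdata(list(x) + list(y))
    u_obs = u_of(pooled_ranks[:n_x])
    u_min = min(u_obs, n_x * n_y - u_obs)
    count = total = 0
    for subset in itertools.combinations(ranks, n_x):
        total += 1
        count += u_of(subset) <= u_min
    return min(1.0, 2 * count / total)


def test_exact_p_equals_enumeration_spot_checks():
    rng = np.random.default_rng(21)
    for n_x, n_y in [(2, 5), (4, 4), (3, 6), (5, 5)]:
        x = rng.permutation(100)[: n_x + n_y].astype(float)
        r = rank_sum_test(x[:n_x], x[n_x:])
        assert r.p_two_sided == pytest.approx(brute_force_exact_p(x[:n_x], x[n_x:]))


class TestContingency:
    def test_perfect_homogeneity(self):
        r = contingency_test(10, 10, 10, 10)
        assert r.statistic == 0 and r.p_two_sided == 1
        assert r.method == "pearson_chi_square"

    def test_fisher_diagonal_table(self):
        r = contingency_test(5, 0, 0, 5)
        assert r.method == "fisher_exact"
        assert r.p_two_sided == pytest.approx(2 / 252)

    def test_large_table_chi_square_worked_value(self):
        # sex distribution of two ~300-patient surgical groups: no difference
        r = contingency_test(204, 116, 173, 101)
        assert r.method == "pearson_chi_square"
        assert round_half_up(r.p_two_sided, 2) == 0.88

    def test_transposition_invariance(self):
        for cells in [(12, 5, 7, 20), (3, 1, 2, 4)]:
            a, b, c, d = cells
            assert contingency_test(a, b, c, d).p_two_sided == pytest.approx(
                contingency_test(a, c, b, d).p_two_sided
            )

    def test_doubling_mode_on_symmetric_table(self):
        r = contingency_test(5, 0, 0, 5, method="fisher_exact", fisher_mode="doubling")
        assert r.p_two_sided == pytest.approx(2 / 252)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            contingency_test(0, 0, 3, 4)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            contingency_test(1.5, 2, 3, 4)


def test_round_half_up_and_percent():
    assert round_half_up(25.45, 1) == 25.5  # .45 rounds up, not to even
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(38.93, 0) == 39.0
    assert percent(199, 7929) == 2.5
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)
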