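"""Exact Mann-Whitney, chi-square, and modifier classification."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from smnmod.growth import (
    GrowthSummary,
    chi_square_2xk,
    classify_modifier,
    compare_growth,
    compare_mean_length,
    mann_whitney_u,
    sem,
)


def mwu_brute_force_p(a, b):
    """Independent oracle: two-sided exact p by explicit enumeration of
    every label assignment, counting discordant pairs directly."""
    c = list(a) + list(b)
    n, n_a = len(c), len(a)
    mu = n_a * (n - n_a) / 2.0

    def u_of(idx_a):
        group_a = [c[i] for i in idx_a]
        group_b = [c[i] for i in range(n) if i not in idx_a]
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x < y) + 0.5 * (x == y)
        return u

    obs = abs(u_of(set(range(n_a))) - mu)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        hits += abs(u_of(set(idx)) - mu) >= obs - 1e-9
    return hits / total


class TestMannWhitney:
    def test_separated_pairs(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_tied_example_matches_brute_force(self):
        a, b = [1, 1, 2], [1, 2, 2]
        res = mann_whitney_u(a, b, mode="exact")
        assert res.p_value == pytest.approx(mwu_brute_force_p(a, b))

    def test_minimum_attainable_p_three_vs_three(self):
        res = mann_whitney_u([0.05, 0.07, 0.06], [0.17, 0.19, 0.18])
        assert res.p_value == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_oracle_on_random_inputs(self):
        # ties are forced by drawing from small integer pools
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n_a = int(rng.integers(1, 7))
            n_b = int(rng.integers(1, 7))
            pool = int(rng.integers(2, 6))
            a = rng.integers(0, pool, size=n_a).tolist()
            b = rng.integers(0, pool, size=n_b).tolist()
            res = mann_whitney_u(a, b, mode="exact")
            assert res.p_value == pytest.approx(mwu_brute_force_p(a, b)), (a, b)

    def test_auto_mode_dispatch(self):
        small = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="auto")
        assert small.method == "exact"
        rng = np.random.default_rng(0)
        big = mann_whitney_u(rng.normal(size=30), rng.normal(size=30), "auto")
        assert big.method == "approximate"
        assert 0 <= big.p_value <= 1

    def test_approximate_agrees_with_exact_at_moderate_n(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=6)
        b = rng.normal(1.0, size=6)
        pe = mann_whitney_u(a, b, mode="exact").p_value
        pa = mann_whitney_u(a, b, mode="approximate").p_value
        assert pa == pytest.approx(pe, abs=0.05)


class TestChiSquare:
    def test_closed_form_2x2(self):
        res = chi_square_2xk([50, 50], [70, 30])
        assert res.chi2 == pytest.approx(200 * (50 * 30 - 50 * 70) ** 2
                                         / (100 * 100 * 120 * 80))
        assert res.chi2 == pytest.approx(8.3333, abs=1e-4)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0039, abs=2e-4)

    def test_proportional_rows_are_null(self):
        res = chi_square_2xk([20, 40], [10, 20])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = chi_square_2xk([10, 0], [0, 10])
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_row_swap_invariance(self):
        a = chi_square_2xk([12, 30, 8], [25, 9, 16])
        b = chi_square_2xk([25, 9, 16], [12, 30, 8])
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.df == b.df == 2

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            a = rng.integers(1, 40, size=k)
            b = rng.integers(1, 40, size=k)
            mine = chi_square_2xk(a, b)
            ref = stats.chi2_contingency(np.vstack([a, b]), correction=False)
            assert mine.chi2 == pytest.approx(ref.statistic)
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_zero_expected_cell_instructs_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            chi_square_2xk([0, 10], [0, 20])


class TestCompareGrowth:
    def test_decrease_at_minimum_p(self):
        treated = GrowthSummary("homozygous", "x", (0.05, 0.07, 0.06))
        control = GrowthSummary("homozygous", "empty", (0.17, 0.19, 0.18))
        res = compare_growth(treated, control)
        assert res.direction == "decrease"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_summaries(self):
        s = GrowthSummary("homozygous", "x", (0.1, 0.2, 0.3))
        res = compare_growth(s, GrowthSummary("homozygous", "empty",
                                              (0.1, 0.2, 0.3)))
        assert res.direction == "none"
        assert res.p_value == pytest.approx(1.0)

    def test_increase_direction(self):
        treated = GrowthSummary("heterozygous", "x", (0.5, 0.6, 0.55))
        control = GrowthSummary("heterozygous", "empty", (0.3, 0.35, 0.32))
        assert compare_growth(treated, control).direction == "increase"

    def test_genotype_mismatch_rejected(self):
        a = GrowthSummary("homozygous", "x", (0.1, 0.2, 0.3))
        b = GrowthSummary("heterozygous", "empty", (0.1, 0.2, 0.3))
        with pytest.raises(ValueError, match="mismatch"):
            compare_growth(a, b)

    def test_requires_three_trials(self):
        a = GrowthSummary("homozygous", "x", (0.1, 0.2))
        b = GrowthSummary("homozygous", "empty", (0.1, 0.2, 0.3))
        with pytest.raises(ValueError, match="3 trials"):
            compare_growth(a, b)

    def test_sem_definition(self):
        vals = [10.0, 14.0, 18.0, 22.0]
        assert sem(vals) == pytest.approx(np.std(vals, ddof=1) / 2.0)
        s = GrowthSummary("homozygous", "x", (0.10, 0.14, 0.18, 0.22))
        assert s.sem_pct == pytest.approx(sem([10, 14, 18, 22]))


class TestClassifyModifier:
    def _res(self, p, direction):
        from smnmod.growth import ComparisonResult

        return ComparisonResult(statistic=0.0, test_used="mann_whitney",
                                p_value=p, direction=direction)

    def test_enhancer_pattern(self):
        # homozygous deficit with an unchanged heterozygous control
        assert classify_modifier(self._res(0.01, "decrease"),
                                 self._res(0.6, "none")) == "enhancer"

    def test_heterozygous_only_change_is_nonspecific(self):
        assert classify_modifier(self._res(0.4, "none"),
                                 self._res(0.01, "increase")) == "nonspecific"

    def test_both_null(self):
        assert classify_modifier(self._res(0.4, "decrease"),
                                 self._res(0.3, "increase")) == "none"

    def test_suppressor_pattern(self):
        assert classify_modifier(self._res(0.02, "increase"),
                                 self._res(0.9, "none")) == "suppressor"

    def test_null_type1_bounded_at_three_trials(self):
        # with three trials per arm the exact test's smallest two-sided p
        # is 0.1, so the enhancer/suppressor false-positive rate at alpha
        # 0.05 is structurally zero (<= alpha bound)
        rng = np.random.default_rng(99)
        calls = 0
        for _ in range(300):
            f = rng.normal(0.2, 0.03, size=(4, 3))
            homo = compare_growth(
                GrowthSummary("homozygous", "x", tuple(f[0])),
                GrowthSummary("homozygous", "empty", tuple(f[1])),
            )
            het = compare_growth(
                GrowthSummary("heterozygous", "x", tuple(f[2])),
                GrowthSummary("heterozygous", "empty", tuple(f[3])),
            )
            calls += classify_modifier(homo, het) in ("enhancer", "suppressor")
        assert calls == 0


class TestCompareMeanLength:
    def test_identical_groups(self):
        a = [100.0, 110.0, 120.0, 130.0]
        res = compare_mean_length(a, list(a))
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "none"

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(100, 5, size=20)
        b = rng.normal(50, 5, size=20)
        res = compare_mean_length(b, a)
        assert res.direction == "decrease"
        assert res.p_value < 0.001

    def test_tiny_groups_take_exact_rank_path(self):
        res = compare_mean_length([1.0, 2.0], [1.5, 2.5])
        assert res.test_used == "mann_whitney"

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_mean_length([1.0], [1.0, 2.0])
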