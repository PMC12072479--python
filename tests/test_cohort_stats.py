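"""Chi-square/Fisher and Mann-Whitney against enumeration oracles;
group-summary behaviour."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icpwaves.cohort_stats import (
    chi_square_2x2,
    comparisons_to_frame,
    mann_whitney,
    summarize_groups,
)


def fisher_enumeration_p(table):
    """Exact two-sided Fisher p by enumerating all tables with the same
    margins (hypergeometric point probabilities <= observed)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


def mwu_permutation_p(x, y):
    """Exact two-sided Mann-Whitney p by brute-force label permutation."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    offset = n1 * (n1 + 1) / 2
    us = [ranks[list(c)].sum() - offset for c in combinations(range(n1 + n2), n1)]
    us = np.array(us)
    u = ranks[:n1].sum() - offset
    lo, hi = min(u, n1 * n2 - u), max(u, n1 * n2 - u)
    return min(1.0, (np.sum(us <= lo + 1e-9) + np.sum(us >= hi - 1e-9)) / len(us))


class TestChiSquare:
    def test_sex_by_prematurity_worked_example(self):
        # 2x2 counts 9/7 vs 13/7 reproduce the printed statistic
        r = chi_square_2x2([[9, 7], [13, 7]])
        assert r.test == "chi2"
        assert r.statistic == pytest.approx(0.286, abs=5e-4)
        assert r.p_value == pytest.approx(0.593, abs=5e-4)

    def test_balanced_table_no_association(self):
        r = chi_square_2x2([[5, 5], [5, 5]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_small_expected_switches_to_fisher_and_matches_enumeration(self):
        table = [[3, 1], [1, 3]]
        r = chi_square_2x2(table)
        assert r.test == "fisher"
        assert r.p_value == pytest.approx(fisher_enumeration_p(table), abs=1e-12)

    def test_fisher_matches_enumeration_on_random_small_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 5, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            r = chi_square_2x2(t)
            if r.test == "fisher":
                assert r.p_value == pytest.approx(fisher_enumeration_p(t.tolist()), abs=1e-9)

    def test_zero_margin_flagged_undefined(self):
        r = chi_square_2x2([[0, 0], [5, 7]])
        assert np.isnan(r.p_value)
        assert "zero margin" in r.note

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, -1], [2, 2]])
        with pytest.raises(ValueError):
            chi_square_2x2([[1.5, 1], [2, 2]])


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(4.5)  # n1*n2/2
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_u_zero(self):
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert r.statistic == 0.0

    def test_all_identical_values_p_one(self):
        r = mann_whitney([7, 7, 7], [7, 7])
        assert r.p_value == 1.0

    def test_exact_p_matches_permutation_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            r = mann_whitney(x, y)
            assert "exact" in r.test
            assert r.p_value == pytest.approx(mwu_permutation_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_matches_permutation_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            if np.unique(np.r_[x, y]).size == 1:
                continue
            r = mann_whitney(x, y)
            assert r.p_value == pytest.approx(mwu_permutation_p(x, y), abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            r = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_use_asymptotic(self, rng):
        r = mann_whitney(rng.normal(size=20), rng.normal(size=20))
        assert "asymptotic" in r.test

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSummarizeGroups:
    @staticmethod
    def _frame(rng, shift=0.0, n=18):
        a = rng.uniform(6.7, 29, n)
        b = rng.uniform(6.7, 29, n) + shift
        return pd.DataFrame(
            {"mean_icp": np.r_[a, b], "group": ["x"] * n + ["y"] * n}
        )

    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 4, 5] * 2, "group": ["a"] * 5 + ["b"] * 5})
        rows = summarize_groups(df, "group")
        assert rows[0].p_value == pytest.approx(1.0)
        assert rows[0].significant is False

    def test_known_location_shift_detected(self, rng):
        hits = sum(
            summarize_groups(self._frame(np.random.default_rng(s), shift=10.0), "group")[0].p_value
            <= 0.05
            for s in range(40)
        )
        assert hits >= 38  # >= 95% power at a 10 mmHg shift, n=18/18

    def test_single_group_summaries_only(self):
        df = pd.DataFrame({"v": [1.0, 2, 3], "group": ["a"] * 3})
        rows = summarize_groups(df, "group")
        assert np.isnan(rows[0].p_value)
        assert rows[0].test == "none"

    def test_test_selection_recorded_and_deterministic(self, rng):
        df = self._frame(rng)
        rows1 = summarize_groups(df, "group")
        rows2 = summarize_groups(df, "group")
        assert rows1[0].test == rows2[0].test
        assert rows1[0].test in ("t-test", "mann-whitney (asymptotic)")

    def test_binary_variable_uses_contingency_test(self, rng):
        df = pd.DataFrame(
            {
                "preterm": [True] * 9 + [False] * 7 + [True] * 13 + [False] * 7,
                "group": ["pre"] * 16 + ["full"] * 20,
            }
        )
        # this is the sex-by-prematurity table transposed into group form
        rows = summarize_groups(df, "group", variables=["preterm"])
        assert rows[0].test == "chi2"
        assert rows[0].statistic == pytest.approx(0.286, abs=5e-4)

    def test_frame_rendering(self, rng):
        df = self._frame(rng)
        out = comparisons_to_frame(summarize_groups(df, "group"))
        assert {"variable", "test", "p_value"} <= set(out.columns)
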