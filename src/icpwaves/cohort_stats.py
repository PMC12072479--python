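"""Cohort summaries and two-group comparisons.

Reproduces the reporting style of small clinical cohorts: continuous
variables are tested for normality (Shapiro–Wilk) and then summarized as
mean ± SD with Student's t-test, or as median (min–max) with the
Mann–Whitney U test; categorical variables use Pearson's chi-square without
continuity correction, switching to Fisher's exact test when any expected
cell count falls below 5.  All p-values are two-sided; significance is
declared at p <= 0.05 and no multiple-testing correction is applied.

For very small samples (both groups of size <= 8) the Mann–Whitney p-value
is computed by exhaustive enumeration of all group-label assignments, which
remains exact in the presence of ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "GroupComparison",
    "chi_square_2x2",
    "mann_whitney",
    "summarize_groups",
]

ALPHA_NORMALITY = 0.05
EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value and the test actually
    used (selection between alternatives is deterministic and recorded)."""

    statistic: float
    p_value: float
    test: str
    note: str = ""


def chi_square_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Association test for a 2x2 contingency table.

    Pearson chi-square on 1 df without continuity correction; switches to
    Fisher's exact test when any expected cell count is below 5.  A zero
    row or column margin makes the test undefined (p = NaN, flagged).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(float("nan"), float("nan"), "chi2", note="zero margin: undefined")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult(float(odds), float(p), "fisher", note="expected cell < 5")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(chi2), float(p), "chi2")


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided Mann–Whitney p by exhaustive enumeration of label
    assignments; exact under ties (midranks are fixed, labels permute)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = x.size, y.size
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (ranks[list(c)].sum() - offset for c in combinations(range(n), n1)),
        dtype=float,
        count=comb(n, n1),
    )
    lo = min(u_obs, n1 * n2 - u_obs)
    hi = max(u_obs, n1 * n2 - u_obs)
    eps = 1e-9
    p = (np.sum(us <= lo + eps) + np.sum(us >= hi - eps)) / us.size
    return float(min(p, 1.0))


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    U is reported for the first sample.  With both samples of size <= 8 the
    p-value comes from exhaustive enumeration (exact even with ties);
    larger samples use the tie-corrected normal approximation.  Completely
    tied data yield p = 1.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(u1, 1.0, "mann-whitney (degenerate)", note="all values identical")
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        p = _exact_mwu_p(x, y, u1)
        return TestResult(u1, p, "mann-whitney (exact enumeration)")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney (asymptotic)")


@dataclass
class GroupComparison:
    """One row of a cohort comparison table."""

    variable: str
    group_labels: tuple[str, ...]
    summaries: tuple[str, ...]
    test: str
    statistic: float
    p_value: float
    significant: bool | None

    def to_dict(self) -> dict:
        d = {"variable": self.variable}
        for lab, s in zip(self.group_labels, self.summaries):
            d[str(lab)] = s
        d.update(test=self.test, statistic=self.statistic, p_value=self.p_value)
        return d


def _summary_string(v: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"
    return f"{np.median(v):.1f} ({v.min():.1f}–{v.max():.1f})"


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return col.dtype == bool or (len(vals) <= 2 and col.dtype == object)


def summarize_groups(
    records: pd.DataFrame,
    grouping: str,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Compare every variable between the two groups defined by
    ``grouping``.

    Numeric variables: Shapiro–Wilk on each group at alpha = 0.05 decides
    between mean ± SD with a t-test (both groups normal) and
    median (min–max) with Mann–Whitney.  Binary variables: chi-square /
    Fisher on the 2x2 table.  A group with fewer than 3 observations gets a
    summary but no test (single-group input likewise).
    """
    if grouping not in records.columns:
        raise ValueError(f"grouping column {grouping!r} not in records")
    levels = [lv for lv in records[grouping].dropna().unique()]
    if variables is None:
        variables = [c for c in records.columns if c != grouping and c != "patient_id"]

    out: list[GroupComparison] = []
    for var in variables:
        groups = [records.loc[records[grouping] == lv, var].dropna() for lv in levels]
        col = records[var]
        testable = len(levels) == 2 and all(len(g) >= 3 for g in groups)

        if pd.api.types.is_numeric_dtype(col) and not _is_binary(col):
            arrs = [g.to_numpy(dtype=float) for g in groups]
            if testable:
                normal = all(
                    g.size >= 3 and np.ptp(g) > 0 and stats.shapiro(g).pvalue > ALPHA_NORMALITY
                    for g in arrs
                )
                if normal:
                    res = stats.ttest_ind(arrs[0], arrs[1])
                    tr = TestResult(float(res.statistic), float(res.pvalue), "t-test")
                else:
                    tr = mann_whitney(arrs[0], arrs[1])
                summaries = tuple(_summary_string(g, normal) for g in arrs)
            else:
                normal = False
                tr = TestResult(float("nan"), float("nan"), "none", note="too few observations")
                summaries = tuple(
                    _summary_string(g, False) if g.size else "-" for g in arrs
                )
        else:
            # categorical: 2x2 table of level x group
            cats = col.dropna().unique()
            if testable and len(cats) == 2:
                table = [
                    [int((g == cats[0]).sum()), int((g == cats[1]).sum())] for g in groups
                ]
                tr = chi_square_2x2(table)
            else:
                tr = TestResult(float("nan"), float("nan"), "none", note="not a 2x2 table")
            summaries = tuple(
                "/".join(str(int((g == c).sum())) for c in cats) for g in groups
            )

        sig = None if not np.isfinite(tr.p_value) else bool(tr.p_value <= alpha)
        out.append(
            GroupComparison(
                variable=str(var),
                group_labels=tuple(str(lv) for lv in levels),
                summaries=summaries,
                test=tr.test,
                statistic=tr.statistic,
                p_value=tr.p_value,
                significant=sig,
            )
        )
    return out


def comparisons_to_frame(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    """Render a list of comparisons as a tidy DataFrame."""
    return pd.DataFrame([r.to_dict() for r in rows])
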