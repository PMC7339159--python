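"""Representativeness testing: tested vs not-tested cohort comparison.

Checks whether the subset of patients whose samples entered a bridging
study is demographically representative of the eligible population:
continuous baseline variables are compared with a two-group t-test
(pooled-variance by default, Welch by flag) and categorical variables with
Pearson's chi-square test without continuity correction.  Variables with
p below the significance level are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "CategoryTable",
    "TestResult",
    "two_group_t",
    "chi_square",
    "representativeness_report",
    "report_from_summaries",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group for a continuous variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class CategoryTable:
    """k x 2 category counts (columns: tested, not tested).

    Categories with zero total across both groups must be dropped before
    construction; categories present in only one group are retained.
    """

    categories: tuple[str, ...]
    counts: np.ndarray  # shape (k, 2), nonnegative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
            raise ValueError("counts must be k x 2 with k >= 2")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("drop categories with zero total across both groups")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float


def two_group_t(
    summary_a: GroupSummary, summary_b: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Two-sided two-group t-test from group summaries.

    ``pooled`` uses the pooled-variance statistic with df = n_a + n_b - 2;
    ``welch`` uses Satterthwaite degrees of freedom.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if summary_a.sd == 0 and summary_b.sd == 0 and summary_a.mean == summary_b.mean:
        raise ValueError("degenerate input: both groups constant and equal")
    res = stats.ttest_ind_from_stats(
        summary_a.mean, summary_a.sd, summary_a.n,
        summary_b.mean, summary_b.sd, summary_b.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = summary_a.n + summary_b.n - 2
    else:  # Satterthwaite
        va, vb = summary_a.sd**2 / summary_a.n, summary_b.sd**2 / summary_b.n
        df = (va + vb) ** 2 / (va**2 / (summary_a.n - 1) + vb**2 / (summary_b.n - 1))
    return TestResult(float(res.statistic), float(df), float(res.pvalue))


def chi_square(table: CategoryTable) -> TestResult:
    """Pearson chi-square test of homogeneity, no continuity correction.

    df = k - 1 for a k x 2 table; raises when any expected count is zero
    (a group with no observations).
    """
    counts = table.counts
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise ValueError("expected count of zero; check group totals")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(chi2), float(df), float(p))


def _category_table(tested: pd.Series, not_tested: pd.Series) -> CategoryTable:
    cats = sorted(set(tested.dropna()) | set(not_tested.dropna()))
    counts = np.column_stack([
        tested.value_counts().reindex(cats, fill_value=0).to_numpy(),
        not_tested.value_counts().reindex(cats, fill_value=0).to_numpy(),
    ])
    keep = counts.sum(axis=1) > 0
    return CategoryTable(tuple(np.array(cats)[keep]), counts[keep])


def representativeness_report(
    demographics: pd.DataFrame,
    continuous: Sequence[str] = ("age", "tumor_area", "viable_cells"),
    categorical: Sequence[str] = ("sex", "race", "ethnicity", "region", "site"),
    group_col: str = "tested",
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> pd.DataFrame:
    """Per-variable comparison of tested vs not-tested patients.

    Returns one row per variable: test used, statistic, df, p and a
    significance flag (p < alpha).  Unknown variables raise.
    """
    known = set(continuous) | set(categorical)
    missing = known - set(demographics.columns)
    if missing:
        raise ValueError(f"variables not in demographics table: {sorted(missing)}")
    grp = demographics[group_col].astype(bool)
    tested, not_tested = demographics[grp], demographics[~grp]
    rows = []
    for var in list(continuous) + list(categorical):
        if var in continuous:
            a = tested[var].dropna().astype(float)
            b = not_tested[var].dropna().astype(float)
            res = two_group_t(
                GroupSummary(len(a), a.mean(), a.std(ddof=1)),
                GroupSummary(len(b), b.mean(), b.std(ddof=1)),
                variant=t_variant,
            )
            test = f"t ({t_variant})"
        else:
            res = chi_square(_category_table(tested[var], not_tested[var]))
            test = "chi-square"
        rows.append({
            "variable": var, "test": test, "statistic": res.statistic,
            "df": res.df, "p": res.p, "significant": res.p < alpha,
        })
    return pd.DataFrame(rows)


def report_from_summaries(
    continuous: Mapping[str, tuple[GroupSummary, GroupSummary]],
    categorical: Mapping[str, CategoryTable],
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> pd.DataFrame:
    """Same report computed from pre-summarised inputs (published tables
    often print only group means/SDs and category counts)."""
    rows = []
    for var, (a, b) in continuous.items():
        res = two_group_t(a, b, variant=t_variant)
        rows.append({"variable": var, "test": f"t ({t_variant})",
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "significant": res.p < alpha})
    for var, table in categorical.items():
        res = chi_square(table)
        rows.append({"variable": var, "test": "chi-square",
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "significant": res.p < alpha})
    return pd.DataFrame(rows)
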