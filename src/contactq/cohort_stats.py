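"""Cohort pooling and group comparison of per-mitochondrion contact metrics.

The experimental unit is the mitochondrion: metrics from all cells of a
group are pooled ("all data points included"), summarized as mean ± s.e.m.,
and two groups are compared with a two-tailed unpaired t-test (Student's
pooled-variance by default; Welch's available).  A per-cell aggregation
mode exists for sensitivity analyses but is off by default, matching the
pooled design of the source experiment (tens of mitochondria across a
handful of cells per genotype).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class CohortError(ValueError):
    """Cohort table violates the comparison contract."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    test: str  # "student" or "welch"


def _group_values(table: pd.DataFrame, metric: str, group_col: str,
                  group: str, *, per_cell: bool = False,
                  cell_col: str = "cell_id") -> np.ndarray:
    if metric not in table.columns:
        raise CohortError(f"metric column {metric!r} not in table")
    if group_col not in table.columns:
        raise CohortError(f"group column {group_col!r} not in table")
    sub = table[table[group_col] == group]
    if sub.empty:
        raise CohortError(f"group {group!r} has no rows")
    if per_cell:
        sub = sub.groupby(cell_col, as_index=False)[metric].mean()
    values = sub[metric].to_numpy(float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("group %s, metric %s: excluded %d missing value(s)",
                    group, metric, n_missing)
    return values[~np.isnan(values)]


def summarize_groups(table: pd.DataFrame, metric: str,
                     group_col: str = "group", *,
                     per_cell: bool = False) -> pd.DataFrame:
    """Per-group n, mean and s.e.m. of a metric.

    Missing values (e.g. the undefined average distance of a zero-contact
    mitochondrion) are excluded and counted.  s.e.m. uses the sample
    standard deviation (n − 1 denominator) divided by √n.
    """
    rows = []
    for group in pd.unique(table[group_col]) if group_col in table.columns else ():
        values = _group_values(table, metric, group_col, group, per_cell=per_cell)
        n = len(values)
        if n < 2:
            raise CohortError(f"group {group!r}: n = {n} < 2 after exclusions")
        n_total = int((table[group_col] == group).sum())
        rows.append({
            "group": group,
            "n": n,
            "n_missing": (n_total - n) if not per_cell else np.nan,
            "mean": float(values.mean()),
            "sem": float(values.std(ddof=1) / math.sqrt(n)),
        })
    if not rows:
        raise CohortError(f"group column {group_col!r} not in table")
    return pd.DataFrame(rows)


def compare_groups(table: pd.DataFrame, metric: str, group_a: str, group_b: str,
                   group_col: str = "group", *, test: str = "student",
                   per_cell: bool = False) -> TTestResult:
    """Two-tailed unpaired t-test between two groups of a cohort table.

    ``test="student"`` uses the pooled-variance test (the default reading of
    an unqualified "unpaired t-test"); ``test="welch"`` drops the equal
    variance assumption.  Degenerate inputs: zero variance in both groups
    with equal means gives t = 0, p = 1 by convention; with unequal means it
    is an error (the test statistic is undefined).
    """
    if test not in {"student", "welch"}:
        raise CohortError(f"unknown test {test!r}")
    a = _group_values(table, metric, group_col, group_a, per_cell=per_cell)
    b = _group_values(table, metric, group_col, group_b, per_cell=per_cell)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs n >= 2 non-missing values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = (len(a) + len(b) - 2) if test == "student" else float("nan")
            return TTestResult(0.0, float(df), 1.0, test)
        raise CohortError("zero variance in both groups with unequal means: "
                          "t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), test)
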