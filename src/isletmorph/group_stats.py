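"""Two-group inference for per-donor morphometric metrics.

Three tests cover the comparisons made on islet morphometry cohorts:

* a pooled-variance two-sided Student's t-test (optionally reconstructed
  from printed ``mean +/- SEM, n`` summaries),
* the two-sided Mann-Whitney U test for non-normal metrics,
* the two-sided Fisher exact test for 2x2 categorical tables.

Under the default ``"auto"`` policy each group is screened with the
Shapiro-Wilk test at alpha = 0.05; the t-test is used only when neither
group rejects normality, otherwise Mann-Whitney.  No multiplicity
correction is applied across metrics: each comparison is reported with
its own two-sided p and a significance flag at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "ttest_from_summary",
    "fisher_exact_2x2",
    "cohort_report",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    metric: str
    test: str  # student_t | mann_whitney
    statistic: float
    df: float | None
    p: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    significant: bool


def _summaries(x: np.ndarray) -> tuple[float, float, int]:
    n = len(x)
    sem = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return float(np.mean(x)), sem, n


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:  # Shapiro-Wilk needs n >= 3 and spread
        return False
    return stats.shapiro(x).pvalue >= alpha


def compare_groups(
    x,
    y,
    policy: str = "auto",
    metric: str = "",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare two samples with the test selected by ``policy``.

    ``policy="auto"`` routes to the pooled t-test when both groups pass
    Shapiro-Wilk at alpha = 0.05 and to Mann-Whitney otherwise;
    ``"force_t"`` / ``"force_mw"`` override the gate.  Mann-Whitney is
    exact for small tie-free samples and uses the midrank normal
    approximation otherwise (scipy's automatic selection).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing observations")
    if policy not in ("auto", "force_t", "force_mw"):
        raise ValueError(f"unknown policy {policy!r}")

    use_t = policy == "force_t" or (
        policy == "auto" and _is_normal(x) and _is_normal(y)
    )
    if use_t:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate: no variance at all
            statistic = 0.0 if np.mean(x) == np.mean(y) else math.inf
            p = 1.0 if np.mean(x) == np.mean(y) else 0.0
        else:
            res = stats.ttest_ind(x, y, equal_var=True)
            statistic, p = float(res.statistic), float(res.pvalue)
        test, df = "student_t", float(len(x) + len(y) - 2)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        statistic, p = float(res.statistic), float(res.pvalue)
        test, df = "mann_whitney", None

    mean_a, sem_a, n_a = _summaries(x)
    mean_b, sem_b, n_b = _summaries(y)
    return ComparisonResult(
        metric=metric,
        test=test,
        statistic=statistic,
        df=df,
        p=p,
        mean_a=mean_a,
        sem_a=sem_a,
        n_a=n_a,
        mean_b=mean_b,
        sem_b=sem_b,
        n_b=n_b,
        significant=p < alpha,
    )


def ttest_from_summary(
    mean1: float,
    sem1: float,
    n1: int,
    mean2: float,
    sem2: float,
    n2: int,
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test from ``mean +/- SEM, n`` summaries.

    Returns ``(t, df, p)`` with ``t = (mean1 - mean2)/sqrt(sem1^2 + sem2^2)``
    and ``df = n1 + n2 - 2``.  For equal group sizes this equals the
    pooled-variance Student's t-test, which makes printed group summaries
    sufficient to reconstruct the test exactly.
    """
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = float(n1 + n2 - 2)
    denom = math.hypot(sem1, sem2)
    if denom == 0:
        # zero sampling variance: equal means are indistinguishable (p = 1),
        # unequal means are a p -> 0 limit
        return (0.0, df, 1.0) if mean1 == mean2 else (math.inf, df, 0.0)
    t = (mean1 - mean2) / denom
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``[[a, b], [c, d]]``.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  An all-zero table carries no information: p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def cohort_report(
    table: pd.DataFrame,
    metrics: list[str],
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    policy: str = "auto",
) -> pd.DataFrame:
    """One two-group comparison per metric over a per-donor cohort table.

    ``table`` holds one row per donor with a ``group_col`` column and one
    column per metric.  ``groups`` names the two levels to compare (first
    vs second); by default the two levels found in the table, in sorted
    order.  Returns a tidy frame with one row per metric.
    """
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise KeyError(f"metric column(s) not in cohort table: {missing}")
    if groups is None:
        levels = sorted(table[group_col].unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, found {levels}")
        groups = (levels[0], levels[1])
    ga, gb = groups
    xa = table.loc[table[group_col] == ga]
    xb = table.loc[table[group_col] == gb]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError(f"empty group in comparison {ga!r} vs {gb!r}")

    rows = []
    for metric in metrics:
        r = compare_groups(
            xa[metric].to_numpy(), xb[metric].to_numpy(), policy=policy, metric=metric
        )
        rows.append(
            {
                "metric": metric,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                f"mean_{ga}": r.mean_a,
                f"sem_{ga}": r.sem_a,
                f"n_{ga}": r.n_a,
                f"mean_{gb}": r.mean_b,
                f"sem_{gb}": r.sem_b,
                f"n_{gb}": r.n_b,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
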