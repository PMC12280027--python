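"""Differential protein abundance with an S0-moderated statistic and
permutation-estimated FDR.

The per-protein statistic is the SAM-style moderated two-sample statistic

    d = (mean_a - mean_b) / (s + s0)

where ``s`` is the pooled two-sample standard error and ``s0`` a small
positive constant that damps proteins whose tiny variance would otherwise
inflate an ordinary t statistic.  The null distribution of ``d`` is built
by permuting group labels; each protein's FDR (q-value) is the median,
over permutations, of the number of permuted statistics at least as
extreme as the protein's |d|, divided by the number of observed
statistics at least that extreme, clipped to [0, 1] and monotonised along
the |d| ranking.  A protein is classed ``up`` or ``down`` when q < 0.05,
with the direction given by the sign of its log2 fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ProteinMatrix",
    "prepare_matrix",
    "s0_statistic",
    "permutation_fdr",
    "volcano_table",
]

logger = logging.getLogger(__name__)

DEFAULT_S0 = 0.01
DEFAULT_N_PERMUTATIONS = 250
DEFAULT_FDR = 0.05


@dataclass
class ProteinMatrix:
    """Log2 intensity matrix (proteins x samples) with sample group labels."""

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.data.columns]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def prepare_matrix(
    raw: pd.DataFrame,
    groups: pd.Series | dict,
    compare: tuple[str, str],
    log_transform: bool = True,
) -> ProteinMatrix:
    """Log2-transform raw intensities and apply the completeness filter.

    Proteins with any missing value in either compared group are dropped
    (strict per-group completeness, no imputation); the number of dropped
    rows is logged.  Non-positive raw intensities are treated as missing
    before the log transform.
    """
    groups = pd.Series(groups)
    ga, gb = compare
    for g in compare:
        n = int((groups == g).sum())
        if n < 2:
            raise ValueError(f"group {g!r} has {n} samples; need >= 2")
    data = raw.astype(float)
    if log_transform:
        data = data.where(data > 0)
        data = np.log2(data)
    cols = [s for s in data.columns if groups.get(s) in compare]
    complete = data[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "completeness filter dropped %d of %d proteins", n_dropped, len(data)
        )
    return ProteinMatrix(data=data.loc[complete], groups=groups)


def _pooled_se(va: np.ndarray, vb: np.ndarray, na: int, nb: int) -> np.ndarray:
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def s0_statistic(group_a, group_b, s0: float = DEFAULT_S0) -> tuple[float, float]:
    """Moderated statistic and log2 fold change for one protein.

    Returns ``(d, log2fc)`` with ``d = (mean_a - mean_b)/(s + s0)`` where
    ``s`` is the pooled two-sample standard error; with ``s0 = 0`` this is
    the ordinary pooled t statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    log2fc = float(a.mean() - b.mean())
    s = float(_pooled_se(a.var(ddof=1), b.var(ddof=1), len(a), len(b)))
    if s + s0 == 0:
        raise ZeroDivisionError(
            "zero variance in both groups with s0 = 0; use a positive s0"
        )
    return log2fc / (s + s0), log2fc


def _d_vector(X: np.ndarray, in_a: np.ndarray, s0: float) -> np.ndarray:
    """Moderated statistic for every protein (row of X) at one labelling."""
    na = int(in_a.sum())
    nb = X.shape[1] - na
    A = X[:, in_a]
    B = X[:, ~in_a]
    diff = A.mean(axis=1) - B.mean(axis=1)
    s = _pooled_se(A.var(axis=1, ddof=1), B.var(axis=1, ddof=1), na, nb)
    return diff / (s + s0)


def permutation_fdr(
    matrix: ProteinMatrix,
    group_a: str,
    group_b: str,
    s0: float = DEFAULT_S0,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-protein differential abundance with permutation FDR.

    Returns a frame indexed by protein with columns ``log2fc``, ``d``,
    ``q``, ``minus_log10_fdr`` and ``class`` (``up``/``down``/``ns`` at
    the chosen ``fdr`` threshold, default 0.05).

    Null statistics come from relabelling the samples of the two compared
    groups: when the number of distinct assignments C(n, n_a) does not
    exceed ``n_permutations`` all of them are used exactly (and logged),
    otherwise ``n_permutations`` assignments are drawn with a seeded
    generator.  For the -log10 FDR, q is floored at 1/(P * n_proteins)
    (one permuted statistic in the whole null ensemble of P permutations)
    so that proteins never exceeded by any permuted statistic plot at a
    large finite height instead of infinity.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    # keep the matrix's own column order so that the permutation ensemble
    # is identical whichever group is named first (label-swap symmetry)
    cols = [s for s in matrix.data.columns if matrix.groups[s] in (group_a, group_b)]
    observed_in_a = np.array([matrix.groups[s] == group_a for s in cols])
    na = int(observed_in_a.sum())
    nb = len(cols) - na
    if na < 2 or nb < 2:
        raise ValueError("each compared group needs >= 2 samples")
    X = matrix.data[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "matrix has missing values in the compared groups; run prepare_matrix"
        )
    d_obs = _d_vector(X, observed_in_a, s0)

    # permuted subsets are drawn for the lexicographically first group, so
    # the ensemble does not depend on the order the groups are named in
    first_is_a = group_a == min(group_a, group_b)
    n0 = na if first_is_a else nb
    n_total = math.comb(len(cols), n0)
    assignments: list[np.ndarray] = []
    if n_total <= n_permutations:
        logger.info(
            "only %d distinct label assignments exist (requested %d); using all",
            n_total,
            n_permutations,
        )
        subsets = combinations(range(len(cols)), n0)
    else:
        rng = np.random.default_rng(seed)
        subsets = (
            rng.choice(len(cols), size=n0, replace=False)
            for _ in range(n_permutations)
        )
    for idx in subsets:
        in_first = np.zeros(len(cols), dtype=bool)
        in_first[list(idx)] = True
        assignments.append(in_first if first_is_a else ~in_first)

    # counts of |null d| >= |observed d| per permutation, via searchsorted
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs)[::-1]  # descending |d|
    sorted_abs = abs_obs[order]
    fp = np.empty((len(assignments), len(d_obs)))
    for p_idx, in_a in enumerate(assignments):
        null_abs = np.sort(np.abs(_d_vector(X, in_a, s0)))
        # number of null stats >= threshold, for each observed threshold
        fp[p_idx] = len(null_abs) - np.searchsorted(null_abs, sorted_abs, side="left")
    median_fp = np.median(fp, axis=0)
    n_called = np.arange(1, len(d_obs) + 1)  # observed stats >= each threshold
    q_sorted = np.clip(median_fp / n_called, 0.0, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone non-increasing in |d|

    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    q_floor = 1.0 / (len(assignments) * max(len(d_obs), 1))
    minus_log10 = -np.log10(np.maximum(q, q_floor))
    log2fc = X[:, observed_in_a].mean(axis=1) - X[:, ~observed_in_a].mean(axis=1)
    cls = np.where(
        q < fdr, np.where(log2fc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "d": d_obs,
            "q": q,
            "minus_log10_fdr": minus_log10,
            "class": cls,
        },
        index=matrix.data.index,
    )


def volcano_table(diff: pd.DataFrame, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Tidy volcano-plot table: protein, log2fc, -log10 FDR, class.

    The class boundary is strict: a protein sitting exactly at
    q = ``fdr`` (-log10 q ~ 1.3 for the default 0.05) is ``ns``.
    """
    out = diff.reset_index(names="protein")[
        ["protein", "log2fc", "minus_log10_fdr"]
    ].copy()
    q = diff["q"].to_numpy()
    log2fc = diff["log2fc"].to_numpy()
    out["class"] = np.where(q < fdr, np.where(log2fc > 0, "up", "down"), "ns")
    return out
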