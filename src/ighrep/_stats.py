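"""Shared statistical helpers (rank-sum test, multiple-testing adjustment)."""

from __future__ import annotations

from itertools import combinations
from typing import Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: both groups at or below this size -> exact enumeration with midranks
EXACT_MAX_N = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    sample. When both groups have at most :data:`EXACT_MAX_N` observations
    the null distribution is enumerated exactly over all group assignments
    using midranks (so ties are handled correctly and identical groups give
    p = 1); otherwise the normal approximation with tie correction is used,
    without the continuity correction (which over-corrects and leaves the
    test noticeably conservative at the cohort's group sizes).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both groups must be non-empty")
    if nx <= EXACT_MAX_N and ny <= EXACT_MAX_N:
        return _exact_rank_sum(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    center = nx * ny / 2.0
    dev_obs = abs(u_obs - center) - 1e-12
    n = nx + ny
    hits = 0
    total = 0
    rank_arr = np.asarray(ranks)
    base = nx * (nx + 1) / 2.0
    for idx in combinations(range(n), nx):
        u = rank_arr[list(idx)].sum() - base
        if abs(u - center) >= dev_obs:
            hits += 1
        total += 1
    return float(u_obs), hits / total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
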