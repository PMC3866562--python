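"""Shared statistical primitives.

The rank-sum test switches between exact enumeration (both samples small)
and the tie-corrected normal approximation; multiple-testing corrections
wrap statsmodels.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_EXACT_MAX = 8  # enumerate all rank configurations when both samples <= this


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled
    ranking (average ranks for ties).  When both samples have at most
    8 observations the p-value is computed by exact enumeration of all
    C(n+m, n) group assignments of the pooled values (ties handled
    naturally); otherwise the normal approximation with tie correction
    and continuity correction is used.

    ``alternative``: "two-sided", "greater" (x tends larger) or "less".
    The two-sided exact p doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n].sum())

    if n <= _EXACT_MAX and m <= _EXACT_MAX:
        total = 0
        ge = 0
        le = 0
        eps = 1e-9
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            total += 1
            if w >= w_obs - eps:
                ge += 1
            if w <= w_obs + eps:
                le += 1
        p_greater = ge / total
        p_less = le / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return w_obs, p

    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return w_obs, float(res.pvalue)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
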