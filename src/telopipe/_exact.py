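"""Exact null distributions for the two Wilcoxon tests.

Small-sample branches of the signed-rank and rank-sum tests, computed by
dynamic programming over the full permutation null rather than a normal
approximation. Both null distributions used here are symmetric about
their mean, so the two-sided p-value is defined symmetrically:

    p = P( |T - mu| >= |t_obs - mu| )

which for the textbook no-ties cases coincides with doubling the smaller
tail. The signed-rank DP works on doubled mid-ranks (integers even under
ties); the rank-sum exact branch is only entered when the pooled sample
is tie-free, where the subset-sum null is symmetric.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Largest number of informative pairs for which the signed-rank null is
#: enumerated exactly.
SIGNED_RANK_EXACT_N = 25
#: Largest pooled sample size for which the rank-sum null is enumerated
#: exactly (tie-free inputs only).
RANK_SUM_EXACT_N = 20


def _subset_sum_counts(weights: np.ndarray) -> np.ndarray:
    """Counts of subsets of ``weights`` by total, over all 2**n subsets."""
    total = int(weights.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in weights:
        w = int(w)
        if w == 0:
            counts *= 2.0
        else:
            counts[w:] += counts[: total + 1 - w].copy()
    return counts


def _symmetric_two_sided_p(counts: np.ndarray, observed: float) -> float:
    support = np.arange(counts.size, dtype=float)
    mu = float((support * counts).sum() / counts.sum())
    dev = abs(observed - mu)
    # tolerance guards half-integer deviations represented in floats
    mask = np.abs(support - mu) >= dev - 1e-9
    return float(counts[mask].sum() / counts.sum())


def signed_rank_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test.

    Zero differences must already be removed. Ties in |d| are handled
    with mid-ranks; the null enumerates all 2**n sign assignments via a
    subset-sum DP on doubled ranks. Returns (W_plus, p).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    doubled = np.rint(2.0 * ranks).astype(int)
    counts = _subset_sum_counts(doubled)
    p = _symmetric_two_sided_p(counts, 2.0 * w_plus)
    return w_plus, min(1.0, p)


def _ranksum_counts(n_total: int, n_group: int) -> np.ndarray:
    """Counts of rank-sums over all size-``n_group`` subsets of 1..n_total."""
    max_sum = n_group * n_total
    dp = np.zeros((n_group + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_group), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n_group]


def rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum test for tie-free pooled samples.

    Returns (W, p) where W is the rank sum of ``x`` within the pooled
    ranking. The null is the hypergeometric shuffle of group labels,
    enumerated by DP over subset rank-sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("exact rank-sum branch requires tie-free data")
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    counts = _ranksum_counts(pooled.size, x.size)
    p = _symmetric_two_sided_p(counts, w)
    return w, min(1.0, p)
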