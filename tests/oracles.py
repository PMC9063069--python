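"""Brute-force reference implementations used only as test oracles.

These deliberately re-derive each decision from first principles —
enumeration or the bare formula — independent of the package's own
(DP- or vectorization-based) code paths.
"""

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def dixon_decision(values, crit=0.970):
    """Removal decision straight from the Q formula, no shared code."""
    v = sorted(values)
    rng = v[2] - v[0]
    if rng == 0:
        return None
    gap_hi = v[2] - v[1]
    gap_lo = v[1] - v[0]
    if gap_hi >= gap_lo:
        q, suspect_value = gap_hi / rng, v[2]
    else:
        q, suspect_value = gap_lo / rng, v[0]
    if q > crit:
        return list(values).index(suspect_value)
    return None


def signed_rank_p_enumeration(diffs):
    """Two-sided signed-rank p by enumerating all 2**n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - total / 2.0)
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2.0) >= dev - 1e-9:
            hits += 1
    return hits / 2**n


def rank_sum_p_enumeration(x, y):
    """Two-sided rank-sum p by enumerating all C(n+m, n) labelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, total_n = x.size, pooled.size
    mu = n * (total_n + 1) / 2.0
    w_obs = ranks[:n].sum()
    dev = abs(w_obs - mu)
    hits = 0
    count = 0
    for idx in combinations(range(total_n), n):
        w = ranks[list(idx)].sum()
        count += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / count


def closest_pair(values):
    """Indices of the closest pair by brute-force pairwise distances."""
    best = None
    for i, j in combinations(range(len(values)), 2):
        d = abs(values[i] - values[j])
        if best is None or d < best[0]:
            best = (d, (i, j))
    return best[1]


def spearman_edge_counts(data, thin=0.3, thick=0.7):
    """Thin/thick edge counts over all feature pairs of the Spearman matrix."""
    cols = list(data.columns)
    ranked = np.column_stack([rankdata(data[c].to_numpy()) for c in cols])
    n_thin = n_thick = 0
    for i, j in combinations(range(len(cols)), 2):
        r = np.corrcoef(ranked[:, i], ranked[:, j])[0, 1]
        if abs(r) >= thick:
            n_thick += 1
        elif abs(r) >= thin:
            n_thin += 1
    return n_thin, n_thick
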