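"""Shared rank-based two-sample tests.

The trajectory-comparison and docking-score modules both report a two-sided
Mann-Whitney U p-value. For small groups (n <= 8 per side) the exact null
distribution of U is enumerated over all assignments of the pooled midranks,
which stays correct in the presence of ties; larger groups use the normal
approximation with continuity and tie correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

EXACT_MAX_N = 8  # per-group cutoff for exact enumeration


def _u_statistic(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value for two independent samples.

    Exact (full enumeration over C(n_x+n_y, n_x) rank assignments, midranks
    for ties) when both groups have at most ``EXACT_MAX_N`` observations;
    otherwise scipy's asymptotic path (continuity + tie correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")
    n_x, n_y = x.size, y.size
    if n_x <= EXACT_MAX_N and n_y <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)  # midranks
        u_obs = _u_statistic(ranks[:n_x], n_x, n_y)
        mu = n_x * n_y / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        idx = range(n_x + n_y)
        for combo in combinations(idx, n_x):
            u = _u_statistic(ranks[list(combo)], n_x, n_y)
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def ks_2sample_p(x, y) -> float:
    """Two-sided, asymptotic two-sample Kolmogorov-Smirnov p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    return float(stats.ks_2samp(x, y, method="asymp").pvalue)
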