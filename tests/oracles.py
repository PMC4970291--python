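"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity along a route deliberately
different from the implementation under test: plain dynamic programming
instead of edlib, from-scratch average-distance recomputation instead
of Lance-Williams updates, normal equations instead of scipy, and an
explicit tricube-weighted fit instead of statsmodels.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np


def unit_edit_distance(a: str, b: str) -> int:
    """Textbook Levenshtein DP (substitution/insertion/deletion cost 1)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def average_linkage_partition(
    D: np.ndarray, cutoff: float
) -> Set[FrozenSet[int]]:
    """Naive average-neighbour clustering: at each step recompute every
    inter-cluster average distance directly from the original matrix,
    merge the smallest pair (ties to the lexicographically smallest
    representative pair) while it is <= cutoff."""
    clusters: List[List[int]] = [[i] for i in range(len(D))]
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = float(
                    np.mean([D[i, j] for i in clusters[x] for j in clusters[y]])
                )
                key = (d, min(clusters[x] + clusters[y]), max(min(clusters[x]), min(clusters[y])))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _, _), x, y = best
        if d > cutoff:
            break
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return {frozenset(c) for c in clusters}


def ols_normal_equations(points: np.ndarray) -> Tuple[float, float, float]:
    """(slope, intercept, r^2) by explicitly solving the normal equations."""
    x, y = points[:, 0], points[:, 1]
    X = np.vstack([x, np.ones_like(x)]).T
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(beta[0]), float(beta[1]), r2


def tricube_weighted_line(points: np.ndarray, x0: float) -> float:
    """Weighted linear fit at x0 with tricube weights over all points
    (the frac=1, zero-robustifying-iterations limit of lowess)."""
    x, y = points[:, 0], points[:, 1]
    d = np.abs(x - x0)
    dmax = d.max()
    w = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
    X = np.vstack([np.ones_like(x), x]).T
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return float(beta[0] + beta[1] * x0)


def hypergeometric_mean(count: int, total: int, depth: int) -> float:
    """Expected subsampled count of a sequence under rarefaction."""
    return depth * count / total
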