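"""Independent brute-force reference computations used as test oracles.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Elementwise pairwise Pearson correlations, explicit loops."""
    p = X.shape[1]
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = pearson(X[:, i], X[:, j])
    return out


def bh_stepup(p: list[float]) -> list[float]:
    """Hand-stepped Benjamini–Hochberg adjusted p-values."""
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        running_min = min(running_min, p[k] * m / rank)
        adj[k] = running_min
    return [min(a, 1.0) for a in adj]


def average_linkage_trace(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive UPGMA: merge the closest pair; inter-cluster distance = mean of
    all cross pairs; ties by first pair in scan order. Returns the merge
    list as (members_a, members_b, height)."""
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], float(d)))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def cophenetic_from_trace(n: int, merges) -> np.ndarray:
    """Cophenetic distance matrix from a naive merge trace."""
    out = np.zeros((n, n))
    for a, b, h in merges:
        for i in a:
            for j in b:
                out[i, j] = out[j, i] = h
    return out


def kgs_penalty_curve(assignments_by_k: dict[int, np.ndarray], dist: np.ndarray,
                      n_leaves: int, alpha: float = 1.0):
    """Exhaustive KGS evaluation from precomputed flat cuts."""
    ks = sorted(assignments_by_k)
    spreads = []
    for k in ks:
        assign = assignments_by_k[k]
        per_cluster = []
        for c in set(assign):
            members = [i for i in range(len(assign)) if assign[i] == c]
            if len(members) >= 2:
                ds = [dist[i, j] for ai, i in enumerate(members) for j in members[ai + 1:]]
                per_cluster.append(float(np.mean(ds)))
        spreads.append(float(np.mean(per_cluster)) if per_cluster else 0.0)
    lo, hi = min(spreads), max(spreads)
    rescaled = [1.0 + (s - lo) * (n_leaves - 2) / (hi - lo) for s in spreads]
    penalties = [alpha * r + k for r, k in zip(rescaled, ks)]
    best = ks[int(np.argmin(penalties))]
    return ks, penalties, best
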