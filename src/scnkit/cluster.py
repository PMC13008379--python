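"""Hierarchical clustering of thalamic nuclei by their SC_diff profiles.

Each nucleus is represented by its row of the case-minus-control structural
covariance difference matrix (its "perturbation profile"); nuclei whose
profiles look alike are presumed similarly affected. Profiles are compared
by correlation distance (1 − r), clustered with unweighted average linkage,
and the number of clusters is chosen by the Kelley–Gardner–Sutcliffe (KGS)
penalty with alpha = 1: the mean within-cluster spread at each cut is
linearly rescaled across cuts onto [1, L − 1] and added to the cluster
count; the cut minimizing the sum wins. Pairs of clusterings (e.g.
intrathalamic vs thalamocortical) are compared by the correlation of their
cophenetic distance matrices; the tanglegram-style leaf pairing is exported
as a table rather than a figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .stats import SCDiff

__all__ = [
    "Dendrogram",
    "KGSSelection",
    "profile_distance",
    "average_linkage",
    "kgs_optimal_k",
    "cophenetic_correlation",
    "cluster_pairing_export",
    "SCDiffClustering",
]


def profile_distance(
    scdiff: SCDiff,
    leaves: list[str],
    columns: list[str] | None = None,
    metric: str = "correlation",
) -> tuple[np.ndarray, list[str]]:
    """Distance matrix between leaves' SC_diff profiles.

    A leaf's profile is its SC_diff row restricted to ``columns`` (default:
    all network nodes), with self-entries excluded pairwise. Correlation
    distance 1 − r (range [0, 2]) by default; Euclidean by config.
    """
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves to cluster")
    cols = columns if columns is not None else list(scdiff.labels)
    li = [scdiff.labels.index(l) for l in leaves]
    ci = [scdiff.labels.index(c) for c in cols]
    profiles = scdiff.matrix[np.ix_(li, ci)]
    # self-columns would pin a structural zero into the profile
    leaf_in_cols = {l: cols.index(l) for l in leaves if l in cols}
    n = len(leaves)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            keep = np.ones(len(cols), dtype=bool)
            for l in (leaves[a], leaves[b]):
                if l in leaf_in_cols:
                    keep[leaf_in_cols[l]] = False
            pa, pb = profiles[a, keep], profiles[b, keep]
            if metric == "correlation":
                sa, sb = pa.std(), pb.std()
                if sa == 0 or sb == 0:
                    bad = leaves[a] if sa == 0 else leaves[b]
                    raise ValueError(f"constant SC_diff profile for leaf {bad!r}")
                d = 1.0 - np.corrcoef(pa, pb)[0, 1]
            elif metric == "euclidean":
                d = float(np.linalg.norm(pa - pb))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            dist[a, b] = dist[b, a] = d
    return dist, list(leaves)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labeled leaves.

    Wraps a SciPy linkage matrix: row m merges clusters Z[m,0] and Z[m,1]
    at height Z[m,2]. Heights are non-decreasing (average linkage on a
    metric is monotone).
    """

    labels: list[str]
    Z: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster assignment (0..k-1) at exactly k clusters."""
        return cut_tree(self.Z, n_clusters=k).reshape(-1)

    def cophenetic_matrix(self) -> np.ndarray:
        """Square matrix of heights at which leaf pairs first merge."""
        return squareform(cophenet(self.Z))

    def merge_list(self) -> list[dict]:
        return [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.Z
        ]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differentials."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for m, (a, b, h, _s) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = f"{node[a]}:{h - height[a]:.10g}"
            lb = f"{node[b]}:{h - height[b]:.10g}"
            node[n + m] = f"({la},{lb})"
            height[n + m] = h
        return node[n + self.Z.shape[0] - 1] + ";"


def average_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration of a distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(labels) != dist.shape[0]:
        raise ValueError("label count does not match distance matrix")
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=list(labels), Z=Z)


@dataclass
class KGSSelection:
    """KGS penalty curve and the selected cluster count."""

    alpha: float
    ks: np.ndarray
    spreads: np.ndarray
    rescaled_spreads: np.ndarray
    penalties: np.ndarray
    k: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "spread": self.spreads,
                "rescaled_spread": self.rescaled_spreads,
                "penalty": self.penalties,
            }
        )


def kgs_optimal_k(dend: Dendrogram, dist: np.ndarray, alpha: float = 1.0) -> KGSSelection:
    """Kelley–Gardner–Sutcliffe cluster-count selection.

    For each cut into k in [2, L−1] clusters: spread(k) = mean, over
    clusters with >= 2 members, of their mean pairwise distance; spreads are
    linearly rescaled across cuts onto [1, L−1]; penalty(k) =
    alpha * rescaled_spread(k) + k; the smallest k attaining the minimum is
    selected. Degenerate rescaling (all spreads equal) falls back to k = 2
    with a warning.
    """
    L = dend.n_leaves
    if L < 4:
        raise ValueError("KGS selection needs at least 4 leaves")
    dist = np.asarray(dist, dtype=float)
    ks = np.arange(2, L)
    spreads = np.empty(len(ks))
    for idx, k in enumerate(ks):
        assign = dend.cut(int(k))
        cluster_means = []
        for c in np.unique(assign):
            members = np.nonzero(assign == c)[0]
            if len(members) >= 2:
                sub = dist[np.ix_(members, members)]
                cluster_means.append(sub[np.triu_indices(len(members), 1)].mean())
        spreads[idx] = np.mean(cluster_means) if cluster_means else 0.0
    lo, hi = spreads.min(), spreads.max()
    if hi == lo:
        warn("all KGS spreads identical; falling back to k = 2")
        rescaled = np.ones_like(spreads)
        penalties = alpha * rescaled + ks
        return KGSSelection(alpha, ks, spreads, rescaled, penalties, 2)
    rescaled = 1.0 + (spreads - lo) * (L - 2) / (hi - lo)
    penalties = alpha * rescaled + ks
    k = int(ks[np.argmin(penalties)])  # argmin takes the first = smallest k on ties
    return KGSSelection(alpha, ks, spreads, rescaled, penalties, k)


def _aligned_cophenetic(dendA: Dendrogram, dendB: Dendrogram) -> tuple[np.ndarray, np.ndarray]:
    if sorted(dendA.labels) != sorted(dendB.labels):
        raise ValueError("dendrograms have different leaf sets")
    ca = dendA.cophenetic_matrix()
    order = [dendB.labels.index(l) for l in dendA.labels]
    cb = dendB.cophenetic_matrix()[np.ix_(order, order)]
    return ca, cb


def cophenetic_correlation(dendA: Dendrogram, dendB: Dendrogram) -> float:
    """Pearson correlation of two trees' cophenetic distances (upper triangles)."""
    ca, cb = _aligned_cophenetic(dendA, dendB)
    iu = np.triu_indices(len(dendA.labels), 1)
    return float(np.corrcoef(ca[iu], cb[iu])[0, 1])


def _first_merge_partners(dend: Dendrogram) -> dict[str, frozenset[str]]:
    """For each leaf, the set of leaves in its smallest containing non-singleton cluster."""
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    partners: dict[str, frozenset[str]] = {}
    for m, (a, b, _h, _s) in enumerate(dend.Z):
        a, b = int(a), int(b)
        merged = members[a] + members[b]
        for leaf in merged:
            lab = dend.labels[leaf]
            if lab not in partners:
                partners[lab] = frozenset(dend.labels[x] for x in merged if x != leaf)
        members[n + m] = merged
    return partners


def cluster_pairing_export(
    dendA: Dendrogram,
    dendB: Dendrogram,
    kA: int | None = None,
    kB: int | None = None,
) -> pd.DataFrame:
    """Machine-readable substitute for a tanglegram.

    One row per leaf: whether its lowest-level merge partners overlap across
    the two clusterings (the tanglegram's matched connections), plus flat
    cluster memberships at the chosen cut of each tree.
    """
    pa = _first_merge_partners(dendA)
    pb = _first_merge_partners(dendB)
    rows = []
    cutA = dendA.cut(kA) if kA else None
    cutB = dendB.cut(kB) if kB else None
    orderB = {l: i for i, l in enumerate(dendB.labels)}
    for i, leaf in enumerate(dendA.labels):
        row = {
            "leaf": leaf,
            "partners_agree": bool(pa[leaf] & pb[leaf]),
        }
        if cutA is not None:
            row["cluster_a"] = int(cutA[i])
        if cutB is not None:
            row["cluster_b"] = int(cutB[orderB[leaf]])
        rows.append(row)
    return pd.DataFrame(rows)


class SCDiffClustering(BaseEstimator):
    """End-to-end SC_diff profile clustering estimator.

    ``fit(scdiff)`` computes profile distances over the chosen leaves,
    builds the average-linkage tree, and selects k by the KGS penalty.
    Fitted attributes: ``distance_``, ``dendrogram_``, ``selection_``,
    ``k_``, ``labels_`` (flat assignment at the selected k).
    """

    def __init__(
        self,
        leaves: list[str] | None = None,
        columns: list[str] | None = None,
        metric: str = "correlation",
        alpha: float = 1.0,
    ):
        self.leaves = leaves
        self.columns = columns
        self.metric = metric
        self.alpha = alpha

    def fit(self, scdiff: SCDiff, y=None):
        leaves = list(self.leaves) if self.leaves is not None else list(scdiff.labels)
        self.distance_, self.leaf_labels_ = profile_distance(
            scdiff, leaves, columns=self.columns, metric=self.metric
        )
        self.dendrogram_ = average_linkage(self.distance_, self.leaf_labels_)
        self.selection_ = kgs_optimal_k(self.dendrogram_, self.distance_, alpha=self.alpha)
        self.k_ = self.selection_.k
        self.labels_ = self.dendrogram_.cut(self.k_)
        return self
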