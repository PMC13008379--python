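"""Group structural covariance networks and the bounded threshold sweep.

An SCN's edges are Pearson correlations of residualized regional volumes
across the subjects of one group. Bipartite networks (thalamocortical,
thalamosubcortical) keep only cross-set edges. Thresholded weighted graphs
retain edges with weight strictly above the threshold; the sweep runs from
r = 0 in steps of 0.025 and is capped by the minimum wiring cost — the
lowest edge density at which the graph still has no disconnected node —
evaluated per group, with the group comparison sweep ending at the smaller
of the two groups' caps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CovarianceNetwork",
    "build_scn",
    "extract_bipartite",
    "threshold_graph",
    "min_wiring_cost_threshold",
    "sweep_thresholds",
    "UNTHRESHOLDED",
]

DEFAULT_STEP = 0.025

#: sentinel for the unthresholded graph (signed weights kept as-is)
UNTHRESHOLDED = None


@dataclass
class CovarianceNetwork:
    """Labeled symmetric edge-weight matrix for one group.

    ``weights`` is a full symmetric matrix (diagonal undefined, stored 0);
    ``mask`` is the symmetric boolean topology: True where an edge exists.
    For bipartite networks only cross-set entries are True and ``partition``
    records the two node sets.
    """

    labels: list[str]
    weights: np.ndarray
    mask: np.ndarray
    group: str = ""
    n_subjects: int = 0
    partition: tuple[list[str], list[str]] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        p = len(self.labels)
        if self.weights.shape != (p, p) or self.mask.shape != (p, p):
            raise ValueError("weights/mask shape does not match label count")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        """Number of unique (undirected) edges in the topology."""
        return int(np.triu(self.mask, 1).sum())

    def index(self, node: str) -> int:
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} not in network") from None

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def masked_weights(self) -> np.ndarray:
        """Weights with non-edges zeroed (safe for strength sums)."""
        return np.where(self.mask, self.weights, 0.0)

    def upper_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) index arrays of unique edges (upper triangle of the mask)."""
        return np.nonzero(np.triu(self.mask, 1))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = self.upper_edges()
        return pd.DataFrame(
            {
                "node_i": [self.labels[i] for i in ii],
                "node_j": [self.labels[j] for j in jj],
                "weight": self.weights[ii, jj],
            }
        )


def build_scn(
    residuals: pd.DataFrame,
    nodes: list[str],
    group: str = "",
) -> CovarianceNetwork:
    """Pearson-correlation SCN over one group's residualized volumes."""
    missing = [c for c in nodes if c not in residuals.columns]
    if missing:
        raise ValueError(f"regions not in table: {missing}")
    if len(residuals) < 4:
        raise ValueError("need at least 4 subjects to build an SCN")
    X = residuals[list(nodes)].to_numpy(dtype=float)
    sds = X.std(axis=0)
    dead = [nodes[k] for k in np.nonzero(sds == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance region(s): {dead}")
    weights = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(weights, 0.0)
    mask = ~np.eye(len(nodes), dtype=bool)
    return CovarianceNetwork(
        labels=list(nodes), weights=weights, mask=mask, group=group,
        n_subjects=len(residuals),
    )


def extract_bipartite(
    net: CovarianceNetwork, setA: list[str], setB: list[str]
) -> CovarianceNetwork:
    """Keep only A–B edges; the result has |A| x |B| unique edges."""
    if set(setA) & set(setB):
        raise ValueError("bipartite sets overlap")
    if set(setA) | set(setB) != set(net.labels):
        raise ValueError("bipartite sets must cover the network's nodes")
    in_a = np.array([lab in set(setA) for lab in net.labels])
    cross = np.outer(in_a, ~in_a)
    mask = net.mask & (cross | cross.T)
    weights = np.where(mask, net.weights, 0.0)
    return CovarianceNetwork(
        labels=net.labels, weights=weights, mask=mask, group=net.group,
        n_subjects=net.n_subjects, partition=(list(setA), list(setB)),
    )


def threshold_graph(net: CovarianceNetwork, t: float | None) -> CovarianceNetwork:
    """Weighted graph keeping edges with weight strictly above ``t``.

    ``t=UNTHRESHOLDED`` (None) returns the network unchanged, signed
    weights and all.
    """
    if t is UNTHRESHOLDED:
        return replace(net, weights=net.weights.copy(), mask=net.mask.copy())
    if t < 0:
        raise ValueError("threshold must be >= 0")
    mask = net.mask & (net.weights > t)
    return replace(net, weights=np.where(mask, net.weights, 0.0), mask=mask)


def _is_connected(net: CovarianceNetwork) -> bool:
    adj = csr_matrix(net.mask.astype(np.int8))
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def min_wiring_cost_threshold(
    net: CovarianceNetwork, step: float = DEFAULT_STEP
) -> float:
    """Largest grid threshold at which no node is disconnected.

    The grid starts at 0 and ascends in constant steps; connectivity is
    binary reachability over the retained edges (for bipartite networks,
    over both node sets jointly). Raises if the graph is already
    disconnected at threshold 0.
    """
    if not _is_connected(threshold_graph(net, 0.0)):
        raise ValueError("network disconnected at threshold 0")
    t = 0.0
    best = 0.0
    k = 0
    wmax = net.masked_weights().max()
    while t <= wmax:
        if _is_connected(threshold_graph(net, t)):
            best = t
        k += 1
        t = round(k * step, 10)  # keep grid values exact-looking (0.875, not 0.8750000000000001)
    return best


def sweep_thresholds(
    net_a: CovarianceNetwork,
    net_b: CovarianceNetwork,
    step: float = DEFAULT_STEP,
) -> list[float]:
    """Shared threshold grid for a two-group comparison.

    Runs from 0 in constant steps until the minimum wiring cost of one of
    the groups is reached; both endpoints stay connected in both groups.
    """
    cap = min(min_wiring_cost_threshold(net_a, step), min_wiring_cost_threshold(net_b, step))
    n_steps = int(round(cap / step))
    return [round(k * step, 10) for k in range(n_steps + 1)]
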