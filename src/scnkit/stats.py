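"""Strength-type graph measures, group differences, and permutation inference.

The group comparison statistic is always a difference of network measures
(graph strength, node strength centrality, or single edge weights) between
case and control SCNs. Significance comes from label-permutation nulls:
diagnostic labels are shuffled with group sizes preserved, the networks are
rebuilt from the residual table under each relabeling, and the two-sided
Monte-Carlo p-value is (b + 1)/(m + 1) where b counts null differences at
least as large in magnitude as the observed one. Multiple-comparison
control is Benjamini–Hochberg within each stated comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import CovarianceNetwork

__all__ = [
    "graph_strength",
    "node_strength",
    "sc_diff",
    "SCDiff",
    "permutation_test",
    "network_permutation_test",
    "PermutationResult",
    "bh_fdr",
]

DEFAULT_N_PERM_GRAPH = 5_000
DEFAULT_N_PERM_EDGE = 100_000
DEFAULT_FDR_Q = 0.05


def graph_strength(net: CovarianceNetwork) -> float:
    """Sum of connection weights across the network, each unique edge once."""
    w = net.masked_weights()
    return float(np.triu(w, 1).sum())


def node_strength(net: CovarianceNetwork, node: str | None = None):
    """Weighted degree of one node, or a Series over all nodes.

    On a bipartite network a node's strength is the row sum of the cross-set
    weight block (within-set entries are absent from the topology).
    """
    strengths = net.masked_weights().sum(axis=1)
    if node is None:
        return pd.Series(strengths, index=net.labels)
    return float(strengths[net.index(node)])


@dataclass
class SCDiff:
    """Edge-wise case-minus-control structural covariance difference."""

    labels: list[str]
    matrix: np.ndarray
    mask: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def top_edge(self) -> tuple[str, str, float]:
        """Edge with the largest |difference| (ties: first in scan order)."""
        masked = np.where(np.triu(self.mask, 1), np.abs(self.matrix), -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return self.labels[i], self.labels[j], float(self.matrix[i, j])


def sc_diff(case_net: CovarianceNetwork, control_net: CovarianceNetwork) -> SCDiff:
    """Elementwise case − control edge weights; networks must share topology."""
    if case_net.labels != control_net.labels:
        raise ValueError("node sets differ between networks")
    if not np.array_equal(case_net.mask, control_net.mask):
        raise ValueError("edge masks differ between networks")
    return SCDiff(
        labels=list(case_net.labels),
        matrix=np.where(case_net.mask, case_net.weights - control_net.weights, 0.0),
        mask=case_net.mask.copy(),
    )


@dataclass
class PermutationResult:
    """Observed statistic(s), null sample, and p-values of one test family."""

    observed: np.ndarray  # shape (k,) — k statistics sharing the labelings
    null: np.ndarray  # shape (m, k)
    p: np.ndarray  # shape (k,)
    n_permutations: int
    seed: int
    family: str = ""
    p_fdr: np.ndarray | None = None

    @property
    def scalar(self) -> bool:
        return self.observed.size == 1

    def observed_value(self) -> float:
        return float(self.observed.reshape(-1)[0])

    def p_value(self) -> float:
        return float(self.p.reshape(-1)[0])


def permutation_test(
    data: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    statistic,
    n_perm: int,
    seed: int = 0,
    case_label="case",
    family: str = "",
    fdr_q: float | None = None,
) -> PermutationResult:
    """Group-size-preserving label permutation test.

    ``statistic(group_rows)`` maps one group's data rows (ndarray, subjects x
    regions) to a scalar or vector of measures; the test statistic is
    statistic(case) − statistic(control), compared two-sided (by magnitude)
    against its relabeling null. Vector statistics (e.g., per-edge or
    per-threshold measures) share the same permutation labelings, and
    ``fdr_q`` triggers BH adjustment across the vector's components.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    case_rows = labels == case_label
    n_case = int(case_rows.sum())
    if n_case == 0 or n_case == len(labels):
        raise ValueError("both groups must be nonempty")

    def diff(mask: np.ndarray) -> np.ndarray:
        return np.atleast_1d(np.asarray(statistic(X[mask]), dtype=float) -
                             np.asarray(statistic(X[~mask]), dtype=float)).reshape(-1)

    observed = diff(case_rows)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    idx = np.arange(len(labels))
    for m in range(n_perm):
        perm_case = np.zeros(len(labels), dtype=bool)
        perm_case[rng.choice(idx, size=n_case, replace=False)] = True
        null[m] = diff(perm_case)
    b = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    p = (b + 1.0) / (n_perm + 1.0)
    result = PermutationResult(
        observed=observed, null=null, p=p, n_permutations=n_perm, seed=seed, family=family,
    )
    if fdr_q is not None and observed.size > 1:
        result.p_fdr = bh_fdr(p)
    return result


def network_permutation_test(
    residuals: pd.DataFrame,
    nodes: list[str],
    measure: str = "graph_strength",
    group_col: str = "group",
    case_label: str = "case",
    n_perm: int = DEFAULT_N_PERM_GRAPH,
    seed: int = 0,
    threshold: float | None = None,
    partition: tuple[list[str], list[str]] | None = None,
    fdr_q: float | None = None,
) -> PermutationResult:
    """Permutation test of an SCN measure, rebuilding networks per shuffle.

    ``measure`` is ``graph_strength`` (scalar), ``node_strength`` (vector over
    nodes), or ``edges`` (vector over unique edges of the topology).
    ``threshold`` applies the strict-inequality weighted threshold before
    measuring (None = unthresholded signed graph).
    """
    from .network import extract_bipartite, threshold_graph

    node_list = list(nodes)
    base_mask = ~np.eye(len(node_list), dtype=bool)

    def make_net(rows: np.ndarray) -> CovarianceNetwork:
        # rebuilt from the relabeled subjects on every shuffle; bypasses the
        # DataFrame wrapper of build_scn because this runs O(n_perm) times
        weights = np.corrcoef(rows, rowvar=False)
        np.fill_diagonal(weights, 0.0)
        net = CovarianceNetwork(labels=node_list, weights=weights, mask=base_mask.copy(),
                                n_subjects=rows.shape[0])
        if partition is not None:
            net = extract_bipartite(net, *partition)
        return threshold_graph(net, threshold)

    template = make_net(residuals[list(nodes)].to_numpy(dtype=float))
    ii, jj = template.upper_edges()

    if measure == "graph_strength":
        stat = lambda rows: graph_strength(make_net(rows))
    elif measure == "node_strength":
        stat = lambda rows: node_strength(make_net(rows)).to_numpy()
    elif measure == "edges":
        stat = lambda rows: make_net(rows).weights[ii, jj]
    else:
        raise ValueError(f"unknown measure {measure!r}")

    return permutation_test(
        residuals[list(nodes)], residuals[group_col].to_numpy(), stat,
        n_perm=n_perm, seed=seed, case_label=case_label, family=measure, fdr_q=fdr_q,
    )


def bh_fdr(p_values, family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float).reshape(-1)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError(f"p-values must lie in (0, 1]{' for family ' + family if family else ''}")
    return multipletests(p, method="fdr_bh")[1]
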