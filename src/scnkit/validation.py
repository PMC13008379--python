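"""Ground-truth recovery experiments on synthetic cohorts.

Because the consortium volume tables the pipeline targets are not
redistributable, the pipeline's operating characteristics are established on
simulated cohorts where the truth is implanted. Each function here runs one
such experiment end to end through the package's own machinery and returns
the measured quantity:

* :func:`permutation_calibration` — type-I error of the graph-strength
  permutation test under a null cohort (no group difference);
* :func:`strength_power` — detection rate for a uniform within-network
  covariance elevation in cases;
* :func:`edge_recovery` — how often a single implanted edge shift is the
  top |SC_diff| edge, and the recovered shift;
* :func:`severity_recovery` — recovery of a severity-linked edge
  perturbation through the IDSCN severity scan;
* :func:`idscn_null_scaling` — shrinkage of null IDSCN deltas with control
  group size, plus the empirical null SD of both Z variants;
* :func:`kgs_recovery` — recovery of implanted SC_diff profile groups by
  KGS-selected average-linkage clustering.

Default problem sizes are the experiments' study conditions (see
docs/methods.md for the power analysis behind the edge-recovery design);
``seed`` drives all randomness.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import regions as regions_mod
from .cluster import SCDiffClustering
from .idscn import IDSCN, null_calibration, severity_edge_scan
from .network import build_scn, extract_bipartite
from .simulate import CohortSpec, generate_cohort, uniform_correlation
from .stats import SCDiff, network_permutation_test, sc_diff

__all__ = [
    "edge_family_sizes",
    "permutation_calibration",
    "strength_power",
    "edge_recovery",
    "severity_recovery",
    "idscn_null_scaling",
    "kgs_recovery",
]


def _labels(p: int) -> list[str]:
    return [f"R{k:02d}" for k in range(p)]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def edge_family_sizes(seed: int = 0) -> dict:
    """Unique-edge counts of the three standard networks, built for real.

    Draws a tiny synthetic table over the full packaged region set, builds
    the intrathalamic, thalamocortical, and thalamosubcortical networks,
    and counts their edges.
    """
    thal = regions_mod.thalamic_labels()
    cort = regions_mod.cortical_labels()
    sub = regions_mod.subcortical_labels()
    all_regions = thal + cort + sub
    import pandas as pd

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(rng.normal(size=(12, len(all_regions))), columns=all_regions)
    intra = build_scn(table, thal)
    tc = extract_bipartite(build_scn(table, thal + cort), thal, cort)
    ts = extract_bipartite(build_scn(table, thal + sub), thal, sub)
    return {
        "intrathalamic": intra.edge_count,
        "thalamocortical": tc.edge_count,
        "thalamosubcortical": ts.edge_count,
    }


def permutation_calibration(
    n_reps: int = 200,
    n_per_group: int = 50,
    n_regions: int = 10,
    base_r: float = 0.3,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the graph-strength test on null cohorts."""
    labels = _labels(n_regions)
    base = uniform_correlation(n_regions, base_r)
    hits = 0
    for rep_seed in _child_seeds(seed, n_reps):
        spec = CohortSpec(n_per_group, n_per_group, labels, base, seed=rep_seed)
        table, _ = generate_cohort(spec)
        res = network_permutation_test(table, labels, measure="graph_strength",
                                       n_perm=n_perm, seed=rep_seed)
        hits += res.p_value() < alpha
    return hits / n_reps


def strength_power(
    n_reps: int = 100,
    n_per_group: int = 500,
    n_regions: int = 50,
    base_r: float = 0.3,
    elevation: float = 0.1,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate of a uniform within-network covariance elevation.

    All pairwise correlations are raised by ``elevation`` in cases — the
    qualitative shape of a globally strengthened covariance network.
    """
    labels = _labels(n_regions)
    base = uniform_correlation(n_regions, base_r)
    effects = [(i, j, elevation) for i in range(n_regions) for j in range(i + 1, n_regions)]
    hits = 0
    for rep_seed in _child_seeds(seed, n_reps):
        spec = CohortSpec(n_per_group, n_per_group, labels, base,
                          case_edge_effects=effects, seed=rep_seed)
        table, _ = generate_cohort(spec)
        res = network_permutation_test(table, labels, measure="graph_strength",
                                       n_perm=n_perm, seed=rep_seed)
        hits += res.p_value() < alpha
    return hits / n_reps


def edge_recovery(
    n_reps: int = 100,
    n_per_group: int = 500,
    n_regions: int = 10,
    base_r: float = 0.6,
    delta: float = 0.2,
    seed: int = 0,
) -> dict:
    """Recovery of a single implanted edge shift through group SC_diff.

    Returns the fraction of replicates where the implanted edge is the
    top-|SC_diff| edge and the mean recovered shift at that edge.
    """
    labels = _labels(n_regions)
    base = uniform_correlation(n_regions, base_r)
    top_hits = 0
    recovered = []
    for rep_seed in _child_seeds(seed, n_reps):
        spec = CohortSpec(n_per_group, n_per_group, labels, base,
                          case_edge_effects=[(0, 1, delta)], seed=rep_seed)
        table, _ = generate_cohort(spec)
        case_net = build_scn(table[table["group"] == "case"], labels, group="case")
        ctrl_net = build_scn(table[table["group"] == "control"], labels, group="control")
        diff = sc_diff(case_net, ctrl_net)
        a, b, value = diff.top_edge()
        top_hits += {a, b} == {labels[0], labels[1]}
        recovered.append(diff.matrix[0, 1])
    return {
        "top_edge_rate": top_hits / n_reps,
        "mean_recovered_delta": float(np.mean(recovered)),
    }


def severity_recovery(
    n_controls: int = 400,
    n_cases: int = 400,
    n_regions: int = 50,
    base_r: float = 0.3,
    link_r: float = 0.3,
    seed: int = 0,
) -> dict:
    """Recovery of a severity-linked edge perturbation via the IDSCN scan.

    One edge's per-subject perturbation is coupled to the symptom score with
    population correlation ``link_r``; the scan must rank that edge first by
    |severity-Z correlation| and recover the correlation itself.
    """
    labels = _labels(n_regions)
    base = uniform_correlation(n_regions, base_r)
    noise_sd = float(np.sqrt(1.0 - link_r**2))
    spec = CohortSpec(n_controls, n_cases, labels, base,
                      severity_link=(0, 1, link_r, noise_sd), seed=seed)
    table, truth = generate_cohort(spec)
    ctrl = table[table["group"] == "control"]
    cases = table[table["group"] == "case"]
    est = IDSCN(nodes=labels).fit(ctrl)
    results = est.transform(cases)
    scan = severity_edge_scan(results, cases["severity"].to_numpy())
    top = scan.iloc[0]
    implanted_row = scan[
        ((scan["node_i"] == labels[0]) & (scan["node_j"] == labels[1]))
        | ((scan["node_i"] == labels[1]) & (scan["node_j"] == labels[0]))
    ].iloc[0]
    return {
        "n_edges": len(scan),
        "top_edge_is_implanted": bool({top["node_i"], top["node_j"]}
                                      == {labels[0], labels[1]}),
        "top_edge_r": float(top["r"]),
        "implanted_edge_r": float(implanted_row["r"]),
        "target_r": link_r,
    }


def idscn_null_scaling(
    control_sizes: tuple[int, ...] = (50, 200, 800),
    n_probe: int = 20,
    n_regions: int = 10,
    base_r: float = 0.3,
    seed: int = 0,
) -> dict:
    """Shrinkage of null IDSCN deltas with n, plus Z-variant null SDs."""
    labels = _labels(n_regions)
    base = uniform_correlation(n_regions, base_r)
    seeds = _child_seeds(seed, len(control_sizes) + 1)
    mean_max_delta = {}
    for n, s in zip(control_sizes, seeds):
        spec = CohortSpec(n + n_probe, 0, labels, base, seed=s)
        table, _ = generate_cohort(spec)
        ctrl = table.iloc[:n]
        probes = table.iloc[n:]
        est = IDSCN(nodes=labels).fit(ctrl)
        maxima = [np.abs(est.transform_subject(row, str(k)).delta).max()
                  for k, row in probes.iterrows()]
        mean_max_delta[n] = float(np.mean(maxima))
    calib_spec = CohortSpec(max(control_sizes) + n_probe, 0, labels, base, seed=seeds[-1])
    calib_table, _ = generate_cohort(calib_spec)
    calib = null_calibration(calib_table[labels], labels, n_probe=n_probe, seed=seeds[-1])
    values = [mean_max_delta[n] for n in control_sizes]
    return {
        "mean_max_delta": mean_max_delta,
        "monotone_decreasing": bool(all(a > b for a, b in zip(values, values[1:]))),
        "null_z_sd": {v: calib[v]["z_sd"] for v in ("printed", "sqrt")},
    }


def kgs_recovery(
    n_reps: int = 50,
    n_groups: int = 6,
    per_group: int = 10,
    n_cols: int = 40,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates recovering implanted SC_diff profile groups.

    60 leaves carry profiles drawn from ``n_groups`` prototypes plus noise;
    a replicate counts as recovered when the KGS-selected cut has exactly
    ``n_groups`` clusters and reproduces the groups (adjusted Rand = 1).
    """
    hits = 0
    leaves = [f"t{i:02d}" for i in range(n_groups * per_group)]
    cols = [f"c{j:02d}" for j in range(n_cols)]
    truth = np.repeat(np.arange(n_groups), per_group)
    for rep_seed in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        prototypes = rng.normal(size=(n_groups, n_cols))
        block = prototypes[truth] + noise_sd * rng.normal(size=(len(leaves), n_cols))
        labels = leaves + cols
        m = np.zeros((len(labels), len(labels)))
        m[: len(leaves), len(leaves):] = block
        m += m.T
        diff = SCDiff(labels=labels, matrix=m,
                      mask=~np.eye(len(labels), dtype=bool))
        clus = SCDiffClustering(leaves=leaves, columns=cols).fit(diff)
        hits += (clus.k_ == n_groups
                 and adjusted_rand_score(truth, clus.labels_) == 1.0)
    return hits / n_reps
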