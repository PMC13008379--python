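"""End-to-end orchestration: simulate/load → preprocess → SCN → stats → IDSCN → cluster.

A single YAML-able configuration drives a deterministic run: identical
config + seed produces identical output files. Each analysis network
(unipartite or bipartite) gets its own outlier screen — a subject excluded
from one network's analysis may be retained in another — followed by site
harmonization, covariate residualization, group network construction, the
bounded threshold sweep, permutation statistics, IDSCN generation, and
SC_diff clustering.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import idscn as idscn_mod
from . import io as io_mod
from . import regions as regions_mod
from .cluster import SCDiffClustering
from .network import build_scn, extract_bipartite, sweep_thresholds, threshold_graph
from .preprocess import harmonize_sites, remove_outliers, residualize
from .simulate import CohortSpec, build_base_covariance, generate_cohort
from .stats import network_permutation_test, sc_diff

__all__ = ["RunConfig", "run_pipeline", "load_config", "spec_from_config"]


@dataclass
class RunConfig:
    """Validated run configuration.

    Either ``input_path`` (a feature-table CSV/TSV) or ``simulate`` (a
    mapping passed to :func:`spec_from_config`) must be given. ``networks``
    maps a network name to ``{"nodes": [...]}`` or
    ``{"setA": [...], "setB": [...]}``; when omitted and the table carries
    the packaged region labels, the three standard networks are used,
    otherwise a single unipartite network over all region columns.
    """

    output_dir: str
    seed: int = 0
    input_path: str | None = None
    simulate: dict | None = None
    networks: dict[str, dict] | None = None
    outlier_z_threshold: float = 2.698
    harmonize: bool = True
    age_basis_degree: int = 2
    residualize_scope: str = "pooled"
    n_perm_graph: int = 5_000
    n_perm_node: int = 5_000
    n_perm_edge: int = 0  # 0 disables the (expensive) edge-level family
    fdr_q: float = 0.05
    idscn_z_variant: str = "printed"
    run_idscn: bool = True
    run_cluster: bool = True
    threshold_step: float = 0.025

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")
        if self.residualize_scope not in ("pooled", "per_group"):
            raise ValueError("residualize_scope must be 'pooled' or 'per_group'")
        for name, n in (("n_perm_graph", self.n_perm_graph), ("n_perm_node", self.n_perm_node)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.networks is not None:
            for name, spec in self.networks.items():
                if "nodes" in spec:
                    if not spec["nodes"]:
                        raise ValueError(f"network {name!r}: empty node list")
                elif "setA" in spec and "setB" in spec:
                    if not spec["setA"] or not spec["setB"]:
                        raise ValueError(f"network {name!r}: empty bipartite set")
                    if set(spec["setA"]) & set(spec["setB"]):
                        raise ValueError(f"network {name!r}: bipartite sets overlap")
                else:
                    raise ValueError(f"network {name!r}: give 'nodes' or 'setA'+'setB'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def spec_from_config(sim: dict, seed: int) -> CohortSpec:
    """Build a :class:`CohortSpec` from the config's ``simulate`` mapping.

    Recognized keys: n_control, n_case, region_labels (default ``R00``…),
    blocks (for :func:`build_base_covariance`), between_r, base_r (uniform
    shortcut), edge_effects, sites (label -> [additive, multiplicative]),
    covariate_effects, severity_link, noise_sd, seed (defaults to the run
    seed).
    """
    sim = dict(sim)
    n_regions = int(sim.get("n_regions", 10))
    labels = list(sim.get("region_labels", [f"R{k:02d}" for k in range(n_regions)]))
    n_regions = len(labels)
    if "blocks" in sim:
        base = build_base_covariance(
            n_regions, [tuple(b) for b in sim["blocks"]],
            seed=seed, between_r=float(sim.get("between_r", 0.0)),
        )
    else:
        base = build_base_covariance(n_regions, [(n_regions, float(sim.get("base_r", 0.3)))])
    sites = sim.get("sites") or {"site1": [0.0, 1.0]}
    return CohortSpec(
        n_control=int(sim.get("n_control", 100)),
        n_case=int(sim.get("n_case", 100)),
        region_labels=labels,
        base_covariance=base,
        case_edge_effects=[tuple(e) for e in sim.get("edge_effects", [])],
        site_labels=list(sites),
        site_effects={s: (float(v[0]), float(v[1])) for s, v in sites.items()},
        covariate_effects=sim.get("covariate_effects"),
        severity_link=tuple(sim["severity_link"]) if sim.get("severity_link") else None,
        noise_sd=float(sim.get("noise_sd", 0.0)),
        seed=int(sim.get("seed", seed)),
    )


def _resolve_networks(config: RunConfig, table: pd.DataFrame) -> dict[str, dict]:
    if config.networks is not None:
        return config.networks
    cols = set(table.columns)
    thal, cort, sub = (
        regions_mod.thalamic_labels(), regions_mod.cortical_labels(),
        regions_mod.subcortical_labels(),
    )
    if set(thal) <= cols:
        nets: dict[str, dict] = {"intrathalamic": {"nodes": thal}}
        if set(cort) <= cols:
            nets["thalamocortical"] = {"setA": thal, "setB": cort}
        if set(sub) <= cols:
            nets["thalamosubcortical"] = {"setA": thal, "setB": sub}
        return nets
    region_cols = [c for c in table.columns if c not in io_mod.METADATA_COLUMNS]
    return {"all": {"nodes": region_cols}}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write stage outputs plus a JSON run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "networks": {}}
    t_start = time.perf_counter()

    def mark(stage: str, t0: float) -> None:
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 4)}

    # --- input ------------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate is not None:
        spec = spec_from_config(config.simulate, config.seed)
        table, truth = generate_cohort(spec)
        io_mod.write_feature_table(table, out_dir / "cohort.csv")
        io_mod.write_json(truth.to_dict(), out_dir / "ground_truth.json")
    else:
        table = io_mod.read_feature_table(config.input_path)
    n_case = int((table["group"] == "case").sum())
    n_control = int((table["group"] == "control").sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both case and control groups must be nonempty")
    report["n_subjects"] = {"case": n_case, "control": n_control}
    mark("input", t0)

    networks = _resolve_networks(config, table)
    ss = np.random.SeedSequence(config.seed)
    net_seeds = {name: int(s.generate_state(1)[0] % 2**31)
                 for name, s in zip(networks, ss.spawn(len(networks)))}

    for name, netspec in networks.items():
        nrep: dict[str, Any] = {}
        nodes = netspec.get("nodes") or (list(netspec["setA"]) + list(netspec["setB"]))
        partition = (
            (list(netspec["setA"]), list(netspec["setB"])) if "setA" in netspec else None
        )

        # --- preprocess (per network) ------------------------------------
        t0 = time.perf_counter()
        kept, removed = remove_outliers(table, regions=nodes, z_threshold=config.outlier_z_threshold)
        nrep["outliers_removed"] = len(removed)
        if config.harmonize and kept["site"].nunique() > 1:
            kept = harmonize_sites(kept, regions=nodes, age_basis_degree=config.age_basis_degree)
        resid = residualize(kept, regions=nodes, scope=config.residualize_scope)
        io_mod.write_feature_table(resid, out_dir / f"{name}_residuals.csv")
        mark(f"{name}:preprocess", t0)

        # --- group networks + sweep --------------------------------------
        t0 = time.perf_counter()
        case_resid = resid[resid["group"] == "case"]
        ctrl_resid = resid[resid["group"] == "control"]

        def finish(net):
            return extract_bipartite(net, *partition) if partition else net

        case_net = finish(build_scn(case_resid, nodes, group="case"))
        ctrl_net = finish(build_scn(ctrl_resid, nodes, group="control"))
        io_mod.write_network(case_net, out_dir, f"{name}_case")
        io_mod.write_network(ctrl_net, out_dir, f"{name}_control")
        grid = sweep_thresholds(case_net, ctrl_net, step=config.threshold_step)
        nrep["edge_count"] = case_net.edge_count
        nrep["threshold_grid"] = grid
        diff = sc_diff(case_net, ctrl_net)
        diff.to_dataframe().to_csv(out_dir / f"{name}_sc_diff.csv",
                                   float_format=io_mod.FLOAT_FORMAT)
        mark(f"{name}:scn", t0)

        # --- permutation statistics --------------------------------------
        t0 = time.perf_counter()
        seed = net_seeds[name]
        res_graph = network_permutation_test(
            resid, nodes, measure="graph_strength", n_perm=config.n_perm_graph,
            seed=seed, partition=partition,
        )
        nrep["graph_strength"] = {
            "observed_diff": res_graph.observed_value(), "p": res_graph.p_value(),
        }
        res_node = network_permutation_test(
            resid, nodes, measure="node_strength", n_perm=config.n_perm_node,
            seed=seed + 1, partition=partition, fdr_q=config.fdr_q,
        )
        node_tbl = pd.DataFrame({
            "node": nodes, "observed_diff": res_node.observed,
            "p": res_node.p, "p_fdr": res_node.p_fdr,
        })
        node_tbl.to_csv(out_dir / f"{name}_node_strength.tsv", sep="\t", index=False,
                        float_format=io_mod.FLOAT_FORMAT)
        nrep["node_strength_significant"] = node_tbl.loc[
            node_tbl["p_fdr"] < config.fdr_q, "node"].tolist()
        if config.n_perm_edge > 0:
            res_edge = network_permutation_test(
                resid, nodes, measure="edges", n_perm=config.n_perm_edge,
                seed=seed + 2, partition=partition, fdr_q=config.fdr_q,
            )
            tmpl = threshold_graph(case_net, None)
            ii, jj = tmpl.upper_edges()
            edge_tbl = pd.DataFrame({
                "node_i": [nodes[i] for i in ii], "node_j": [nodes[j] for j in jj],
                "observed_diff": res_edge.observed, "p": res_edge.p, "p_fdr": res_edge.p_fdr,
            })
            edge_tbl.to_csv(out_dir / f"{name}_edges_perm.tsv", sep="\t", index=False,
                            float_format=io_mod.FLOAT_FORMAT)
            nrep["edges_significant"] = int((res_edge.p_fdr < config.fdr_q).sum())
        mark(f"{name}:stats", t0)

        # --- IDSCN --------------------------------------------------------
        if config.run_idscn:
            t0 = time.perf_counter()
            est = idscn_mod.IDSCN(
                nodes=nodes, partition=partition, z_variant=config.idscn_z_variant,
                q=config.fdr_q,
            ).fit(ctrl_resid)
            results = est.transform(case_resid)
            profile = idscn_mod.altered_edge_profile(results)
            profile.to_dataframe().to_csv(out_dir / f"{name}_idscn_profile.tsv",
                                          sep="\t", index=False)
            nrep["idscn_mean_altered"] = float(profile.totals.mean())
            severity = case_resid["severity"].to_numpy(dtype=float)
            if np.isfinite(severity).all() and np.std(severity) > 0 and len(severity) >= 10:
                assoc = idscn_mod.severity_association(profile.totals, severity) \
                    if profile.totals.std() > 0 else {"r": float("nan"), "p": float("nan")}
                nrep["severity_vs_total_altered"] = assoc
                scan = idscn_mod.severity_edge_scan(results, severity, fdr_q=config.fdr_q)
                scan.to_csv(out_dir / f"{name}_severity_edges.tsv", sep="\t", index=False,
                            float_format=io_mod.FLOAT_FORMAT)
                top = scan.iloc[0]
                nrep["severity_top_edge"] = {
                    "node_i": top["node_i"], "node_j": top["node_j"],
                    "r": float(top["r"]), "p_fdr": float(top["p_fdr"]),
                }
            mark(f"{name}:idscn", t0)

        # --- clustering ----------------------------------------------------
        if config.run_cluster and partition is None and len(nodes) >= 5:
            t0 = time.perf_counter()
            clus = SCDiffClustering().fit(diff)
            nrep["cluster_k"] = clus.k_
            clus.selection_.to_dataframe().to_csv(
                out_dir / f"{name}_kgs_penalty.tsv", sep="\t", index=False,
                float_format=io_mod.FLOAT_FORMAT)
            (out_dir / f"{name}_dendrogram.nwk").write_text(clus.dendrogram_.to_newick() + "\n")
            io_mod.write_json({"merges": clus.dendrogram_.merge_list(),
                               "labels": clus.dendrogram_.labels},
                              out_dir / f"{name}_dendrogram.json")
            mark(f"{name}:cluster", t0)

        report["networks"][name] = nrep

    report["total_seconds"] = round(time.perf_counter() - t_start, 4)
    io_mod.write_json(report, out_dir / "run_report.json")
    return report
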