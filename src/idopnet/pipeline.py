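"""End-to-end orchestration: index -> cluster -> select -> fit -> test ->
crosstalk -> metrics/hubs -> export, with a hashed artifact manifest.

The pipeline runs on one segment's matrix (clustered over its compartment
index, then a network per leaf module) and, when both segments of the same
grafts are supplied, adds per-gene crosstalk typing over the niche index.
All randomness descends from the single configured seed; rerunning with the
same config and seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from idopnet.clustering import cluster_tree
from idopnet.crosstalk import classify_crosstalk, fit_crosstalk, type_frequencies
from idopnet.errors import IdopnetError
from idopnet.io_indices import compartment_index, read_expression
from idopnet.network import (
    apply_significance,
    fit_network,
    hubness,
    network_metrics,
    smooth_trajectories,
)
from idopnet.selection import build_problem, choose_lambda, group_lasso_path


@dataclass
class RunConfig:
    matrix: str = ""
    meta: str = ""
    scion_matrix: str = ""            # optional, enables the crosstalk stage
    rootstock_matrix: str = ""
    outdir: str = "idopnet_out"
    order: int = 4
    k_min: int = 1
    k_max: int = 8
    max_leaf: int = 60
    max_network_genes: int = 40       # cap per-module network size
    max_modules: int = 2              # how many leaf modules to fit networks for
    criterion: str = "extendedBIC"
    n_perm: int = 200
    alpha: float = 0.05
    seed: int = 0
    crosstalk_genes: int = 20         # cap for the crosstalk stage

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = [k for k in raw if k not in known]
        if bad:
            raise IdopnetError(f"unknown config keys: {bad}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def select_module(Y: np.ndarray, gene_ids: list[str], E, order: int = 4,
                  criterion: str = "extendedBIC"):
    """Group-Lasso regulator selection for every gene of one module."""
    order_idx = E.order
    E_sorted = E.values[order_idx]
    Yo = np.asarray(Y, dtype=float)[:, order_idx]
    smooth = smooth_trajectories(Yo, E_sorted)
    curves = {g: smooth[j] for j, g in enumerate(gene_ids)}
    results = {}
    for j, g in enumerate(gene_ids):
        problem = build_problem(g, curves, E_sorted, y=Yo[j], order=order)
        path = group_lasso_path(problem)
        results[g] = choose_lambda(path, criterion=criterion)
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "stages": [],
                "artifacts": artifacts}

    def record(stage: str, path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    try:
        ds = read_expression(cfg.matrix, cfg.meta)
    except IdopnetError as err:
        raise SystemExit(f"[input] invalid expression input: {err}") from err

    # --- stage: index ---
    E = compartment_index(ds)
    idx_path = out / "compartment_index.tsv"
    pd.DataFrame({"sample_id": E.sample_ids, "value": E.values}).to_csv(
        idx_path, sep="\t", index=False)
    record("index", idx_path)

    # --- stage: cluster ---
    tree = cluster_tree(ds.values, E, range(cfg.k_min, cfg.k_max + 1),
                        max_leaf=cfg.max_leaf, seed=cfg.seed)
    labels = tree.leaf_labels()
    assign_path = out / "module_assignments.tsv"
    pd.DataFrame({"gene_id": ds.gene_ids, "module": labels}).to_csv(
        assign_path, sep="\t", index=False)
    record("cluster", assign_path)

    # --- stage: select + fit + test per module ---
    leaves = sorted(tree.leaves(), key=lambda nd: -len(nd))
    nets_meta = []
    for leaf in leaves[: cfg.max_modules]:
        idx = leaf.gene_indices[: cfg.max_network_genes]
        genes = [ds.gene_ids[i] for i in idx]
        if len(genes) < 3:
            continue
        Ym = ds.values[idx]
        sel = select_module(Ym, genes, E, order=cfg.order,
                            criterion=cfg.criterion)
        net = fit_network(Ym, genes, E, sel, order=cfg.order, seed=cfg.seed)
        apply_significance(net, n_perm=cfg.n_perm, seed=cfg.seed,
                           alpha=cfg.alpha)
        edge_path = out / f"network_{leaf.label}.tsv"
        pd.DataFrame([
            {"source": e.source, "target": e.target, "weight": e.weight,
             "sign": e.sign, "lr": e.lr, "significant": e.significant}
            for e in net.edges
        ]).to_csv(edge_path, sep="\t", index=False)
        record("network", edge_path)
        metrics = network_metrics(net)
        hubs = hubness(net)
        nets_meta.append({"module": leaf.label, "n_genes": len(genes),
                          "metrics": metrics,
                          "top_hub": max(hubs, key=hubs.get) if hubs else None})
        gml_path = out / f"network_{leaf.label}.graphml"
        import networkx as nx

        G = net.to_graph()
        nx.set_node_attributes(G, hubs, "centrality")
        nx.write_graphml(G, gml_path)
        record("network", gml_path)
    metrics_path = out / "network_metrics.json"
    metrics_path.write_text(json.dumps(nets_meta, indent=2, sort_keys=True))
    record("metrics", metrics_path)

    # --- stage: crosstalk (optional) ---
    if cfg.scion_matrix and cfg.rootstock_matrix:
        ds_s = read_expression(cfg.scion_matrix, cfg.meta)
        ds_r = read_expression(cfg.rootstock_matrix, cfg.meta)
        shared = [g for g in ds_s.gene_ids if g in set(ds_r.gene_ids)]
        calls = []
        for g in shared[: cfg.crosstalk_genes]:
            fit = fit_crosstalk(
                g, ds_s.values[ds_s.gene_ids.index(g)],
                ds_r.values[ds_r.gene_ids.index(g)], seed=cfg.seed,
            )
            calls.append(classify_crosstalk(fit, n_perm=cfg.n_perm,
                                            alpha=cfg.alpha, seed=cfg.seed))
        calls_path = out / "crosstalk_calls.tsv"
        pd.DataFrame([
            {"gene_id": c.gene, "combination": c.combination,
             "effect_scion_to_rootstock": c.effect_on_rootstock.value,
             "effect_rootstock_to_scion": c.effect_on_scion.value,
             "type": c.type.value}
            for c in calls
        ]).to_csv(calls_path, sep="\t", index=False)
        record("crosstalk", calls_path)
        freq_path = out / "crosstalk_frequencies.json"
        freq_path.write_text(json.dumps(
            {k: v.values.tolist() for k, v in type_frequencies(calls).items()},
            indent=2, sort_keys=True))
        record("crosstalk", freq_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
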