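"""End-to-end pipeline: config in, result bundle on disk out.

All randomized stages draw from one master seed through fixed per-stage
offsets (see ``STAGE_OFFSETS``), so an entire result bundle is
reproducible from the config alone; two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hypernetwork as hn
from . import io as tio
from . import simulate as sim
from .classifier import annotate_interface, boruta_classify
from .containers import ExpressionMatrix, InterfaceTable, ValidationError
from .interface import build_interface, summarize_interface
from .velocity import velocity_heatmap

logger = logging.getLogger(__name__)

__all__ = ["STAGE_OFFSETS", "stage_seed", "load_config", "run_pipeline"]

STAGE_OFFSETS = {
    "receptivity": 11,
    "te_single_cells": 23,
    "interaction_graph": 37,
    "localization": 41,
    "tsc_stb": 53,
    "velocity": 71,
    "null_polar": 101,
    "null_mural": 103,
    "boruta": 131,
}

REQUIRED_KEYS = (
    "seed",
    "deg_alpha",
    "localization_terms",
    "min_expressed_fraction",
    "sd_multiplier",
    "n_permutations",
    "rf_iterations",
)


def stage_seed(master: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence([int(master), STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if "simulate" not in cfg and "inputs" not in cfg:
        missing.append("simulate|inputs")
    if missing:
        raise ValidationError(f"config missing required keys: {missing}")


def _fmt(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def _simulate_inputs(cfg: dict, seed: int) -> dict:
    s = cfg.get("simulate") or {}
    n_interface = int(s.get("n_interface", 39))
    eec_mat, eec_truth = sim.generate_receptivity_dataset(
        n_genes=int(s.get("n_genes", 2000)),
        n_per_group=int(s.get("n_per_group", 4)),
        n_degs=int(s.get("n_degs", 200)),
        effect_sd=float(s.get("effect_sd", 5.0)),
        seed=stage_seed(seed, "receptivity"),
    )
    interface_genes = sim.default_interface_genes(n_interface)
    te_kw = dict(s.get("te", {}))
    te_mat, te_truth = sim.generate_te_single_cells(
        interface_genes=interface_genes,
        seed=stage_seed(seed, "te_single_cells"),
        **te_kw,
    )
    eec_surface = sorted(eec_truth.planted_degs)[:n_interface]
    graph, graph_truth = sim.generate_interaction_graph(
        eec_surface,
        interface_genes,
        n_decoy_edges=int(s.get("n_decoy_edges", 50)),
        seed=stage_seed(seed, "interaction_graph"),
    )
    loc = sim.generate_localization_table(
        eec_surface + interface_genes,
        sorted(set(eec_mat.gene_ids) - set(eec_surface)),
        seed=stage_seed(seed, "localization"),
    )
    return {
        "eec_matrix": eec_mat,
        "te_matrix": te_mat,
        "graph": graph,
        "localization": loc,
        "groups": ("proliferative", "mid_secretory"),
        "truth": {
            "planted_degs": sorted(eec_truth.planted_degs),
            "planted_edges": sorted(map(list, graph_truth.planted_edges)),
            "planted_modules": te_truth.planted_modules,
            "sparsity": te_truth.sparsity,
        },
    }


def _file_inputs(cfg: dict) -> dict:
    inp = cfg["inputs"]
    needed = ["eec_matrix", "eec_groups", "te_matrix", "te_groups", "edges", "localization"]
    missing = [k for k in needed if k not in inp]
    if missing:
        raise ValidationError(f"config inputs missing keys: {missing}")
    eec = tio.read_expression_matrix(inp["eec_matrix"], group_file=inp["eec_groups"])
    te = tio.read_expression_matrix(inp["te_matrix"], group_file=inp["te_groups"])
    return {
        "eec_matrix": eec,
        "te_matrix": te,
        "graph": tio.read_edge_list(inp["edges"]),
        "localization": tio.read_localization_table(inp["localization"]),
        "groups": tuple(inp.get("groups", ("proliferative", "mid_secretory"))),
        "truth": None,
    }


def run_pipeline(config: dict | str | Path, out: str | Path, stages: set[str] | None = None) -> dict:
    """Run the configured stages and write the result bundle under ``out``.

    Stages: interface, hypernetwork, classify, velocity (default all).
    Returns a summary dict of the headline metrics.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _validate(config)
    stages = stages or {"interface", "hypernetwork", "classify", "velocity"}
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"seed": seed, "stages": sorted(stages)}

    data = _simulate_inputs(config, seed) if "simulate" in config else _file_inputs(config)
    group_a, group_b = data["groups"]

    table = build_interface(
        data["eec_matrix"],
        group_a,
        group_b,
        data["localization"],
        data["graph"],
        data["te_matrix"],
        alpha=float(config["deg_alpha"]),
        allowed_terms=frozenset(config["localization_terms"]),
        min_fraction=float(config["min_expressed_fraction"]),
    )
    if len(table) == 0:
        logger.warning("empty interface table; downstream stages skipped")
        tio.write_interface_table(table, out / "interface_table.tsv")
        summary["interface"] = {"n_rows": 0}
        _write_log(config, summary, out)
        return summary

    clusters: dict[str, list[str]] = {}
    if "hypernetwork" in stages:
        sd_mult = float(config["sd_multiplier"])
        n_perm = int(config["n_permutations"])
        te = data["te_matrix"]
        metrics_rows = []
        conn_by_subset = {}
        for subset, null_stage in (("polar", "null_polar"), ("mural", "null_mural")):
            cells = te.obs_in_group(subset)
            sub = te.subset_obs(cells)
            hyper, vals, mean_c, ent = hn.analyze_subset(
                table.te_genes, sub, sd_multiplier=sd_mult
            )
            null = hn.permutation_null(
                sub,
                None,
                set_size=len(set(table.te_genes)),
                n_permutations=n_perm,
                seed=stage_seed(seed, null_stage),
                sd_multiplier=sd_mult,
            )
            rel_ent = float(ent - np.nanmedian(null.entropy_samples)) if n_perm else None
            cluster = hyper.central_cluster
            clusters[subset] = cluster
            conn_by_subset[subset] = vals
            genes_linked = hn.connected_gene_set(hyper, cluster)
            _fmt(hyper.M, out / f"M_{subset}.tsv", index_label="gene")
            _fmt(hyper.H.loc[hyper.row_order, hyper.row_order], out / f"H_{subset}.tsv",
                 index_label="gene")
            (out / f"connected_genes_{subset}.txt").write_text(
                "".join(f"{g}\n" for g in genes_linked)
            )
            _fmt(
                pd.DataFrame(
                    {
                        "connectivity": null.connectivity_samples,
                        "entropy": null.entropy_samples,
                    }
                ),
                out / f"null_{subset}.tsv",
                index=False,
            )
            metrics_rows.append(
                {
                    "subset": subset,
                    "cluster_size": len(cluster),
                    "mean_connectivity": mean_c,
                    "entropy_bits": ent,
                    "relative_entropy": rel_ent,
                    "n_connected_genes": len(genes_linked),
                }
            )
        p_conn, direction = hn.rank_sum_compare(
            conn_by_subset["polar"], conn_by_subset["mural"]
        )
        mdf = pd.DataFrame(metrics_rows)
        _fmt(mdf, out / "hypernetwork_metrics.tsv", index=False)
        summary["hypernetwork"] = {
            "metrics": metrics_rows,
            "connectivity_rank_sum_p": p_conn,
            "connectivity_direction": direction,
        }
        membership = {}
        for _, row in table.rows.iterrows():
            te_g = row["te_gene"]
            in_p, in_m = te_g in clusters.get("polar", []), te_g in clusters.get("mural", [])
            membership[(row["eec_gene"], te_g)] = (
                "polar_and_mural" if in_p and in_m
                else "polar" if in_p
                else "mural" if in_m
                else "neither"
            )
        table = table.with_updates("cluster_membership", membership)

    cluster_genes = sorted(set(clusters.get("polar", [])) | set(clusters.get("mural", [])))
    if not cluster_genes:
        cluster_genes = sorted(set(table.te_genes))

    if "classify" in stages:
        s = config.get("simulate") or {}
        frac_inf = float(s.get("informative_fraction", 0.8))
        n_inf = int(round(frac_inf * len(cluster_genes)))
        informative = set(cluster_genes[:n_inf])
        bulk, _ = sim.generate_tsc_stb_bulk(
            cluster_genes,
            n_per_group=int(s.get("n_per_group", 4)),
            informative_genes=informative,
            effect_sd=float(s.get("stb_effect_sd", 3.0)),
            seed=stage_seed(seed, "tsc_stb"),
        )
        importance = boruta_classify(
            np.log1p(bulk.values),
            bulk.obs_groups.loc[bulk.obs_ids].to_numpy(),
            n_iterations=int(config["rf_iterations"]),
            seed=stage_seed(seed, "boruta"),
        )
        _fmt(importance.summary, out / "importance_table.tsv", index_label="gene")
        table = annotate_interface(table, importance, expressed_genes=set(cluster_genes))
        counts = importance.summary["status"].value_counts().to_dict()
        summary["classify"] = {"status_counts": counts}

    if "velocity" in stages:
        s = config.get("simulate") or {}
        vm, _ = sim.generate_velocity_matrix(
            cluster_genes,
            cells_per_day_subset=int(s.get("cells_per_day_subset", 20)),
            dynamic_genes=set(cluster_genes[: max(1, len(cluster_genes) // 2)]),
            amplitude=float(s.get("velocity_amplitude", 1.0)),
            seed=stage_seed(seed, "velocity"),
        )
        heat, ann = velocity_heatmap(vm, cluster_genes)
        _fmt(heat, out / "velocity_heatmap.tsv", index_label="gene")
        _fmt(ann, out / "velocity_annotation.tsv", index_label="track")
        summary["velocity"] = {"n_genes": heat.shape[0], "n_cells": heat.shape[1]}

    tio.write_interface_table(table, out / "interface_table.tsv")
    summary["interface"] = summarize_interface(table)
    if data["truth"] is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(data["truth"], fh, indent=1, sort_keys=True)
    _write_log(config, summary, out)
    return summary


def _write_log(config: dict, summary: dict, out: Path) -> None:
    log = {
        "config": config,
        "stage_seeds": {s: stage_seed(int(config["seed"]), s) for s in STAGE_OFFSETS},
        "summary": summary,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
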