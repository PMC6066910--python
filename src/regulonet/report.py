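"""Marker z-score panels, network export, and the end-to-end pipeline.

Covers the reporting surface of the analysis: row-standardized expression
heatmap matrices for marker gene panels (HE vs non-HE discriminating genes
by default), export of regulatory networks and category graphs to
Cytoscape-readable formats (GraphML, SIF, node/edge TSV), and a YAML-driven
pipeline runner that chains simulate/load → normalize → DE → regulon
scoring → GO scoring → exports with a deterministic run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    DEResult,
    estimate_size_factors,
    load_counts,
    normalize_counts,
    run_contrast,
    write_de_results,
)
from .go import (
    build_category_graph,
    category_scores_to_frame,
    go_universe,
    load_annotations,
    score_categories,
)
from .regulon import (
    build_network,
    load_interactions,
    score_contrast,
    scores_to_frame,
)
from . import synthetic

logger = logging.getLogger(__name__)

#: HE / non-HE discriminating marker genes shipped as the default panels
MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "HE": ("RHAG", "GFI1", "RUNX1", "NTS", "BMPER"),
    "nonHE": ("SOX17", "COL15A1", "CAV1", "SCG5", "EMCN"),
}


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate genes")


@dataclass
class ZMatrix:
    """Row-standardized expression for a marker panel.

    ``values`` is genes x samples with each non-constant row at mean 0 and
    sample SD 1 (ddof=1); constant rows are all-zero and listed in
    ``constant_genes``. Panel genes absent from the expression matrix are
    listed in ``missing_genes`` rather than silently dropped.
    """

    values: pd.DataFrame
    panel: str
    missing_genes: list[str] = field(default_factory=list)
    constant_genes: list[str] = field(default_factory=list)


def row_zscore(expr: pd.DataFrame, panel: MarkerPanel) -> ZMatrix:
    """Per-gene z-scores (x - row mean) / row sample SD across samples."""
    if expr.shape[1] < 2:
        raise ValueError("row z-scores need >=2 samples")
    present = [g for g in panel.genes if g in expr.index]
    missing = [g for g in panel.genes if g not in expr.index]
    if missing:
        logger.warning("panel %s: %d gene(s) missing: %s", panel.name, len(missing), missing)
    sub = expr.loc[present].astype(float)
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    constant = sds <= 0
    safe_sd = sds.where(~constant, 1.0)
    z = sub.sub(means, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    return ZMatrix(
        values=z,
        panel=panel.name,
        missing_genes=missing,
        constant_genes=list(sub.index[constant]),
    )


# ---------------------------------------------------------------------------
# network export


def export_network(graph: nx.Graph, format: str, path: str | Path) -> list[Path]:
    """Export a regulatory network or category graph.

    ``graphml`` round-trips all node/edge attributes; ``sif`` carries
    topology only (orphan nodes get their own line); ``node_edge_tsv``
    writes ``<stem>.nodes.tsv`` / ``<stem>.edges.tsv`` with all attributes.
    """
    path = Path(path)
    if format == "graphml":
        # GraphML types attributes per key; NaN floats are dropped so a node
        # without a fold change simply lacks the attribute
        clean = graph.copy()
        for _, attrs in clean.nodes(data=True):
            for key, value in list(attrs.items()):
                if isinstance(value, float) and math.isnan(value):
                    del attrs[key]
        nx.write_graphml(clean, path, named_key_ids=True)
        return [path]
    if format == "sif":
        relation = "regulates" if graph.is_directed() else "shares"
        with open(path, "w") as fh:
            linked = set()
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\t{relation}\t{v}\n")
                linked |= {u, v}
            for node in sorted(set(graph.nodes()) - linked):
                fh.write(f"{node}\n")
        return [path]
    if format == "node_edge_tsv":
        stem = path.with_suffix("") if path.suffix else path
        nodes_path = Path(f"{stem}.nodes.tsv")
        edges_path = Path(f"{stem}.edges.tsv")
        node_rows = [{"node": n, **attrs} for n, attrs in sorted(graph.nodes(data=True))]
        pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
        edge_rows = [
            {"source": u, "target": v, **attrs} for u, v, attrs in sorted(graph.edges(data=True))
        ]
        cols = ["source", "target"]
        pd.DataFrame(edge_rows, columns=cols + sorted(
            {k for _, _, a in graph.edges(data=True) for k in a}
        )).to_csv(edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format: {format!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML export back (attribute types restored by networkx)."""
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# pipeline


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"seed", "output_dir", "simulate", "inputs", "annotations", "contrasts", "thresholds"}
_THRESHOLD_KEYS = {
    "fdr", "lfc", "pseudocount", "select_alpha", "min_overlap", "min_odds_ratio",
    "min_regulon_size", "size_category_lfc", "display_q", "min_category_size",
}
_SIMULATE_KEYS = {"preset", "n_tfs", "n_targets", "mean_regulon_size", "regulon_overlap"}


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown config key in {where}: {sorted(unknown)[0]!r}")


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(config, _TOP_KEYS, "top level")
    _check_keys(config.get("thresholds", {}) or {}, _THRESHOLD_KEYS, "thresholds")
    if "simulate" in config and "inputs" in config:
        raise ConfigError("config sets both 'simulate' and 'inputs'")
    if "simulate" not in config and "inputs" not in config:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")
    return config


def _simulate_inputs(block: Mapping[str, Any], seed: int):
    _check_keys(block or {}, _SIMULATE_KEYS, "simulate")
    preset = (block or {}).get("preset", "default")
    studies = {
        "default": synthetic.default_study,
        "global_null": synthetic.null_study,
        "recovery": synthetic.recovery_study,
    }
    if preset not in studies:
        raise ConfigError(f"unknown simulate preset: {preset!r}")
    db, sim_config = studies[preset](seed)
    counts, truth = synthetic.simulate_counts(db, sim_config)
    contrasts = {
        c.contrast_id: {"group_a": dict(c.group_a), "group_b": dict(c.group_b)}
        for c in sim_config.contrasts
    }
    return db, counts, truth, contrasts


def run_pipeline(config_path: str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the full analysis described by a YAML config; return outdir.

    Stages: simulate (or load) inputs → size factors → per-contrast DE →
    regulon scoring + network export → GO category scoring + category graph
    → marker z-score panels → manifest.json. Identical config and seed give
    identical artifact contents.
    """
    config = load_config(config_path)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "regulonet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = dict(config.get("thresholds", {}) or {})
    manifest: dict[str, Any] = {
        "package": "regulonet",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    truth = None
    if "simulate" in config:
        logger.info("stage simulate: preset %s", (config["simulate"] or {}).get("preset", "default"))
        db, counts, truth, contrasts = _simulate_inputs(config["simulate"], seed)
        fixture_dir = outdir / "inputs"
        synthetic.write_fixtures(db, counts, truth, fixture_dir)
        annotations = synthetic.generate_annotation_table(list(counts.genes), seed=seed)
    else:
        inputs = config["inputs"]
        _check_keys(inputs, {"interactions", "counts", "metadata", "annotations"}, "inputs")
        for key in ("interactions", "counts", "metadata"):
            if key not in inputs:
                raise ConfigError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input file not found: {inputs[key]}")
        db = load_interactions(inputs["interactions"])
        counts = load_counts(inputs["counts"], inputs["metadata"])
        annotations = (
            load_annotations(inputs["annotations"]) if "annotations" in inputs else None
        )
        contrasts = config.get("contrasts") or {}
        if not contrasts:
            raise ConfigError("config needs a 'contrasts' block when loading inputs")
    if "annotations" in config:
        annotations = load_annotations(config["annotations"])
    if "contrasts" in config and config["contrasts"]:
        contrasts = config["contrasts"]

    manifest["stages"]["inputs"] = {
        "n_genes": int(counts.counts.shape[0]),
        "n_samples": int(counts.counts.shape[1]),
        "n_interactions": len(db),
        "n_regulators": len(db.regulators),
    }

    estimate_size_factors(counts).to_csv(outdir / "size_factors.tsv", sep="\t")
    norm = normalize_counts(counts)

    de_results: dict[str, DEResult] = {}
    all_scores = []
    all_categories = []
    for contrast_id in sorted(contrasts):
        selectors = contrasts[contrast_id]
        _check_keys(selectors, {"group_a", "group_b"}, f"contrast {contrast_id!r}")
        logger.info("stage de: contrast %s", contrast_id)
        de = run_contrast(
            counts,
            selectors["group_a"],
            selectors["group_b"],
            contrast_id=contrast_id,
            pseudocount=float(thresholds.get("pseudocount", 1.0)),
            fdr_threshold=float(thresholds.get("fdr", 0.05)),
            lfc_threshold=float(thresholds.get("lfc", 1.0)),
        )
        de_results[contrast_id] = de

        scores = score_contrast(
            db,
            de,
            min_regulon_size=int(thresholds.get("min_regulon_size", 3)),
            select_alpha=float(thresholds.get("select_alpha", 0.05)),
            min_overlap=int(thresholds.get("min_overlap", 3)),
            min_odds_ratio=float(thresholds.get("min_odds_ratio", 2.0)),
        )
        all_scores.append(scores_to_frame(scores))
        network = build_network(
            db, scores, de,
            size_category_lfc=float(thresholds.get("size_category_lfc", 0.585)),
        )
        export_network(network, "graphml", outdir / f"network_{contrast_id}.graphml")
        export_network(network, "sif", outdir / f"network_{contrast_id}.sif")
        export_network(network, "node_edge_tsv", outdir / f"network_{contrast_id}")

        cat_scores = []
        if annotations is not None and annotations.gene_to_categories:
            cat_scores = score_categories(
                de, annotations,
                min_category_size=int(thresholds.get("min_category_size", 3)),
            )
            all_categories.append(category_scores_to_frame(cat_scores))
            graph = build_category_graph(
                cat_scores, annotations, go_universe(de, annotations),
                display_q=float(thresholds.get("display_q", 0.05)),
            )
            export_network(graph, "graphml", outdir / f"categories_{contrast_id}.graphml")
            export_network(graph, "node_edge_tsv", outdir / f"categories_{contrast_id}")

        manifest["stages"][contrast_id] = {
            "n_tested": int(de.table.shape[0]),
            "n_untested": len(de.untested),
            "n_up": len(de.up_set),
            "n_down": len(de.down_set),
            "n_nc": len(de.gene_set("nc")),
            "n_regulons_scored": len(scores),
            "n_regulons_selected": sum(s.selected for s in scores),
            "n_network_nodes": network.number_of_nodes(),
            "n_categories_scored": len(cat_scores),
        }

    write_de_results(de_results.values(), outdir / "de_results.tsv")
    if all_scores:
        pd.concat(all_scores, ignore_index=True).to_csv(
            outdir / "regulon_scores.tsv", sep="\t", index=False
        )
    if all_categories:
        pd.concat(all_categories, ignore_index=True).to_csv(
            outdir / "category_scores.tsv", sep="\t", index=False
        )

    for name, genes in MARKER_PANELS.items():
        z = row_zscore(norm, MarkerPanel(name, genes))
        z.values.rename_axis("gene").to_csv(outdir / f"zscore_{name}.tsv", sep="\t")
        (outdir / f"zscore_{name}.missing.txt").write_text(
            "\n".join(z.missing_genes) + ("\n" if z.missing_genes else "")
        )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return outdir
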