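"""End-to-end orchestration of the three-step integration strategy.

1. Per omics layer, Random-Forest regression of the trait with a
   permutation null; keep layers whose OOB R^2 clears the null gate and,
   within them, the features whose impurity importance clears the pooled
   null threshold. Refit on each significant subset and on the combined
   subset across layers.
2. When genotypes are available, scan the trait and every significant
   feature for QTLs with permutation genome-wide thresholds, classify
   cis/trans, and keep one representative feature per layer per linkage
   group that carries a trait QTL (highest RF importance). Refit on the
   representatives.
3. Build a lasso-regularized partial-correlation network over the trait
   plus representatives.

Without genotypes the QTL stages are skipped (logged) and the network is
built on the top-importance features per layer instead ("no-genetics"
mode).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datasets import StudyBundle
from .io import AnalysisConfig, align_samples
from .network import (
    build_network,
    export_network,
    fit_graphical_lasso,
    precision_to_partial,
    select_penalty,
    standardize,
)
from .qtl import (
    QTLCall,
    call_qtls,
    classify_cis_trans,
    genomewide_threshold,
    scan_features,
    select_representatives,
)
from .rf import (
    RFParams,
    combine_layers,
    fit_random_forest,
    permutation_null,
    refit_on_selection,
    select_significant,
)

logger = logging.getLogger(__name__)

__all__ = ["LayerResult", "PipelineReport", "run_pipeline", "write_report"]


@dataclass
class LayerResult:
    layer: str
    oob_r2_all: float
    model_significant: bool
    n_significant: int
    oob_r2_significant: float  # NaN when not significant
    r2_threshold: float
    importance_threshold: float
    significant_features: pd.DataFrame


@dataclass
class PipelineReport:
    trait: str
    layers: list[LayerResult]
    combined_r2: float
    combined_n: int
    representative_r2: float
    representative_entries: pd.DataFrame
    trait_qtl_groups: list[int]
    regulation_counts: dict[str, int]
    network_nodes: int
    network_edges: int
    network_penalty: float
    no_genetics_mode: bool
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "layers": [
                {
                    "layer": r.layer,
                    "oob_r2_all": r.oob_r2_all,
                    "model_significant": r.model_significant,
                    "n_significant": r.n_significant,
                    "oob_r2_significant": r.oob_r2_significant,
                    "r2_threshold": r.r2_threshold,
                    "importance_threshold": r.importance_threshold,
                    "significant_features": r.significant_features.to_dict("records"),
                }
                for r in self.layers
            ],
            "combined_r2": self.combined_r2,
            "combined_n": self.combined_n,
            "representative_r2": self.representative_r2,
            "representatives": self.representative_entries.to_dict("records"),
            "trait_qtl_groups": self.trait_qtl_groups,
            "regulation_counts": self.regulation_counts,
            "network": {
                "nodes": self.network_nodes,
                "edges": self.network_edges,
                "penalty": self.network_penalty,
            },
            "no_genetics_mode": self.no_genetics_mode,
            "provenance": self.provenance,
        }


def _derive_seed(base: int, offset: int) -> int:
    return int((base * 100003 + offset) % (2**31 - 1))


def run_pipeline(
    bundle: StudyBundle, config: AnalysisConfig, out_dir: str | Path | None = None
):
    """Run the full strategy; returns (PipelineReport, networkx graph).

    Intermediate artifacts (selection tables, QTL calls, the network) are
    written under ``out_dir`` when given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    bundle = align_samples(bundle, config.trait)
    y = bundle.traits[config.trait]
    rf_params = config.rf

    # --- stage 1: per-layer RF selection ----------------------------------
    layer_results: list[LayerResult] = []
    sig_sets = []
    for i, layer in enumerate(bundle.layers):
        logger.info("stage RF: layer %s (%d features)", layer.layer, layer.n_features)
        params_i = RFParams(
            rf_params.n_trees, rf_params.max_features, rf_params.min_node_size,
            _derive_seed(config.seed, 10 + i),
        )
        fit = fit_random_forest(layer, y, params_i)
        null = permutation_null(
            layer, y, params_i, n_perm=config.n_perm,
            seed=_derive_seed(config.seed, 100 + i),
        )
        sel = select_significant(
            fit, null, config.alpha_feature, config.alpha_model,
            per_feature=config.per_feature_null,
        )
        sig_sets.append(sel)
        refit_r2 = float("nan")
        if sel.model_significant and len(sel) > 0:
            refit_r2 = refit_on_selection(layer, sel, y, params_i).oob_r2
        layer_results.append(
            LayerResult(
                layer.layer, fit.oob_r2, sel.model_significant, len(sel), refit_r2,
                sel.r2_threshold, sel.importance_threshold, sel.features,
            )
        )
        if out is not None and len(sel):
            tab = sel.features.assign(layer=layer.layer, threshold=sel.importance_threshold)
            tab.to_csv(out / f"selection_{layer.layer}.tsv", sep="\t", index=False)

    # --- combined refit ----------------------------------------------------
    combined_r2, combined_n = float("nan"), 0
    nonempty = [s for s in sig_sets if len(s) > 0]
    if nonempty:
        combined = combine_layers(nonempty, bundle.layers)
        combined_n = combined.n_features
        combined_params = RFParams(
            rf_params.n_trees, rf_params.max_features, rf_params.min_node_size,
            _derive_seed(config.seed, 7),
        )
        combined_r2 = fit_random_forest(combined, y, combined_params).oob_r2

    # --- stage 2: QTL co-localization --------------------------------------
    no_genetics = not bundle.has_genetics
    trait_groups: list[int] = []
    regulation_counts: dict[str, int] = {}
    representative_entries = pd.DataFrame(
        columns=["layer", "linkage_group", "feature_id", "importance", "peak_lod"]
    )
    representative_r2 = float("nan")
    rep_ids: list[str] = []

    if no_genetics:
        logger.info("no genotypes in bundle: skipping QTL and representative stages")
        # fall back to top-importance features per layer for the network
        for sel in nonempty:
            rep_ids.extend(sel.features.nlargest(3, "importance")["feature_id"])
    else:
        trait_scan_all = scan_features(
            bundle.traits[[config.trait]], bundle.genotypes, bundle.gmap
        )
        trait_scan = trait_scan_all[config.trait]
        trait_thr = genomewide_threshold(
            y, bundle.genotypes, bundle.gmap, n_perm=config.qtl_n_perm,
            alpha=config.qtl_alpha, seed=_derive_seed(config.seed, 200),
        )
        trait_calls = call_qtls(trait_scan, trait_thr, bundle.gmap)
        trait_groups = sorted({c.linkage_group for c in trait_calls})
        logger.info("trait QTLs on linkage groups %s (threshold %.2f)", trait_groups, trait_thr)

        annotation = bundle.annotation_map()
        feature_calls: dict[str, list[QTLCall]] = {}
        call_rows = []
        for sel, layer in zip(sig_sets, bundle.layers):
            if len(sel) == 0:
                continue
            sub = layer.restrict(sel.feature_ids).to_sample_matrix()
            scans = scan_features(sub, bundle.genotypes, bundle.gmap)
            for k, fid in enumerate(sel.feature_ids):
                thr = genomewide_threshold(
                    sub[fid], bundle.genotypes, bundle.gmap,
                    n_perm=config.qtl_n_perm, alpha=config.qtl_alpha,
                    seed=_derive_seed(config.seed, 300 + k),
                )
                calls = call_qtls(scans[fid], thr, bundle.gmap)
                for c in calls:
                    c.regulation = classify_cis_trans(c, annotation)
                    regulation_counts[c.regulation] = regulation_counts.get(c.regulation, 0) + 1
                    call_rows.append(
                        (fid, sel.layer, c.linkage_group, c.peak_marker, c.peak_lod,
                         thr, c.support_interval[0], c.support_interval[1], c.regulation)
                    )
                feature_calls[fid] = calls
        if out is not None:
            pd.DataFrame(
                call_rows,
                columns=["feature_id", "layer", "linkage_group", "peak_marker",
                         "peak_lod", "threshold", "interval_lo", "interval_hi",
                         "regulation"],
            ).to_csv(out / "qtl_calls.tsv", sep="\t", index=False)

        reps = select_representatives(nonempty, feature_calls, trait_calls, config.trait)
        representative_entries = reps.entries
        rep_ids = reps.feature_ids
        if out is not None:
            reps.entries.to_csv(out / "representatives.tsv", sep="\t", index=False)

    # refit on representatives (or on the fallback set)
    feature_frames = {l.layer: l.to_sample_matrix() for l in bundle.layers}
    if rep_ids:
        all_features = pd.concat(feature_frames.values(), axis=1)
        rep_params = RFParams(
            rf_params.n_trees, rf_params.max_features, rf_params.min_node_size,
            _derive_seed(config.seed, 8),
        )
        representative_r2 = refit_on_selection(all_features, rep_ids, y, rep_params).oob_r2

    # --- stage 3: network ---------------------------------------------------
    graph = None
    net_nodes, net_edges, net_penalty = 0, 0, float("nan")
    if rep_ids:
        all_features = pd.concat(feature_frames.values(), axis=1)
        data = pd.concat([y.rename(config.trait), all_features[rep_ids]], axis=1)
        data = data.loc[:, ~data.columns.duplicated()]
        layer_of = {
            fid: l.layer for l in bundle.layers for fid in l.feature_ids
        }
        std = standardize(data)
        penalty, score_table = select_penalty(
            std, criterion=config.penalty_criterion, grid=config.penalty_grid,
            seed=_derive_seed(config.seed, 9),
        )
        est = fit_graphical_lasso(std, penalty)
        rho = precision_to_partial(est.precision)
        nodes = [(config.trait, "trait")] + [
            (fid, layer_of.get(fid, "matrix")) for fid in data.columns[1:]
        ]
        graph = build_network(rho, nodes, penalty=penalty)
        net_nodes, net_edges, net_penalty = graph.number_of_nodes(), graph.number_of_edges(), penalty
        if out is not None:
            export_network(graph, out / "network.graphml", "graphml")
            export_network(graph, out / "network_edges.tsv", "edge_tsv")
            score_table.to_csv(out / "penalty_scores.tsv", sep="\t", index=False)

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha_model": config.alpha_model,
        "alpha_feature": config.alpha_feature,
        "qtl_alpha": config.qtl_alpha,
        "qtl_n_perm": config.qtl_n_perm,
        "version": __version__,
        "n_samples": len(y),
    }
    report = PipelineReport(
        trait=config.trait,
        layers=layer_results,
        combined_r2=combined_r2,
        combined_n=combined_n,
        representative_r2=representative_r2,
        representative_entries=representative_entries,
        trait_qtl_groups=trait_groups,
        regulation_counts=regulation_counts,
        network_nodes=net_nodes,
        network_edges=net_edges,
        network_penalty=net_penalty,
        no_genetics_mode=no_genetics,
        provenance=provenance,
    )
    return report, graph


def _pct(x: float) -> str:
    """Display helper: R^2 as a whole percentage, clipped at 0 for display."""
    if np.isnan(x):
        return "NA"
    return f"{max(x, 0.0) * 100:.0f} %"


def write_report(report: PipelineReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as JSON plus a human-readable summary table.

    The table mirrors the classical layout: one row per layer with the
    all-features OOB R^2, the significant-subset R^2 with the subset size
    in brackets, and NS for layers whose model failed the permutation gate;
    then the combined and representative rows.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, default=float))

    lines = [f"Trait: {report.trait}", ""]
    lines.append(f"{'Layer':<12}{'All features':<16}{'Significant subset':<22}")
    for r in report.layers:
        if r.model_significant:
            all_cell = _pct(r.oob_r2_all)
            sig_cell = f"{_pct(r.oob_r2_significant)} ({r.n_significant})"
        else:
            all_cell = f"NS (alpha = {report.provenance['alpha_model']})"
            sig_cell = "NS"
        lines.append(f"{r.layer:<12}{all_cell:<16}{sig_cell:<22}")
    lines.append("")
    if report.combined_n:
        lines.append(f"Combined significant features: {_pct(report.combined_r2)} ({report.combined_n})")
    if not np.isnan(report.representative_r2):
        counts = report.representative_entries.groupby("layer").size().to_dict()
        count_str = " + ".join(f"{k}({v})" for k, v in sorted(counts.items()))
        total = len(report.representative_entries)
        lines.append(
            f"Representatives (max one QTL per layer per chromosome): "
            f"{_pct(report.representative_r2)} ({count_str}; total = {total})"
        )
    if report.no_genetics_mode:
        lines.append("NOTE: no genotypes supplied; QTL stages skipped (no-genetics mode)")
    lines.append(
        f"Network: {report.network_nodes} nodes, {report.network_edges} edges, "
        f"penalty = {report.network_penalty}"
    )
    txt_path = out / "report.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "table": txt_path}
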