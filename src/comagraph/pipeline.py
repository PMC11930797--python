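"""End-to-end orchestration: simulate -> connectivity -> graph -> stats -> predict.

Each stage writes its outputs (delimited text) and a log of routing and
exclusion decisions; the whole run is deterministic given the config seed,
and the resolved config is written next to the outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import PipelineConfig, save_config
from .connectivity import connectivity_from_timeseries, ConnectivityMatrix
from .graphs import compute_graph_metrics
from .predict import compare_prediction_models
from .stats import (
    compare_metrics_between_groups,
    eeg_category_tests,
    metric_correlations,
    nodewise_outcome_correlation,
)
from .synthetic import generate_cohort

logger = logging.getLogger("comagraph")

__all__ = [
    "run_simulate",
    "run_connectivity",
    "run_graph",
    "run_stats",
    "run_predict",
    "run_pipeline",
]

METRIC_COLS = ("whole_brain_fc", "clustering_auc", "global_efficiency_auc", "modularity_auc")


def _stage(name: str, subject: str | None = None):
    where = f"stage {name}" + (f", subject {subject}" if subject else "")
    logger.info("running %s", where)
    return where


def run_simulate(config: PipelineConfig) -> Path:
    _stage("simulate")
    records = generate_cohort(config.cohort)
    return cio.write_cohort(records, config.input_dir)


def run_connectivity(config: PipelineConfig) -> pd.DataFrame:
    """Per-subject connectivity matrices + whole-brain FC summary CSV."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir) / "connectivity"
    outdir.mkdir(parents=True, exist_ok=True)
    meta = cio.read_metadata(indir / "metadata.csv")
    rows = []
    for sid in meta["subject_id"]:
        where = _stage("connectivity", sid)
        try:
            ts, report = cio.read_subject_table(indir / f"{sid}_timeseries.tsv")
            conn = connectivity_from_timeseries(ts, discard_first=config.discard_first_k)
        except ValueError as exc:
            raise RuntimeError(f"{where}: {exc}") from exc
        cio.write_matrix(outdir / f"{sid}_connectivity.tsv", conn.weights)
        from .connectivity import whole_brain_fc
        rows.append({
            "subject_id": sid,
            "n_nodes": report["n_nodes"],
            "whole_brain_fc": whole_brain_fc(conn, include_zeros=config.fc_include_zeros),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "whole_brain_fc.csv", index=False)
    return df


def run_graph(config: PipelineConfig) -> pd.DataFrame:
    """Graph-measure AUC surrogates per subject; metrics + nodewise CSVs."""
    outdir = Path(config.output_dir)
    conndir = outdir / "connectivity"
    meta = cio.read_metadata(Path(config.input_dir) / "metadata.csv")
    grid = config.density_grid()
    rows, nodewise_rows = [], []
    for sid in meta["subject_id"]:
        where = _stage("graph", sid)
        try:
            conn = ConnectivityMatrix(cio.read_matrix(conndir / f"{sid}_connectivity.tsv"))
            ms = compute_graph_metrics(
                conn, grid, gamma=config.gamma, n_restarts=config.n_restarts,
                seed=config.seed, binarize=config.binarize,
            )
        except (ValueError, OSError) as exc:
            raise RuntimeError(f"{where}: {exc}") from exc
        rows.append({
            "subject_id": sid,
            "whole_brain_fc": ms.whole_brain_fc,
            "clustering_auc": ms.clustering_auc,
            "global_efficiency_auc": ms.global_efficiency_auc,
            "modularity_auc": ms.modularity_auc,
        })
        nodewise_rows.append([sid, *ms.nodewise])
    metrics = pd.DataFrame(rows)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    n_nodes = len(nodewise_rows[0]) - 1
    pd.DataFrame(
        nodewise_rows, columns=["subject_id", *(f"node{i}" for i in range(n_nodes))]
    ).to_csv(outdir / "nodewise.csv", index=False)
    return metrics


def run_stats(config: PipelineConfig) -> dict:
    """Group comparisons, metric correlations, nodewise and EEG contrasts."""
    _stage("stats")
    outdir = Path(config.output_dir)
    meta = cio.read_metadata(Path(config.input_dir) / "metadata.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    nodewise = pd.read_csv(outdir / "nodewise.csv")

    comparisons = compare_metrics_between_groups(metrics, meta)
    comparisons.to_csv(outdir / "group_comparisons.csv", index=False)

    r, p = metric_correlations(metrics[list(METRIC_COLS)])
    r.to_csv(outdir / "metric_correlations_r.csv")
    p.to_csv(outdir / "metric_correlations_p.csv")

    merged = nodewise.merge(meta[["subject_id", "outcome"]], on="subject_id")
    node_cols = [c for c in nodewise.columns if c != "subject_id"]
    results, counts = nodewise_outcome_correlation(
        merged[node_cols].to_numpy(), merged["outcome"].to_numpy()
    )
    pd.DataFrame([res.__dict__ for res in results]).to_csv(
        outdir / "nodewise_outcome.csv", index=False
    )

    merged_m = metrics.merge(meta, on="subject_id")
    eeg = {}
    for col in METRIC_COLS:
        by_cat = {
            cat: grp[col].to_numpy()
            for cat, grp in merged_m.groupby("eeg_category")
        }
        try:
            eeg[col] = eeg_category_tests(by_cat, alpha=config.alpha)
        except ValueError as exc:
            logger.warning("EEG contrast skipped for %s: %s", col, exc)
    eeg_rows = []
    for col, res in eeg.items():
        eeg_rows.append({"metric": col, "contrast": "omnibus",
                         "statistic": res["kruskal_h"], "p": res["kruskal_p"]})
        for pw in res["pairwise"]:
            eeg_rows.append({"metric": col,
                             "contrast": f"{pw['categories'][0]}v{pw['categories'][1]}",
                             "statistic": float("nan"), "p": pw["p_fdr"]})
    pd.DataFrame(eeg_rows).to_csv(outdir / "eeg_contrasts.csv", index=False)
    return {"comparisons": comparisons, "metric_r": r,
            "nodewise_counts": counts, "eeg": eeg}


def run_predict(config: PipelineConfig) -> pd.DataFrame:
    _stage("predict")
    outdir = Path(config.output_dir)
    meta = cio.read_metadata(Path(config.input_dir) / "metadata.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    models = compare_prediction_models(meta, metrics)
    models.to_csv(outdir / "model_comparison.csv", index=False)
    return models


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> dict:
    """Execute all stages; returns the in-memory result bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config_resolved.yaml")
    handler = logging.FileHandler(outdir / "pipeline.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if simulate:
            run_simulate(config)
        fc = run_connectivity(config)
        metrics = run_graph(config)
        stats = run_stats(config)
        models = run_predict(config)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {"fc": fc, "metrics": metrics, "stats": stats, "models": models}
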