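"""End-to-end orchestration: load/simulate -> QC -> calibrate -> normalize
-> quantify -> statistics -> classify, with report rendering.

Every stage emits its table(s) into the output directory; a manifest
records the full configuration (defaults included), seeds, package
versions and a config hash so a run can be reproduced bit-identically
within one installation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import apply_calibration, ipc_factors
from .classifier import (
    ClassifierReport,
    run_design_cross_cohort,
    run_design_forest,
    run_design_logistic,
)
from .config import PipelineConfig
from .errors import EvmirError
from .expression import (
    ExpressionTable,
    ddcq_fold_change,
    fold_regulation,
    group_fold_change_stats,
    kruskal_wallis,
    mann_whitney_posthoc,
    mask_outliers,
)
from .normalization import normalize_dcq, normfinder_stability, pairwise_variation
from .panel import FINGERPRINT_TARGETS
from .plate_io import RunData, build_cq_matrix, load_run
from .quality_control import QCConfig, run_qc
from .synthetic import GroundTruth, SyntheticDesign, corrupt_run, simulate_run


@dataclass
class PipelineResult:
    """In-memory bundle of every report surface the pipeline produces."""

    config: PipelineConfig
    run: RunData
    truth: Optional[GroundTruth]
    qc_table: pd.DataFrame
    calibration: dict
    stability: pd.DataFrame
    pairwise_v: dict
    expression: ExpressionTable
    fold_regulation_table: pd.DataFrame
    statistics_table: pd.DataFrame
    classifier_reports: dict[str, ClassifierReport] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def _metrics_row(report: ClassifierReport) -> dict:
    row = {
        "design": report.design_id,
        "seed": report.seed,
        "n_train": report.n_train,
        "n_test": report.n_test,
        "n_features": len(report.features),
        "auc": report.auc,
    }
    row.update(report.metrics)
    row.update(report.confusion)
    return row


def _dcq_features(expr: ExpressionTable, cohorts: tuple[str, str] = ("ALS", "HC")):
    """Complete-case dCq feature table for the two-class designs.

    Per the study design, outliers are NOT removed before classification;
    only samples with a missing fingerprint value are dropped
    (complete-case requirement of the fitters).
    """
    keep = expr.groups.index[expr.groups.isin(cohorts)]
    feats = expr.ddcq.loc[expr.ddcq.index.intersection(keep), list(FINGERPRINT_TARGETS)]
    feats = feats.dropna(axis=0, how="any")
    labels = expr.groups.loc[feats.index]
    return feats, labels


def _acquire_data(config: PipelineConfig):
    mode = config.input_mode()
    if mode == "files":
        run = load_run(config.plates, config.metadata)
        return run, None
    overrides = {}
    syn = config.synthetic
    if syn.cohort_sizes is not None:
        overrides["cohort_sizes"] = syn.cohort_sizes
    if syn.sigma_sample is not None:
        overrides["sigma_sample"] = syn.sigma_sample
    if syn.sigma_noise is not None:
        overrides["sigma_noise"] = syn.sigma_noise
    design = SyntheticDesign(**overrides)
    run, truth = simulate_run(design, seed=syn.seed)
    if syn.corrupt:
        run, truth = corrupt_run(run, design, seed=syn.seed + 1, truth=truth)
    return run, truth


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full pipeline under ``config``.

    With ``write`` the report surfaces are rendered as TSV/JSON into
    ``config.outdir``; the returned :class:`PipelineResult` always holds
    them in memory.
    """
    run, truth = _acquire_data(config)

    matrix = build_cq_matrix(run)
    qc_cfg = QCConfig(
        haemolysis_threshold=config.qc.haemolysis_threshold,
        iqr_k=config.qc.iqr_k,
        spikein_sd_mult=config.qc.spikein_sd_mult,
        low_signal_max_cq=config.qc.low_signal_max_cq,
        exclude_flagged=config.qc.exclude_flagged,
    )
    qc_report = run_qc(matrix, run, qc_cfg)
    if qc_report.excluded_samples:
        matrix.values = matrix.values.drop(index=qc_report.excluded_samples)

    ref_plate = (
        config.reference_plate if config.calibration_mode == "reference_plate" else None
    )
    factors = ipc_factors(run, reference_plate=ref_plate)
    matrix = apply_calibration(matrix, factors)

    groups = dict(zip(run.metadata["sample_id"], run.metadata["cohort"]))
    candidates = sorted(set(config.references) | set(FINGERPRINT_TARGETS))
    stability = normfinder_stability(matrix, groups, candidates)
    v_series = pairwise_variation(matrix, stability.ranked, threshold=config.v_threshold)

    dcq = normalize_dcq(matrix, refs=config.references, targets=list(FINGERPRINT_TARGETS))
    expr = ddcq_fold_change(dcq, groups, control=config.control_cohort)
    expr = mask_outliers(
        expr,
        sd_mult=config.outliers.sd_mult,
        invalid_frac=config.outliers.invalid_frac,
        targets=list(FINGERPRINT_TARGETS),
    )

    stats = group_fold_change_stats(expr)
    means, medians = stats["mean"], stats["median"]
    fr_rows = {}
    fr_rows["ALS_vs_HC"] = fold_regulation(means, "ALS", config.control_cohort)
    for cohort in ("PD", "PLS"):
        if cohort in means.index:
            fr_rows[f"{cohort}_vs_ALS"] = fold_regulation(means, cohort, "ALS")
    fr_table = pd.DataFrame(fr_rows)
    fr_table.index.name = "target"

    kw = kruskal_wallis(expr)
    mw = mann_whitney_posthoc(expr, gate=config.gate_posthoc, kw=kw, alpha=config.alpha)
    stat_rows = []
    for t in expr.fold_change.columns:
        row = {
            "target": t,
            "H": kw.loc[t, "H"],
            "p_kw": kw.loc[t, "p"],
            "median_ALS": medians.loc["ALS", t] if "ALS" in medians.index else np.nan,
            "median_control": medians.loc[config.control_cohort, t],
            "fold_regulation": fr_table.loc[t, "ALS_vs_HC"],
        }
        sub = mw.loc[(mw["target"] == t) & (mw["pair"] == "ALS vs HC")]
        if len(sub):
            row["abs_Z_ALS_vs_HC"] = float(sub["abs_Z"].iloc[0])
            row["p_mw_ALS_vs_HC"] = float(sub["p"].iloc[0])
        row["regulation"] = (
            "Down-regulated" if row["fold_regulation"] < 0 else "Up-regulated"
        )
        stat_rows.append(row)
    stat_table = pd.DataFrame(stat_rows).set_index("target")

    result = PipelineResult(
        config=config,
        run=run,
        truth=truth,
        qc_table=qc_report.table,
        calibration={
            "mode": config.calibration_mode,
            "reference_level": factors.reference_level,
            "corrections": factors.corrections,
        },
        stability=stability.table,
        pairwise_v={
            "v": v_series.v,
            "pass_3_4": v_series.pass_3_4,
            "truncated": v_series.truncated,
            "threshold": v_series.threshold,
        },
        expression=expr,
        fold_regulation_table=fr_table,
        statistics_table=stat_table,
    )

    if config.run_classifiers:
        feats, labels = _dcq_features(expr)
        d = config.designs
        result.classifier_reports["logistic_80_20"] = run_design_logistic(
            feats, labels, fraction=d.logistic_fraction, seed=d.split_seed
        )
        result.classifier_reports["forest_79_21"] = run_design_forest(
            feats,
            labels,
            fraction=d.forest_fraction,
            seed=d.split_seed,
            iterative_removal=d.iterative_removal,
            n_trees=d.n_trees,
        )
        if config.input_mode() == "synthetic":
            # Independent training cohort emulating the earlier 50/50 study.
            train_design = SyntheticDesign(
                cohort_sizes={"ALS": 50, "HC": 50, "PD": 0, "PLS": 0}
            )
            train_run, _ = simulate_run(train_design, seed=config.synthetic.seed + 9000)
            train_expr = _quantify(train_run, config)
            train_feats, train_labels = _dcq_features(train_expr)
            result.classifier_reports["forest_cross_cohort"] = run_design_cross_cohort(
                train_feats,
                train_labels,
                feats,
                labels,
                seed=d.cross_cohort_seed,
                iterative_removal=d.iterative_removal,
                n_trees=d.n_trees,
            )

    if write:
        _write_bundle(result)
    return result


def _quantify(run: RunData, config: PipelineConfig) -> ExpressionTable:
    """Matrix -> calibration -> dCq -> ddCq for an auxiliary cohort."""
    matrix = build_cq_matrix(run)
    matrix = apply_calibration(matrix, ipc_factors(run))
    groups = dict(zip(run.metadata["sample_id"], run.metadata["cohort"]))
    dcq = normalize_dcq(matrix, refs=config.references, targets=list(FINGERPRINT_TARGETS))
    return ddcq_fold_change(dcq, groups, control=config.control_cohort)


def _write_bundle(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = result.outputs

    def tsv(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        out[name] = path

    tsv("qc_report.tsv", result.qc_table)
    qc_json = result.qc_table.reset_index().to_json(orient="records", indent=2)
    (outdir / "qc_report.json").write_text(qc_json)
    out["qc_report.json"] = outdir / "qc_report.json"
    (outdir / "calibration.json").write_text(
        json.dumps(result.calibration, indent=2, sort_keys=True)
    )
    out["calibration.json"] = outdir / "calibration.json"
    tsv("reference_stability.tsv", result.stability)
    (outdir / "pairwise_variation.json").write_text(
        json.dumps(result.pairwise_v, indent=2, sort_keys=True)
    )
    out["pairwise_variation.json"] = outdir / "pairwise_variation.json"
    tsv("fold_regulation.tsv", result.fold_regulation_table)
    tsv("statistics.tsv", result.statistics_table)

    audit = result.expression.outlier_mask
    masked_cells = [
        {"sample_id": s, "target": t}
        for s in audit.index
        for t in audit.columns
        if bool(audit.loc[s, t])
    ]
    (outdir / "outlier_audit.json").write_text(
        json.dumps(
            {
                "masked_cells": masked_cells,
                "invalid_samples": result.expression.invalid_samples,
            },
            indent=2,
        )
    )
    out["outlier_audit.json"] = outdir / "outlier_audit.json"

    if result.classifier_reports:
        panel = pd.DataFrame(
            [_metrics_row(r) for r in result.classifier_reports.values()]
        ).set_index("design")
        tsv("classification_metrics.tsv", panel)
        for name, rep in result.classifier_reports.items():
            if rep.roc_points is not None:
                tsv(f"roc_{name}.tsv", rep.roc_points, index=False)
            if rep.importances is not None:
                tsv(f"gini_{name}.tsv", rep.importances.to_frame())
            if rep.coefficients is not None:
                tsv(f"coefficients_{name}.tsv", rep.coefficients)
            if rep.deviance is not None:
                (outdir / f"deviance_{name}.json").write_text(
                    json.dumps(rep.deviance, indent=2, sort_keys=True)
                )
                out[f"deviance_{name}.json"] = outdir / f"deviance_{name}.json"

    config_json = result.config.model_dump_json(indent=2)
    manifest = {
        "package": "evmir",
        "version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seeds": {
            "synthetic": result.config.synthetic.seed,
            "split": result.config.designs.split_seed,
            "cross_cohort": result.config.designs.cross_cohort_seed,
        },
        "outputs": sorted(str(p.name) for p in out.values()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    out["manifest.json"] = outdir / "manifest.json"


class StageFailure(EvmirError):
    """Raised by the CLI wrapper naming the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
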