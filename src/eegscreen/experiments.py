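"""Experiment orchestration: baseline comparison, connectivity ablation,
top-K feature-selection ablation, and cross-repeat Gini-importance
summaries.

All experiments within a run share the cohort, the preprocessing outputs
and the split plans; only the representation and the model vary, which is
what makes the ablations controlled comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Roster, build_roster, read_recording
from .evaluation import (
    MetricsReport, ProtocolConfig, SegmentDataset, evaluate_split,
    run_repeated_holdout, stratified_subject_split, summarize_repeats,
)
from .features import (
    EstimatorConfig, connectivity_feature_names, extract_features,
    fused_feature_names, spectral_feature_names,
)
from .models import FittedModel, ModelConfig
from .preprocess import PreprocessConfig, preprocess_recording

log = logging.getLogger(__name__)

DEFAULT_K_GRID = (5, 10, 15, 20, 30, 50, 70, 90)

FEATURE_CONDITIONS = ("spectral", "connectivity", "fusion", "raw")


@dataclass
class ExperimentConfig:
    dataset_root: str | Path
    models: tuple[str, ...] = ("et", "mlp")       # nets enabled by config
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    keep_raw: bool = False                         # load raw arrays for nets
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        ks = list(self.k_grid)
        if ks != sorted(set(ks)) or any(k > len(spectral_feature_names())
                                        for k in ks):
            raise ValueError("K grid must be strictly increasing and <= 90")


def prepare_dataset(config: ExperimentConfig) -> tuple[Roster, SegmentDataset]:
    """Read the cohort, preprocess every recording once, extract the fused
    feature table (and optionally stack raw segment arrays)."""
    roster = build_roster(config.dataset_root)
    all_segments = []
    for record in roster.records:
        for ref in record.recordings:
            rec = read_recording(ref.path, subject_key=record.subject_key,
                                 condition=ref.condition)
            accepted, _ = preprocess_recording(rec, config.preprocess)
            all_segments.extend(accepted)
    log.info("preprocessed %d accepted segments from %d subjects",
             len(all_segments), len(roster.records))
    table = extract_features(all_segments, config.estimator)
    meta = table[["subject_key", "condition", "segment_index"]]
    features = table[fused_feature_names()]
    raw = None
    if config.keep_raw:
        raw = np.stack([s.samples for s in all_segments])
    return roster, SegmentDataset(meta=meta, features=features, raw=raw)


def _condition_columns(condition: str) -> list[str]:
    if condition == "spectral":
        return spectral_feature_names()
    if condition == "connectivity":
        return connectivity_feature_names()
    if condition == "fusion":
        return fused_feature_names()
    raise ValueError(f"unknown feature condition {condition!r}")


def run_baselines(roster: Roster, dataset: SegmentDataset,
                  config: ExperimentConfig) -> dict[str, MetricsReport]:
    """Experiment 1: the compact baselines on the eight-channel setup.

    ET and MLP run on spectral features; the conv nets run on raw segments.
    Split plans are a pure function of (roster, fraction, seed), so every
    model sees the identical train/test subject sets within a repeat.
    """
    reports: dict[str, MetricsReport] = {}
    for model_id in config.models:
        if model_id in ("et", "mlp"):
            ds = dataset.select_features(spectral_feature_names())
        else:
            if dataset.raw is None:
                raise ValueError(f"{model_id} needs raw segments "
                                 "(keep_raw=True)")
            ds = dataset
        reports[model_id] = run_repeated_holdout(
            roster, ds, ModelConfig(model_id=model_id),
            config.protocol, keep_fitted=(model_id == "et"),
        )
    return reports


def run_connectivity_ablation(roster: Roster, dataset: SegmentDataset,
                              config: ExperimentConfig
                              ) -> dict[str, MetricsReport]:
    """Experiment 2: ET on spectral / connectivity / fused features plus an
    MLP on the fused representation, all on shared split plans."""
    conditions = [
        ("et_spectral", "et", "spectral"),
        ("et_connectivity", "et", "connectivity"),
        ("et_fusion", "et", "fusion"),
        ("mlp_fusion", "mlp", "fusion"),
    ]
    reports: dict[str, MetricsReport] = {}
    for name, model_id, condition in conditions:
        ds = dataset.select_features(_condition_columns(condition))
        reports[name] = run_repeated_holdout(
            roster, ds, ModelConfig(model_id=model_id), config.protocol,
            keep_fitted=(model_id == "et"),
        )
    return reports


def rank_features_by_importance(fitted_et: FittedModel) -> list[str]:
    """Feature names by descending Gini importance; ties broken by the
    canonical vocabulary order (stable)."""
    imp = fitted_et.feature_importances
    order = np.argsort(-imp.to_numpy(), kind="stable")
    return [imp.index[i] for i in order]


def run_topk_ablation(roster: Roster, dataset: SegmentDataset,
                      config: ExperimentConfig) -> dict[int, MetricsReport]:
    """Experiment 3: per repeat, fit the full spectral ET on training
    subjects, rank by Gini importance, then refit and re-evaluate on the
    top-K columns for each K — in importance-sorted column order, so the
    K=90 run is a reordered (not identical) rerun of the full model.
    """
    spectral = dataset.select_features(spectral_feature_names())
    protocol = config.protocol
    per_k_rows: dict[int, list[dict]] = {k: [] for k in config.k_grid}
    for i in range(protocol.n_repeats):
        plan = stratified_subject_split(
            roster, protocol.test_fraction, protocol.seed_base + i, i
        )
        cfg = ModelConfig(model_id="et", seed=protocol.seed_base + i)
        train_ds = spectral.subset_subjects(plan.train_keys)
        from .evaluation import fit_model_on

        fitted_full = fit_model_on(train_ds, cfg)
        ranking = rank_features_by_importance(fitted_full)
        for k in config.k_grid:
            cols = ranking[:k]          # importance-sorted column order
            ds_k = spectral.select_features(cols)
            metrics, _, _ = evaluate_split(ds_k, plan, cfg, protocol.threshold)
            per_k_rows[k].append(metrics)
    out: dict[int, MetricsReport] = {}
    for k, rows in per_k_rows.items():
        per_repeat = pd.DataFrame(rows)
        out[k] = MetricsReport(per_repeat=per_repeat,
                               summary=summarize_repeats(per_repeat, protocol))
    return out


def topk_table(reports: dict[int, MetricsReport]) -> pd.DataFrame:
    """Per-K summary table (mean/sd/CI of balanced accuracy and AUROC)."""
    rows = []
    for k in sorted(reports):
        s = reports[k].summary
        rows.append({
            "K": k,
            "ba_mean": s.loc["balanced_accuracy", "mean"],
            "ba_sd": s.loc["balanced_accuracy", "sd"],
            "ba_ci_low": s.loc["balanced_accuracy", "ci_low"],
            "ba_ci_high": s.loc["balanced_accuracy", "ci_high"],
            "auroc_mean": s.loc["auroc", "mean"],
            "auroc_sd": s.loc["auroc", "sd"],
        })
    return pd.DataFrame(rows)


def summarize_importance(per_repeat_models: list[FittedModel]
                         ) -> pd.DataFrame:
    """Mean Gini importance per feature across the repeat-level models,
    with descending rank; importances come only from models fitted on
    training subjects."""
    if not per_repeat_models:
        raise ValueError("need at least one fitted model per repeat")
    vocab = per_repeat_models[0].feature_names
    for m in per_repeat_models[1:]:
        if m.feature_names != vocab:
            raise ValueError("inconsistent feature vocabularies across repeats")
    stacked = pd.concat([m.feature_importances for m in per_repeat_models],
                        axis=1)
    table = pd.DataFrame({"mean_importance": stacked.mean(axis=1)})
    table["rank"] = table["mean_importance"].rank(
        ascending=False, method="first").astype(int)
    return table.sort_values("rank")


def summary_to_json(reports: dict[str, MetricsReport]) -> dict:
    """Mean/sd/CI per metric per model, mirroring the benchmark tables."""
    return {
        name: {
            metric: {
                "mean": float(rep.summary.loc[metric, "mean"]),
                "sd": float(rep.summary.loc[metric, "sd"]),
                "ci_low": float(rep.summary.loc[metric, "ci_low"]),
                "ci_high": float(rep.summary.loc[metric, "ci_high"]),
            }
            for metric in rep.summary.index
        }
        for name, rep in reports.items()
    }
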