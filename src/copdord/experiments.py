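"""Experiment orchestration: the baseline/ablation suite on a fixed split.

One stratified 20% validation split of the target cohort is frozen for the
whole suite; every model variant and every repeat trains against the same
source + target-train rows and is scored on the identical validation rows
(the fairness contract of the comparison).  Run-to-run variation comes only
from the parameter-initialization seed (base_seed + run index), unless
``freeze_run_seeds`` pins every run to the same seed — which reproduces the
zero-standard-deviation regime of fully frozen experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import EvalReport, evaluate_predictions
from .models import ModelConfig, fit_logistic_baseline
from .preprocessing import DesignBlocks, build_design_blocks
from .schema import CohortTable, FeatureSpec, SplitIndices, default_feature_specs, stratified_split
from .training import DomainBatch, TrainConfig, TrainLog, predict_stages, train

#: suite variants in reporting order; "logistic" is the non-network baseline
SUITE_VARIANTS = (
    "multiclass",
    "shared_only_ordinal",
    "private_only_ordinal",
    "logistic",
    "full_ordinal",
)

DEFAULT_SPLIT_SEED = 42
DEFAULT_VAL_FRACTION = 0.2


@dataclass
class ExperimentData:
    """Preprocessed blocks and the frozen split shared by every suite run."""

    source_batch: DomainBatch
    target_train_batch: DomainBatch
    val_batch: DomainBatch
    split: SplitIndices
    config_dims: dict[str, int]
    source_blocks: DesignBlocks
    target_blocks: DesignBlocks


@dataclass
class RunRecord:
    variant: str
    run_index: int
    seed: int
    report: EvalReport
    predictions: np.ndarray
    truth: np.ndarray
    train_log: "TrainLog | None" = None


@dataclass
class SuiteResult:
    runs: list[RunRecord]
    summary: pd.DataFrame
    split: SplitIndices
    provenance: dict


def prepare_experiment(
    source: CohortTable,
    target: CohortTable,
    specs: "list[FeatureSpec] | None" = None,
    fraction: float = DEFAULT_VAL_FRACTION,
    split_seed: int = DEFAULT_SPLIT_SEED,
) -> ExperimentData:
    """Build design blocks and the single stratified split used suite-wide.

    The source cohort is never split — all of it is training data; only the
    target cohort is partitioned into train/validation.
    """
    specs = list(specs) if specs is not None else default_feature_specs()
    source_blocks = build_design_blocks(source, specs)
    target_blocks = build_design_blocks(target, specs)
    split = stratified_split(target.labels, fraction, split_seed)

    source_batch = DomainBatch(
        source_blocks.shared, source_blocks.private, "source", source.labels
    )
    tt = target_blocks.subset(split.train)
    tv = target_blocks.subset(split.validation)
    target_train_batch = DomainBatch(tt.shared, tt.private, "target", target.labels[split.train])
    val_batch = DomainBatch(tv.shared, tv.private, "target", target.labels[split.validation])
    dims = {
        "d_shared": source_blocks.d_shared,
        "d_source_private": source_blocks.d_private,
        "d_target_private": target_blocks.d_private,
    }
    return ExperimentData(
        source_batch=source_batch,
        target_train_batch=target_train_batch,
        val_batch=val_batch,
        split=split,
        config_dims=dims,
        source_blocks=source_blocks,
        target_blocks=target_blocks,
    )


def _logistic_design(data: ExperimentData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full value-mask design [shared | source-private | target-private].

    The private block of the other domain is all zeros — exactly the
    value-mask encoding of features that cohort never measured.
    """
    d_sp = 2 * data.config_dims["d_source_private"]
    d_tp = 2 * data.config_dims["d_target_private"]

    def rows(batch: DomainBatch) -> np.ndarray:
        n = batch.n
        if batch.domain == "source":
            return np.hstack([batch.shared, batch.private, np.zeros((n, d_tp))])
        return np.hstack([batch.shared, np.zeros((n, d_sp)), batch.private])

    x_train = np.vstack([rows(data.source_batch), rows(data.target_train_batch)])
    y_train = np.concatenate(
        [data.source_batch.stages, data.target_train_batch.stages]
    )
    x_val = rows(data.val_batch)
    return x_train, y_train, x_val


def run_one(
    variant: str,
    data: ExperimentData,
    seed: int,
    train_config: "TrainConfig | None" = None,
) -> RunRecord:
    """Train/fit a single variant with one seed and score it on validation."""
    truth = data.val_batch.stages
    if variant == "logistic":
        x_train, y_train, x_val = _logistic_design(data)
        baseline = fit_logistic_baseline(x_train, y_train, seed)
        pred = baseline.predict(x_val)
        log = None
    else:
        tc = train_config or TrainConfig()
        tc = TrainConfig(**{**tc.__dict__, "seed": seed})
        config = ModelConfig(variant=variant, **data.config_dims)
        best_params, log = train(
            config, [data.source_batch, data.target_train_batch], data.val_batch, tc
        )
        pred = predict_stages(best_params, config, data.val_batch)
    report = evaluate_predictions(truth, pred)
    return RunRecord(
        variant=variant, run_index=0, seed=seed, report=report,
        predictions=np.asarray(pred), truth=truth, train_log=log,
    )


def summarize_runs(runs: list[RunRecord]) -> pd.DataFrame:
    """Per-variant mean +/- sd of accuracy, MAE and QWK (population sd)."""
    rows = []
    for variant in SUITE_VARIANTS:
        vruns = [r for r in runs if r.variant == variant]
        if not vruns:
            continue
        metrics = {
            "accuracy": [r.report.accuracy for r in vruns],
            "mae": [r.report.mae for r in vruns],
            "qwk": [r.report.qwk for r in vruns],
        }
        row: dict = {"variant": variant, "n_runs": len(vruns)}
        for name, vals in metrics.items():
            row[f"{name}_mean"] = float(np.mean(vals))
            row[f"{name}_sd"] = float(np.std(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def run_suite(
    source: CohortTable,
    target: CohortTable,
    specs: "list[FeatureSpec] | None" = None,
    repeats: int = 5,
    base_seed: int = 0,
    split_seed: int = DEFAULT_SPLIT_SEED,
    fraction: float = DEFAULT_VAL_FRACTION,
    train_config: "TrainConfig | None" = None,
    variants: "tuple[str, ...] | None" = None,
    freeze_run_seeds: bool = False,
) -> SuiteResult:
    """Run the full baseline/ablation grid on one frozen split.

    Each variant is run ``repeats`` times with per-run seeds base_seed + r
    (or all pinned to base_seed when ``freeze_run_seeds``), every run scored
    on the byte-identical validation rows.  Any single failing run aborts the
    suite naming the variant and seed.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    variants = tuple(variants) if variants is not None else SUITE_VARIANTS
    data = prepare_experiment(source, target, specs, fraction, split_seed)
    runs: list[RunRecord] = []
    for variant in variants:
        for r in range(repeats):
            seed = base_seed if freeze_run_seeds else base_seed + r
            try:
                record = run_one(variant, data, seed, train_config)
            except Exception as exc:
                raise RuntimeError(
                    f"suite run failed for variant={variant!r} seed={seed}: {exc}"
                ) from exc
            record.run_index = r
            runs.append(record)
    summary = summarize_runs(runs)
    provenance = {
        "base_seed": base_seed,
        "split_seed": split_seed,
        "fraction": fraction,
        "repeats": repeats,
        "freeze_run_seeds": freeze_run_seeds,
        "variants": list(variants),
        "run_seeds": sorted({r.seed for r in runs}),
        "validation_indices": data.split.validation.tolist(),
    }
    return SuiteResult(runs=runs, summary=summary, split=data.split, provenance=provenance)


def runs_to_frame(runs: list[RunRecord]) -> pd.DataFrame:
    """Long-format per-run predictions (one row per validation sample)."""
    rows = []
    for rec in runs:
        for i, (t, p) in enumerate(zip(rec.truth, rec.predictions)):
            rows.append(
                {
                    "variant": rec.variant,
                    "run_index": rec.run_index,
                    "seed": rec.seed,
                    "sample": i,
                    "truth": int(t),
                    "pred": int(p),
                }
            )
    return pd.DataFrame(rows)


def summary_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Recompute the suite summary from persisted per-run predictions."""
    runs = []
    for (variant, run_index, seed), grp in frame.groupby(
        ["variant", "run_index", "seed"], sort=True
    ):
        report = evaluate_predictions(grp["truth"].to_numpy(), grp["pred"].to_numpy())
        runs.append(
            RunRecord(
                variant=str(variant), run_index=int(run_index), seed=int(seed),
                report=report, predictions=grp["pred"].to_numpy(),
                truth=grp["truth"].to_numpy(),
            )
        )
    return summarize_runs(runs)
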