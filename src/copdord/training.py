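"""Full-batch training with Adam, gradient clipping and MAE checkpointing.

One optimization step per epoch on the pooled loss over all training rows
from both cohorts (each row routed through its own private encoder; the
shared encoder and head see everything).  Ordinal variants minimize binary
cross-entropy averaged over the N x 3 threshold grid; the multiclass
baseline minimizes softmax cross-entropy.  The global gradient norm is
clipped before each Adam update (lr 3e-4, conventional beta/eps defaults, no
dropout, no mini-batching, no early stopping).  Validation metrics are
logged every `eval_every` epochs and the returned parameters are those of
the evaluation with minimum validation MAE (earliest epoch on ties) — the
checkpoint rule used throughout the experiment suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .metrics import evaluate_predictions
from .ordinal import decode_thresholds, encode_stages

_EPS = 1e-7  # probability clip inside the loss, for numerical safety


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    max_epochs: int = 3000
    eval_every: int = 10
    clip_norm: float = 1.0
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.eval_every < 1 or self.max_epochs < 1:
            raise ValueError("eval_every and max_epochs must be >= 1")


@dataclass(frozen=True)
class DomainBatch:
    """One cohort's design blocks plus labels, tagged with its domain."""

    shared: np.ndarray
    private: np.ndarray
    domain: str
    stages: np.ndarray

    @property
    def n(self) -> int:
        return len(self.stages)


@dataclass
class EvalRecord:
    epoch: int
    train_loss: float
    val_accuracy: float
    val_mae: float
    val_qwk: float


@dataclass
class TrainLog:
    records: list[EvalRecord] = field(default_factory=list)
    best_epoch: int = 0
    best_val_mae: float = float("inf")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "epoch": r.epoch,
                    "loss": r.train_loss,
                    "val_accuracy": r.val_accuracy,
                    "val_mae": r.val_mae,
                    "val_qwk": r.val_qwk,
                }
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ordinal_bce_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all N x 3 threshold entries.

    Probabilities are clipped to [1e-7, 1 - 1e-7] so the loss stays finite
    even for saturated sigmoids.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs targets {t.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def _multiclass_ce_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, _EPS, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def _targets_for(config: models.ModelConfig, stages: np.ndarray) -> np.ndarray:
    if config.variant == "multiclass":
        return (stages[:, None] == np.arange(1, 5)[None, :]).astype(np.float64)
    return encode_stages(stages)


def pooled_loss_and_grads(
    params: dict[str, np.ndarray],
    config: models.ModelConfig,
    batches: list[DomainBatch],
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and exact gradients pooled over all rows of all domain batches.

    The pooled loss is the mean per-entry BCE (ordinal) or per-row CE
    (multiclass) across every training row from both cohorts jointly — no
    per-domain reweighting.
    """
    n_total = sum(b.n for b in batches)
    if n_total == 0:
        raise ValueError("empty training set")
    grads = models.zero_grads(config)
    loss_sum = 0.0
    for batch in batches:
        if batch.n == 0:
            continue
        cache = models.forward_cached(
            params, config, batch.shared, batch.private, batch.domain
        )
        targets = _targets_for(config, batch.stages)
        probs = cache["probs"]
        if config.variant == "multiclass":
            loss_sum += _multiclass_ce_loss(probs, targets) * batch.n
            d_z = (probs - targets) / n_total
        else:
            loss_sum += ordinal_bce_loss(probs, targets) * (batch.n * 3)
            d_z = (probs - targets) / (n_total * 3)
        models.backward_from_dz(params, config, cache, d_z, grads)
    scale = n_total * (3 if config.variant != "multiclass" else 1)
    return loss_sum / scale, grads


def clip_global_norm(grads: dict[str, np.ndarray], clip_norm: float) -> float:
    """Scale all gradients in place so their joint L2 norm <= clip_norm."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
    if total > clip_norm and total > 0.0:
        factor = clip_norm / total
        for g in grads.values():
            g *= factor
    return total


def predict_stages(
    params: dict[str, np.ndarray],
    config: models.ModelConfig,
    batch: DomainBatch,
) -> np.ndarray:
    """Decode model outputs to GOLD stages 1-4 (single rule used everywhere)."""
    probs = models.forward(params, config, batch.shared, batch.private, batch.domain)
    if config.variant == "multiclass":
        return 1 + probs.argmax(axis=1)
    return decode_thresholds(probs)


def train(
    config: models.ModelConfig,
    train_batches: list[DomainBatch],
    val_batch: DomainBatch,
    tc: TrainConfig,
) -> tuple[dict[str, np.ndarray], TrainLog]:
    """Full-batch training returning the minimum-validation-MAE checkpoint.

    Epoch 0 (the untouched initialization) is evaluated first, then one Adam
    step per epoch with validation every ``tc.eval_every`` epochs.  Fully
    deterministic for a fixed ``tc.seed``.
    """
    if val_batch.n == 0:
        raise ValueError("validation set must be nonempty")
    params = models.init_params(config, tc.seed)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    log = TrainLog()

    def evaluate(epoch: int, loss: float) -> None:
        pred = predict_stages(params, config, val_batch)
        report = evaluate_predictions(val_batch.stages, pred)
        log.records.append(
            EvalRecord(epoch, loss, report.accuracy, report.mae, report.qwk)
        )
        if report.mae < log.best_val_mae:
            log.best_val_mae = report.mae
            log.best_epoch = epoch
            best_params.clear()
            best_params.update({k: p.copy() for k, p in params.items()})

    best_params: dict[str, np.ndarray] = {}
    loss0, _ = pooled_loss_and_grads(params, config, train_batches)
    evaluate(0, loss0)

    lr, b1, b2 = tc.learning_rate, tc.beta1, tc.beta2
    for epoch in range(1, tc.max_epochs + 1):
        loss, grads = pooled_loss_and_grads(params, config, train_batches)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss {loss} at epoch {epoch} "
                f"(variant={config.variant}, seed={tc.seed})"
            )
        clip_global_norm(grads, tc.clip_norm)
        t = epoch
        for key in params:
            g = grads[key]
            m[key] = b1 * m[key] + (1 - b1) * g
            v[key] = b2 * v[key] + (1 - b2) * g * g
            m_hat = m[key] / (1 - b1 ** t)
            v_hat = v[key] / (1 - b2 ** t)
            params[key] -= lr * m_hat / (np.sqrt(v_hat) + tc.adam_eps)
        if epoch % tc.eval_every == 0:
            evaluate(epoch, loss)

    return best_params, log
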