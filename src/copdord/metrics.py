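"""Ordinal evaluation: accuracy, stage-MAE, quadratic weighted kappa.

Exact agreement (accuracy) ignores how far off a wrong stage is; stage-MAE
measures the average ordinal distance; quadratic weighted kappa (QWK)
chance-corrects agreement with a penalty proportional to the squared stage
distance, so confusing GOLD 1 with GOLD 4 costs nine times as much as an
adjacent-stage slip.  The within-+/-1 rate summarizes how clinically benign
the *errors* are: among misclassified patients, the fraction predicted within
one stage of truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, mean_absolute_error

N_STAGES = 4
_STAGE_LABELS = (1, 2, 3, 4)


@dataclass
class EvalReport:
    """Full ordinal evaluation of one prediction set (stage axes fixed 1-4)."""

    accuracy: float
    mae: float
    qwk: float
    confusion: np.ndarray  # 4x4 counts, rows = true stage, cols = predicted
    within_1_rate: float

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mae": self.mae,
            "qwk": self.qwk,
            "within_1_rate": self.within_1_rate,
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_stages(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.int64)
    if arr.size and not np.isin(arr, _STAGE_LABELS).all():
        raise ValueError(f"{name} contains stages outside 1-4")
    return arr


def quadratic_weighted_kappa(truth, pred, n_classes: int = N_STAGES) -> float:
    """Quadratic weighted Cohen's kappa over ordinal classes 1..n_classes.

    kappa = 1 - sum(w * O) / sum(w * E), with w_ij = (i-j)^2 / (K-1)^2,
    O the observed confusion count matrix and E the outer product of its
    marginals scaled to N.  Ranges over [-1, 1]; 1 is perfect agreement.
    """
    t = np.asarray(truth, dtype=np.int64)
    p = np.asarray(pred, dtype=np.int64)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and pred must be equal-length and nonempty")
    for arr, name in ((t, "truth"), (p, "pred")):
        if ((arr < 1) | (arr > n_classes)).any():
            raise ValueError(f"{name} contains stages outside 1-{n_classes}")
    k = n_classes
    observed = confusion_matrix(t, p, labels=np.arange(1, k + 1)).astype(np.float64)
    n = observed.sum()
    idx = np.arange(k, dtype=np.float64)
    weights = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    denom = float((weights * expected).sum())
    num = float((weights * observed).sum())
    if denom == 0.0:
        # both marginals concentrated on one identical class
        if num == 0.0:
            return 1.0
        raise ValueError(
            "degenerate marginals (single identical class) with off-diagonal "
            "observations; kappa undefined"
        )
    return 1.0 - num / denom


def evaluate_predictions(truth, pred) -> EvalReport:
    """Compute the full :class:`EvalReport` for predicted vs true stages.

    ``within_1_rate`` is computed over misclassified pairs only and is 1.0 by
    convention when there are no errors.
    """
    t = _as_stages(truth, "truth")
    p = _as_stages(pred, "pred")
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and pred must be equal-length and nonempty")
    conf = confusion_matrix(t, p, labels=np.asarray(_STAGE_LABELS))
    accuracy = float((t == p).mean())
    mae = float(mean_absolute_error(t, p))
    qwk = quadratic_weighted_kappa(t, p)
    errs = np.abs(t - p)[t != p]
    within_1 = 1.0 if errs.size == 0 else float((errs <= 1).mean())
    return EvalReport(
        accuracy=accuracy, mae=mae, qwk=qwk, confusion=conf, within_1_rate=within_1
    )


def confusion_to_csv(confusion: np.ndarray, path) -> None:
    import pandas as pd

    frame = pd.DataFrame(
        confusion,
        index=[f"true_{s}" for s in _STAGE_LABELS],
        columns=[f"pred_{s}" for s in _STAGE_LABELS],
    )
    frame.to_csv(path)


def plot_confusion(confusion: np.ndarray, path, title: str = "GOLD stage confusion") -> None:
    """Heatmap of the 4x4 stage confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(confusion, cmap="Blues")
    ax.set_xticks(range(N_STAGES), [f"GOLD {s}" for s in _STAGE_LABELS])
    ax.set_yticks(range(N_STAGES), [f"GOLD {s}" for s in _STAGE_LABELS])
    ax.set_xlabel("Predicted stage")
    ax.set_ylabel("True stage")
    ax.set_title(title)
    for i in range(N_STAGES):
        for j in range(N_STAGES):
            ax.text(j, i, str(int(confusion[i, j])), ha="center", va="center",
                    color="white" if confusion[i, j] > confusion.max() / 2 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
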