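"""Leave-one-out cross-validation, binary metrics, ROC/AUC, model selection.

Metrics follow the standard confusion-count definitions: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 when any marginal (hence the denominator) is zero so
that model selection remains total.  AUC is the area under the ROC obtained
by sweeping a threshold over the decision scores (equal scores grouped); it
equals the normalized Mann-Whitney U statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut

logger = logging.getLogger(__name__)


class _Predictor(Protocol):
    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts, threshold metrics, AUC and per-sample predictions."""

    counts: ConfusionCounts
    metrics: Metrics
    auc: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    per_sample: pd.DataFrame  # columns id, label, prediction, score

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "accuracy": self.metrics.accuracy,
            "mcc": self.metrics.mcc,
            "auc": self.auc,
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return Metrics(sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc)


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points (with the all-negative/all-positive endpoints) and AUC.

    Constant scores are degenerate: a warning is logged and AUC is 0.5 (the
    ROC is the chance diagonal).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    if np.allclose(scores, scores[0]):
        logger.warning("constant decision scores: AUC is 0.5 by convention")
        roc = pd.DataFrame(
            {"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "threshold": [np.inf, scores[0]]}
        )
        return roc, 0.5
    fpr, tpr, thr = roc_curve(y, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    auc = float(np.trapezoid(tpr, fpr))
    return roc, auc


def loocv(
    trainer: Callable[[np.ndarray, np.ndarray], _Predictor],
    X: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Leave-one-out cross-validation of an arbitrary training procedure.

    Each sample is predicted by a model trained on the remaining n-1; all
    fitted parameters are recomputed without the held-out sample.  Returns
    ``(predictions, scores, failed_folds)``; a fold whose training raises
    (e.g. a degenerate single-class split the trainer rejects) is recorded in
    ``failed_folds`` with NaN prediction and score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV requires at least two samples")
    preds = np.full(n, np.nan)
    scores = np.full(n, np.nan)
    failed: list[int] = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        i = int(test_idx[0])
        try:
            model = trainer(X[train_idx], y[train_idx])
            p, s = model.predict(X[test_idx])
            preds[i], scores[i] = p[0], s[0]
        except Exception as exc:  # noqa: BLE001 - fold failure is reportable
            logger.warning("LOOCV fold %d failed: %s", i, exc)
            failed.append(i)
    return preds, scores, failed


def evaluate_predictions(
    ids: Sequence[str],
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
) -> EvaluationReport:
    """Assemble a full report from per-sample predictions and scores."""
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    metrics = compute_metrics(counts)
    roc, auc = roc_auc(np.asarray(scores), np.asarray(y_true))
    per_sample = pd.DataFrame(
        {
            "id": list(ids),
            "label": np.asarray(y_true).astype(int),
            "prediction": np.asarray(y_pred).astype(int),
            "score": np.asarray(scores, dtype=float),
        }
    )
    return EvaluationReport(
        counts=counts, metrics=metrics, auc=auc, roc=roc, per_sample=per_sample
    )


def select_best_model(candidates: Sequence[dict]) -> int:
    """Index of the winning candidate by maximal LOOCV MCC.

    Each candidate is a mapping with keys ``mcc``, ``accuracy``,
    ``subset_size`` and ``cutoff_index``.  Ties break by higher accuracy,
    then smaller subset, then lower cutoff index; fully deterministic.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    keys = [
        (-c["mcc"], -c["accuracy"], c["subset_size"], c["cutoff_index"], i)
        for i, c in enumerate(candidates)
    ]
    return min(keys)[-1]
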