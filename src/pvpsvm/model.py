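"""RBF-kernel SVM with log2 grid search, plus RF/ERT comparator classifiers.

The final classifier is a support vector machine with the Gaussian radial
basis kernel K(x, y) = exp(-gamma * ||x - y||^2).  Its two hyperparameters —
the error/margin trade-off C and the kernel width gamma — are optimized by an
exhaustive grid search over the integer log2 lattice C in 2^-15..2^10 and
gamma in 2^-10..2^10 (546 points), scored by cross-validated MCC, with an
optional second-stage refinement on a 0.25-step lattice around the coarse
optimum.  Random-forest and extremely-randomized-trees comparators tune their
``mtry`` on the same cross-validation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .evaluation import ConfusionCounts, compute_metrics

ARCHIVE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters; gamma = 1/sigma^2."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class TrainedClassifier:
    """A fitted classifier bound to the feature subset it was trained on.

    ``predict`` refuses input whose width differs from the training width:
    callers must project columns to the stored feature subset first.
    """

    algorithm: str  # svm | rf | ert
    estimator: object
    n_features: int
    config: dict
    seed: int | None = None
    feature_indices: tuple[int, ...] | None = None
    feature_names: tuple[str, ...] | None = None

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels (1=positive) and decision scores.

        SVM scores are the raw decision-function values (positive class at
        score > 0); forest scores are the fraction of trees voting positive
        (positive class at score > 0.5).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            got = X.shape[1] if X.ndim == 2 else X.shape
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features} "
                f"columns, got {got}"
            )
        if self.algorithm == "svm":
            scores = self.estimator.decision_function(X)
            labels = (scores > 0).astype(int)
        else:
            scores = self.estimator.predict_proba(X)[:, 1]
            labels = (scores > 0.5).astype(int)
        return labels, scores


def _check_training_input(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def train_svm(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> TrainedClassifier:
    """Fit an RBF-kernel SVM; decision scores accompany class predictions."""
    X, y = _check_training_input(X, y)
    cfg = SVMConfig(C=C, gamma=gamma)
    est = SVC(C=cfg.C, gamma=cfg.gamma, kernel="rbf")
    est.fit(X, y)
    return TrainedClassifier(
        algorithm="svm",
        estimator=est,
        n_features=X.shape[1],
        config={"C": cfg.C, "gamma": cfg.gamma},
    )


def _cv_splits(
    X: np.ndarray, y: np.ndarray, cv: int | str, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    if cv == "loo":
        return list(LeaveOneOut().split(X))
    k = int(cv)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    return list(splitter.split(X, y))


def _cv_mcc_acc(
    make_estimator,
    X: np.ndarray,
    y: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """Pooled cross-validated MCC and accuracy for one hyperparameter point."""
    preds = np.empty(len(y), dtype=int)
    for train_idx, test_idx in splits:
        est = make_estimator()
        est.fit(X[train_idx], y[train_idx])
        preds[test_idx] = est.predict(X[test_idx])
    m = compute_metrics(ConfusionCounts.from_predictions(y, preds))
    return m.mcc, m.accuracy


@dataclass(frozen=True)
class GridSearchResult:
    best: SVMConfig
    best_mcc: float
    best_accuracy: float
    table: pd.DataFrame  # columns: log2C, log2gamma, C, gamma, mcc, accuracy, stage


def _select_best(table: pd.DataFrame) -> pd.Series:
    # max MCC; ties -> higher accuracy, then smaller C, then smaller gamma
    key = table.assign(_negC=-table["C"], _negG=-table["gamma"])
    idx = key.sort_values(
        ["mcc", "accuracy", "_negC", "_negG"],
        ascending=[False, False, False, False],
        kind="mergesort",
    ).index[0]
    return table.loc[idx]


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_range: tuple[float, float] = (-15, 10),
    gamma_range: tuple[float, float] = (-10, 10),
    cv: int | str = "loo",
    refine: bool = True,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search on the integer log2 lattice.

    Every lattice point is scored by pooled cross-validated MCC under the
    supplied scheme (``cv="loo"`` or a fold count).  With ``refine``, a
    second pass evaluates a 0.25-step lattice spanning +-1 around the coarse
    optimum (clipped to the search ranges).  Ties break toward higher
    accuracy, then smaller C, then smaller gamma (the smoother model).
    """
    X, y = _check_training_input(X, y)
    if c_range[0] > c_range[1] or gamma_range[0] > gamma_range[1]:
        raise ValueError("grid bounds must satisfy lower <= upper")
    splits = _cv_splits(X, y, cv, seed)

    rows = []
    for lc in np.arange(c_range[0], c_range[1] + 1):
        for lg in np.arange(gamma_range[0], gamma_range[1] + 1):
            C, gamma = float(2.0**lc), float(2.0**lg)
            mcc, acc = _cv_mcc_acc(
                lambda: SVC(C=C, gamma=gamma, kernel="rbf"), X, y, splits
            )
            rows.append((float(lc), float(lg), C, gamma, mcc, acc, "coarse"))
    table = pd.DataFrame(
        rows, columns=["log2C", "log2gamma", "C", "gamma", "mcc", "accuracy", "stage"]
    )

    if refine:
        top = _select_best(table)
        lc0, lg0 = top["log2C"], top["log2gamma"]
        seen = {(r[0], r[1]) for r in rows}
        for lc in np.arange(lc0 - 1, lc0 + 1.001, 0.25):
            for lg in np.arange(lg0 - 1, lg0 + 1.001, 0.25):
                lc_c = float(np.clip(lc, *c_range))
                lg_c = float(np.clip(lg, *gamma_range))
                if (lc_c, lg_c) in seen:
                    continue
                seen.add((lc_c, lg_c))
                C, gamma = float(2.0**lc_c), float(2.0**lg_c)
                mcc, acc = _cv_mcc_acc(
                    lambda: SVC(C=C, gamma=gamma, kernel="rbf"), X, y, splits
                )
                rows.append((lc_c, lg_c, C, gamma, mcc, acc, "refine"))
        table = pd.DataFrame(
            rows,
            columns=["log2C", "log2gamma", "C", "gamma", "mcc", "accuracy", "stage"],
        )

    best_row = _select_best(table)
    return GridSearchResult(
        best=SVMConfig(C=float(best_row["C"]), gamma=float(best_row["gamma"])),
        best_mcc=float(best_row["mcc"]),
        best_accuracy=float(best_row["accuracy"]),
        table=table,
    )


def _train_forest(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    n_trees: int,
    cv: int | str,
    seed: int,
) -> TrainedClassifier:
    X, y = _check_training_input(X, y)
    p = X.shape[1]
    mtry_grid = sorted({max(1, int(round(np.sqrt(p)))), max(1, p // 4), max(1, p // 2)})
    cls = RandomForestClassifier if kind == "rf" else ExtraTreesClassifier
    splits = _cv_splits(X, y, cv, seed)
    scored = []
    for mtry in mtry_grid:
        mcc, acc = _cv_mcc_acc(
            lambda: cls(
                n_estimators=n_trees,
                max_features=mtry,
                random_state=seed % 2**31,
                n_jobs=1,
            ),
            X,
            y,
            splits,
        )
        scored.append((mcc, acc, -mtry))
    best_mtry = -max(scored)[2]
    est = cls(
        n_estimators=n_trees, max_features=best_mtry, random_state=seed % 2**31, n_jobs=1
    )
    est.fit(X, y)
    return TrainedClassifier(
        algorithm=kind,
        estimator=est,
        n_features=p,
        config={"n_trees": n_trees, "mtry": best_mtry},
        seed=seed,
    )


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    cv: int | str = 5,
    seed: int = 0,
) -> TrainedClassifier:
    """Random-forest comparator; ``mtry`` tuned over {sqrt(p), p/4, p/2}."""
    return _train_forest(X, y, "rf", n_trees, cv, seed)


def train_ert(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    cv: int | str = 5,
    seed: int = 0,
) -> TrainedClassifier:
    """Extremely-randomized-trees comparator; tuned like :func:`train_rf`."""
    return _train_forest(X, y, "ert", n_trees, cv, seed)


def save_model(
    model: TrainedClassifier,
    path: str | Path,
    table_version: str,
    extra: dict | None = None,
) -> None:
    """Persist a model archive embedding its feature subset and table version."""
    payload = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "table_version": table_version,
        "model": model,
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> tuple[TrainedClassifier, dict]:
    """Load a model archive; returns (model, metadata)."""
    payload = joblib.load(path)
    if payload.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model archive schema: {payload.get('schema_version')}"
        )
    meta = {k: v for k, v in payload.items() if k != "model"}
    return payload["model"], meta
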