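"""End-to-end orchestration: dataset -> features -> selection -> final model.

The four-step protocol:

1. assemble the labeled dataset (positive/negative FASTA);
2. encode every sequence into the 583-dimensional hybrid feature vector;
3. rank features by randomized-forest importance and form cutoff-stepped
   candidate subsets;
4. for each subset, tune the classifier by grid search and score it with
   leave-one-out cross-validation; the subset/configuration with the highest
   LOOCV MCC becomes the final model, refit on the full training set.

A single run seed fans out into per-stage seeds (via ``numpy`` seed
sequences), so individual stages can be rerun in isolation and a run is
fully reproducible from (inputs, RunConfig, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .evaluation import (
    EvaluationReport,
    evaluate_predictions,
    loocv,
    select_best_model,
)
from .feature_selection import (
    DEFAULT_CUTOFFS,
    FeatureSubset,
    FISTable,
    compute_fis,
    generate_feature_sets,
)
from .model import (
    TrainedClassifier,
    grid_search_svm,
    load_model,
    save_model,
    train_ert,
    train_rf,
    train_svm,
)
from .properties import default_tables
from .seq_io import LabeledSequenceSet, ProteinSequence

logger = logging.getLogger(__name__)

_STAGES = {"fis": 0, "grid": 1, "final": 2, "synth": 3}


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single run seed."""
    ss = np.random.SeedSequence(entropy=run_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full training run."""

    algo: str = "svm"  # svm | rf | ert
    fis_trees: int = 5000
    fis_folds: int = 10
    mtry_range: tuple[int, int] = (1, 100)
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    c_range: tuple[float, float] = (-15, 10)
    gamma_range: tuple[float, float] = (-10, 10)
    refine: bool = True
    inner_cv: int | str = "loo"  # CV scheme inside the grid search
    nested: bool = False  # re-tune hyperparameters within every LOOCV fold
    forest_trees: int = 500
    sanitize: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.algo not in ("svm", "rf", "ert"):
            raise ValueError(f"unknown algorithm {self.algo!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for k in ("mtry_range", "c_range", "gamma_range", "cutoffs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TrainResult:
    """Everything a training run produces."""

    config: RunConfig
    fis: FISTable
    subsets: list[FeatureSubset]
    subset_table: pd.DataFrame  # one row per candidate subset with its metrics
    best_index: int
    final_model: TrainedClassifier
    final_report: EvaluationReport

    @property
    def best_subset(self) -> FeatureSubset:
        return self.subsets[self.best_index]


def _svm_trainer(C: float, gamma: float):
    return lambda X, y: train_svm(X, y, C=C, gamma=gamma)


def _forest_trainer(kind: str, n_trees: int, mtry: int, seed: int):
    from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

    cls = RandomForestClassifier if kind == "rf" else ExtraTreesClassifier

    def trainer(X, y):
        est = cls(
            n_estimators=n_trees, max_features=min(mtry, X.shape[1]),
            random_state=seed, n_jobs=1,
        )
        est.fit(X, y)
        return TrainedClassifier(
            algorithm=kind, estimator=est, n_features=X.shape[1],
            config={"n_trees": n_trees, "mtry": mtry}, seed=seed,
        )

    return trainer


def _nested_svm_trainer(config: RunConfig, seed: int):
    def trainer(X, y):
        gs = grid_search_svm(
            X, y,
            c_range=config.c_range, gamma_range=config.gamma_range,
            cv=config.inner_cv, refine=config.refine, seed=seed,
        )
        return train_svm(X, y, C=gs.best.C, gamma=gs.best.gamma)

    return trainer


def _evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    ids: list[str],
    subset: FeatureSubset,
    config: RunConfig,
    grid_seed: int,
) -> tuple[dict, dict, EvaluationReport]:
    """Tune on one feature subset and score it by LOOCV.

    Returns (summary row, fitted config for the final refit, LOOCV report).
    """
    Xs = X[:, list(subset.indices)]
    if config.algo == "svm":
        if config.nested:
            trainer = _nested_svm_trainer(config, grid_seed)
            fitted = {"nested": True}
        else:
            gs = grid_search_svm(
                Xs, y,
                c_range=config.c_range, gamma_range=config.gamma_range,
                cv=config.inner_cv, refine=config.refine, seed=grid_seed,
            )
            trainer = _svm_trainer(gs.best.C, gs.best.gamma)
            fitted = {"C": gs.best.C, "gamma": gs.best.gamma}
    else:
        tuned = (train_rf if config.algo == "rf" else train_ert)(
            Xs, y, n_trees=config.forest_trees,
            cv=config.inner_cv if config.inner_cv != "loo" else 5, seed=grid_seed,
        )
        mtry = tuned.config["mtry"]
        trainer = _forest_trainer(config.algo, config.forest_trees, mtry, grid_seed)
        fitted = {"n_trees": config.forest_trees, "mtry": mtry}

    preds, scores, failed = loocv(trainer, Xs, y)
    ok = ~np.isnan(preds)
    report = evaluate_predictions(
        [i for i, keep in zip(ids, ok) if keep], y[ok], preds[ok], scores[ok]
    )
    row = {
        "cutoff": subset.cutoff,
        "subset_size": len(subset),
        "mcc": report.metrics.mcc,
        "accuracy": report.metrics.accuracy,
        "sensitivity": report.metrics.sensitivity,
        "specificity": report.metrics.specificity,
        "auc": report.auc,
        "failed_folds": len(failed),
        **{f"param_{k}": v for k, v in fitted.items()},
    }
    return row, fitted, report


def run_train(dataset: LabeledSequenceSet, config: RunConfig) -> TrainResult:
    """Execute the full training protocol on a labeled sequence set."""
    if not dataset.positives or not dataset.negatives:
        raise ValueError("training requires both positive and negative sequences")
    tables = default_tables()
    names = feat.feature_names()
    X, y = feat.encode_set(dataset, tables)
    ids = [s.id for s in dataset.sequences]
    logger.info("encoded %d sequences into %d features", *X.shape)

    fis = compute_fis(
        X, y,
        n_trees=config.fis_trees, folds=config.fis_folds,
        mtry_range=config.mtry_range, seed=stage_seed(config.seed, "fis"),
        names=names,
    )
    subsets = generate_feature_sets(fis, config.cutoffs)
    if not subsets:
        raise ValueError("no cutoff produced a non-empty feature subset")
    logger.info("generated %d candidate feature subsets", len(subsets))

    grid_seed = stage_seed(config.seed, "grid")
    rows, fitted_configs, reports = [], [], []
    for k, subset in enumerate(subsets):
        row, fitted, report = _evaluate_subset(X, y, ids, subset, config, grid_seed)
        row["cutoff_index"] = k
        rows.append(row)
        fitted_configs.append(fitted)
        reports.append(report)
        logger.info(
            "subset %d (cutoff %.6f, %d features): MCC %.3f acc %.3f",
            k, subset.cutoff, len(subset), row["mcc"], row["accuracy"],
        )
    subset_table = pd.DataFrame(rows)
    best = select_best_model(rows)

    # refit the winner on the full training set
    winner, fitted = subsets[best], fitted_configs[best]
    Xb = X[:, list(winner.indices)]
    if config.algo == "svm":
        if config.nested:
            final_model = _nested_svm_trainer(config, grid_seed)(Xb, y)
        else:
            final_model = train_svm(Xb, y, C=fitted["C"], gamma=fitted["gamma"])
    else:
        final_model = _forest_trainer(
            config.algo, config.forest_trees, fitted["mtry"], grid_seed
        )(Xb, y)
    final_model.seed = config.seed
    final_model.feature_indices = winner.indices
    final_model.feature_names = winner.names
    final_report = reports[best]

    return TrainResult(
        config=config,
        fis=fis,
        subsets=subsets,
        subset_table=subset_table,
        best_index=best,
        final_model=final_model,
        final_report=final_report,
    )


def save_result(result: TrainResult, out_dir: str | Path) -> Path:
    """Write a training run's artifacts under ``out_dir`` (fixed layout v1)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(result.config.to_json() + "\n")
    fis_df = pd.DataFrame(
        {
            "feature": result.fis.names,
            "block": [feat.feature_block(n) for n in result.fis.names],
            "fis": result.fis.scores,
        }
    )
    fis_df.to_csv(out_dir / "fis_table.tsv", sep="\t", index=False)
    result.subset_table.to_csv(out_dir / "subset_metrics.tsv", sep="\t", index=False)
    subsets_json = [
        {"cutoff": s.cutoff, "indices": list(s.indices), "names": list(s.names)}
        for s in result.subsets
    ]
    (out_dir / "feature_subsets.json").write_text(
        json.dumps(subsets_json, indent=2) + "\n"
    )
    report_path = out_dir / "final_report.json"
    report_path.write_text(json.dumps(result.final_report.to_dict(), indent=2) + "\n")
    result.final_report.per_sample.to_csv(
        out_dir / "loocv_predictions.tsv", sep="\t", index=False
    )
    archive = out_dir / "model.joblib"
    save_model(
        result.final_model,
        archive,
        table_version=default_tables().version,
        extra={
            "run_config": dataclasses.asdict(result.config),
            "best_cutoff": result.best_subset.cutoff,
        },
    )
    return archive


def _project(X: np.ndarray, model: TrainedClassifier) -> np.ndarray:
    if model.feature_indices is None:
        return X
    return X[:, list(model.feature_indices)]


def _check_table_version(meta: dict) -> None:
    current = default_tables().version
    if meta.get("table_version") not in (None, current):
        raise ValueError(
            f"model archive was built with property tables "
            f"{meta['table_version']!r} but {current!r} is installed; "
            f"refusing to re-encode"
        )


def run_predict(
    archive: str | Path, sequences: list[ProteinSequence]
) -> pd.DataFrame:
    """Predict labels and decision scores for query sequences.

    Encoding and projection onto the archived feature subset happen
    internally; the archive's property-table version must match the
    installed tables.
    """
    model, meta = load_model(archive)
    _check_table_version(meta)
    if not sequences:
        return pd.DataFrame(columns=["id", "prediction", "score"])
    tables = default_tables()
    X = np.vstack([feat.encode(s, tables) for s in sequences])
    labels, scores = model.predict(_project(X, model))
    return pd.DataFrame(
        {"id": [s.id for s in sequences], "prediction": labels, "score": scores}
    )


def run_evaluate(
    archive: str | Path, dataset: LabeledSequenceSet
) -> EvaluationReport:
    """Score an archived model on a labeled set (e.g. an independent dataset)."""
    model, meta = load_model(archive)
    _check_table_version(meta)
    tables = default_tables()
    X, y = feat.encode_set(dataset, tables)
    labels, scores = model.predict(_project(X, model))
    ids = [s.id for s in dataset.sequences]
    return evaluate_predictions(ids, y, labels, scores)
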