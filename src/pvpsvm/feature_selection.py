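"""Random-forest feature-importance scoring and cutoff-stepped feature subsets.

The feature importance score (FIS) of each feature is the mean impurity-based
(Gini) importance over forests grown on the training split of each round of a
k-fold cross-validation.  Each round's forest uses its own ``mtry`` (number of
candidate variables per split) drawn uniformly from a configurable range, so
averaging over rounds also averages over ``mtry``.  Candidate feature subsets
are then formed by thresholding the FIS at an increasing schedule of cutoffs,
which yields nested subsets ordered by descending importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: Default cutoff schedule: 25 evenly spaced thresholds over [0.001, 0.004].
DEFAULT_CUTOFFS: tuple[float, ...] = tuple(np.linspace(0.001, 0.004, 25))


@dataclass(frozen=True)
class FISTable:
    """Per-feature importance scores plus the protocol metadata behind them."""

    scores: np.ndarray
    names: tuple[str, ...]
    n_trees: int
    folds: int
    mtry_per_fold: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.names):
            raise ValueError("scores and names length mismatch")
        if np.any(self.scores < 0):
            raise ValueError("FIS must be nonnegative")

    def ranked_indices(self) -> np.ndarray:
        """Feature indices sorted by descending FIS, ties by ascending index."""
        order = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return order


@dataclass(frozen=True)
class FeatureSubset:
    """Feature indices with FIS >= cutoff, ordered by descending importance."""

    cutoff: float
    indices: tuple[int, ...]
    names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.indices)


def compute_fis(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 5000,
    folds: int = 10,
    mtry_range: tuple[int, int] = (1, 100),
    seed: int = 0,
    names: list[str] | None = None,
) -> FISTable:
    """Estimate per-feature importance by the randomized-forest protocol.

    For each of ``folds`` stratified CV rounds, a forest of ``n_trees`` is
    grown on the round's training split with ``mtry`` drawn uniformly from
    ``mtry_range`` (clipped to the number of features, with a warning).  The
    FIS is the mean Gini importance across rounds.  Deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; need both classes")
    n_features = X.shape[1]
    lo, hi = mtry_range
    if n_features < hi:
        logger.warning(
            "mtry upper bound %d exceeds %d features; clipping", hi, n_features
        )
        hi = n_features
        lo = min(lo, hi)
    if names is None:
        names = [f"f{i}" for i in range(n_features)]

    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    importances = np.zeros(n_features)
    mtrys: list[int] = []
    for fold, (train_idx, _test_idx) in enumerate(splitter.split(X, y)):
        mtry = int(rng.integers(lo, hi + 1))
        mtrys.append(mtry)
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=mtry,
            random_state=(seed + fold) % 2**31,
            n_jobs=1,
        )
        forest.fit(X[train_idx], y[train_idx])
        importances += forest.feature_importances_
    importances /= folds
    return FISTable(
        scores=importances,
        names=tuple(names),
        n_trees=n_trees,
        folds=folds,
        mtry_per_fold=tuple(mtrys),
        seed=seed,
    )


def candidate_features(fis: FISTable, cutoff: float = 0.001) -> FeatureSubset:
    """Features with FIS >= cutoff, sorted by descending FIS then index."""
    keep = [int(i) for i in fis.ranked_indices() if fis.scores[i] >= cutoff]
    if not keep:
        raise ValueError(
            f"no feature reaches FIS cutoff {cutoff}; lower the cutoff "
            f"(max FIS is {fis.scores.max():.6f})"
        )
    return FeatureSubset(
        cutoff=cutoff,
        indices=tuple(keep),
        names=tuple(fis.names[i] for i in keep),
    )


def generate_feature_sets(
    fis: FISTable, cutoffs: list[float] | tuple[float, ...] = DEFAULT_CUTOFFS
) -> list[FeatureSubset]:
    """One subset per cutoff of a strictly increasing schedule (nested).

    Cutoffs that would yield an empty subset are dropped with a warning.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoff schedule must be strictly increasing")
    subsets = []
    for c in cutoffs:
        try:
            subsets.append(candidate_features(fis, c))
        except ValueError:
            logger.warning("cutoff %.6f yields an empty subset; dropped", c)
    return subsets
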