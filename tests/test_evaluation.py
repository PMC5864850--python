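import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from _oracles import oracle_loocv, oracle_metrics
from pvpsvm.evaluation import (
    ConfusionCounts,
    compute_metrics,
    evaluate_predictions,
    loocv,
    roc_auc,
    select_best_model,
)
from pvpsvm.model import train_ert, train_rf, train_svm


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        n = len(X)
        return np.full(n, self.value), np.full(n, float(self.value))


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=99, tn=208, fp=0, fn=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_chance_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (0.5, 0.5, 0.5, 0)

    def test_formula_oracle_near_operating_point(self):
        m = compute_metrics(ConfusionCounts(tp=73, tn=194, fp=14, fn=26))
        sens, spec, acc, mcc = oracle_metrics(73, 194, 14, 26)
        assert abs(m.sensitivity - sens) < 1e-12
        assert abs(m.specificity - spec) < 1e-12
        assert abs(m.accuracy - acc) < 1e-12
        assert abs(m.mcc - mcc) < 1e-12

    def test_zero_denominator_mcc_is_zero(self):
        assert compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5)).mcc == 0.0

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_mcc_antisymmetry_under_label_swap(self, tp, tn, fp, fn):
        """Flipping the true labels negates MCC; relabeling the positive class
        consistently in truth and prediction swaps sensitivity/specificity."""
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert -1 - 1e-12 <= m.mcc <= 1 + 1e-12
        # truth flip: predicted positives on flipped truth hit old FP/TP
        flipped = compute_metrics(ConfusionCounts(tp=fp, tn=fn, fp=tp, fn=tn))
        assert abs(m.mcc + flipped.mcc) < 1e-12
        # consistent relabeling of the positive class
        relabeled = compute_metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert abs(m.mcc - relabeled.mcc) < 1e-12
        assert abs(m.sensitivity - relabeled.specificity) < 1e-12
        assert abs(m.specificity - relabeled.sensitivity) < 1e-12


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0

    def test_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y)
        assert auc == 0.0

    def test_constant_scores_chance_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            _, auc = roc_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
        assert auc == 0.5 and "constant" in caplog.text

    def test_roc_spans_origin_to_corner(self, rng):
        scores = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        roc, _ = roc_auc(scores, y)
        assert (roc["fpr"].iloc[0], roc["tpr"].iloc[0]) == (0, 0)
        assert (roc["fpr"].iloc[-1], roc["tpr"].iloc[-1]) == (1, 1)

    def test_auc_equals_normalized_mannwhitney_u(self, rng):
        n = 200
        y = np.array([1] * 80 + [0] * 120)
        scores = rng.normal(size=n) + 0.5 * y
        scores = np.round(scores, 1)  # force ties to exercise grouping
        _, auc = roc_auc(scores, y)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert abs(auc - u / (80 * 120)) < 1e-10


class TestLoocv:
    def test_constant_trainer(self, rng):
        X = rng.random((6, 2))
        y = np.array([1, 0, 1, 0, 1, 0])
        preds, scores, failed = loocv(lambda X_, y_: _ConstantModel(1), X, y)
        assert np.all(preds == 1) and not failed

    def test_smallest_n_degenerate_folds_reported(self, rng):
        # n=2, one per class: each fold trains on a single opposite-class sample
        X = rng.random((2, 3))
        y = np.array([1, 0])
        preds, _, failed = loocv(
            lambda X_, y_: train_svm(X_, y_, C=1.0, gamma=1.0), X, y
        )
        assert failed == [0, 1] and np.all(np.isnan(preds))

    @pytest.mark.parametrize(
        "trainer",
        [
            lambda X, y: train_svm(X, y, C=8.0, gamma=0.5),
            lambda X, y: train_rf(X, y, n_trees=30, cv=2, seed=5),
            lambda X, y: train_ert(X, y, n_trees=30, cv=2, seed=5),
        ],
        ids=["svm", "rf", "ert"],
    )
    def test_matches_naive_slice_refit_oracle(self, small_encoded, trainer):
        X, y = small_encoded
        X = X[:, :40]  # trim for speed; contract is about fold handling
        preds, scores, failed = loocv(trainer, X, y)
        assert not failed
        exp_preds, exp_scores = oracle_loocv(trainer, X, y)
        np.testing.assert_array_equal(preds, exp_preds)
        np.testing.assert_allclose(scores, exp_scores, atol=1e-12)


class TestSelectBestModel:
    def _cand(self, mcc, acc=0.9, size=10, idx=0):
        return {"mcc": mcc, "accuracy": acc, "subset_size": size, "cutoff_index": idx}

    def test_single_candidate(self):
        assert select_best_model([self._cand(0.5)]) == 0

    def test_higher_mcc_wins(self):
        assert select_best_model([self._cand(0.6), self._cand(0.7)]) == 1

    def test_tie_smaller_subset_wins(self):
        cands = [self._cand(0.7, size=200, idx=0), self._cand(0.7, size=136, idx=1)]
        assert select_best_model(cands) == 1

    def test_tie_higher_accuracy_precedes_size(self):
        cands = [self._cand(0.7, acc=0.91, size=200), self._cand(0.7, acc=0.90, size=10)]
        assert select_best_model(cands) == 0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_best_model([])


class TestReportConsistency:
    def test_metrics_recomputable_from_per_sample(self, rng):
        y = (rng.random(50) < 0.4).astype(int)
        preds = (rng.random(50) < 0.5).astype(int)
        scores = rng.normal(size=50) + preds
        report = evaluate_predictions([f"s{i}" for i in range(50)], y, preds, scores)
        c = ConfusionCounts.from_predictions(
            report.per_sample["label"], report.per_sample["prediction"]
        )
        assert report.counts == c
        assert report.metrics.accuracy == (c.tp + c.tn) / 50
        _, auc = roc_auc(report.per_sample["score"].to_numpy(), y)
        assert report.auc == auc
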