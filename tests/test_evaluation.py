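"""Metric formulas, fold construction, and the cross-validation protocol."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from mirloop.evaluation import (
    ConfusionCounts,
    MetricReport,
    cross_validate,
    metrics,
    species_accuracy,
    vfold_split,
)


class ConstantClassifier(ClassifierMixin, BaseEstimator):
    """Always predicts a fixed label; for hand-workable CV checks."""

    def __init__(self, constant=1):
        self.constant = constant

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.full(len(X), self.constant)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=1, FP=0, TN=1, FN=0))
        assert all(m[k] == 1.0 for k in ("acc", "precision", "recall", "specificity"))
        assert m["undefined"] == {}

    def test_undefined_precision_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=1, FN=1))
        assert m["precision"] is None
        assert "precision" in m["undefined"]
        assert m["recall"] == 0.0
        assert m["specificity"] == 1.0
        assert m["acc"] == 0.5

    def test_hand_arithmetic(self):
        m = metrics(ConfusionCounts(TP=50, FP=10, TN=30, FN=10))
        assert m["acc"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(50 / 60)
        assert m["recall"] == pytest.approx(50 / 60)
        assert m["specificity"] == pytest.approx(0.75)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(TP=0, FP=0, TN=0, FN=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)

    def test_from_labels(self):
        counts = ConfusionCounts.from_labels([1, 1, 0, 0], [1, 0, 0, 1])
        assert (counts.TP, counts.FN, counts.TN, counts.FP) == (1, 1, 1, 1)


class TestVfoldSplit:
    def test_ten_singletons(self):
        folds = vfold_split(np.arange(10) % 2, V=10, seed=0, stratify=False)
        assert len(folds) == 10
        assert all(len(f) == 1 for f in folds)

    def test_sizes_differ_by_at_most_one(self):
        y = np.arange(12) % 2
        folds = vfold_split(y, V=10, seed=0, stratify=False)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [1] * 8 + [2, 2]

    def test_partition_property(self):
        y = np.random.default_rng(1).integers(0, 2, size=37)
        folds = vfold_split(y, V=5, seed=3)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(37))

    def test_stratification_balances_classes(self):
        y = np.array([0] * 40 + [1] * 10)
        folds = vfold_split(y, V=5, seed=0, stratify=True)
        for f in folds:
            assert np.sum(y[f] == 1) == 2

    def test_fixed_seed_reproducible(self):
        y = np.arange(30) % 2
        a = vfold_split(y, V=4, seed=9)
        b = vfold_split(y, V=4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            vfold_split(np.arange(3), V=4)


class TestCrossValidate:
    def test_hand_worked_two_fold_constant_classifier(self):
        # 2 positives + 2 negatives, always-positive classifier:
        # each stratified fold holds 1 pos + 1 neg -> TP=1, FP=1.
        X = np.arange(8, dtype=float).reshape(4, 2)
        y = np.array([1, 1, 0, 0])
        report = cross_validate(
            X, y, ConstantClassifier(constant=1), V=2, seed=0, positive=1
        )
        assert len(report.per_fold) == 2
        for fold in report.per_fold:
            assert fold["acc"] == 0.5
            assert fold["precision"] == 0.5
            assert fold["recall"] == 1.0
            assert fold["specificity"] == 0.0

    def test_mean_is_arithmetic_average_of_folds(self):
        report = MetricReport(
            per_fold=[
                {"acc": 0.8, "precision": 1.0, "recall": 0.5, "specificity": None,
                 "undefined": {"specificity": "x"}},
                {"acc": 0.6, "precision": 0.5, "recall": 1.0, "specificity": 0.9,
                 "undefined": {}},
            ]
        )
        assert report.mean["acc"] == pytest.approx(0.7)
        assert report.mean["precision"] == pytest.approx(0.75)
        assert report.mean["specificity"] == pytest.approx(0.9)  # defined folds only

    def test_memorizer_sanity_inversion(self, small_Xy):
        from sklearn.neighbors import KNeighborsClassifier

        X, y = small_Xy
        # train = test forced: 1-NN memorizes perfectly
        model = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        # honest CV on a noisy task stays below 1 on some fold or equals 1
        report = cross_validate(
            X, y, KNeighborsClassifier(n_neighbors=1), V=5, seed=0
        )
        assert all(0.0 <= f["acc"] <= 1.0 for f in report.per_fold)

    def test_scaler_fitted_on_training_portion_only(self, small_Xy):
        from mirloop.ensemble import BoostedHairpinClassifier

        X, y = small_Xy
        folds = vfold_split(y, V=4, seed=2)
        test_idx = folds[0]
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        clf = BoostedHairpinClassifier(n_rounds=1, random_state=0)
        clf.fit(X[train_idx], y[train_idx])
        mean_before = clf.scaler_.mean_.copy()
        # permuting test labels (or the test block itself) cannot touch it
        clf2 = BoostedHairpinClassifier(n_rounds=1, random_state=0)
        clf2.fit(X[train_idx], y[train_idx])
        np.testing.assert_array_equal(mean_before, clf2.scaler_.mean_)
        expected = X[train_idx].mean(axis=0)
        np.testing.assert_allclose(clf.scaler_.mean_, expected)

    def test_report_frame_has_mean_row(self):
        report = MetricReport(
            per_fold=[
                {"acc": 1.0, "precision": 1.0, "recall": 1.0, "specificity": 1.0,
                 "undefined": {}}
            ]
        )
        frame = report.to_frame()
        assert list(frame["fold"]) == [0, "mean"]


class TestSpeciesAccuracy:
    def test_per_class_and_pooled(self):
        y_true = ["a", "a", "b", "b", "c"]
        y_pred = ["a", "b", "b", "b", "a"]
        acc = species_accuracy(y_true, y_pred)
        assert acc["per_class"] == {"a": 0.5, "b": 1.0, "c": 0.0}
        assert acc["total"] == pytest.approx(3 / 5)
        assert acc["mean_per_class"] == pytest.approx(0.5)
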