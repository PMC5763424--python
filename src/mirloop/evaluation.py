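"""Confusion-matrix metrics and V-fold cross-validation.

Metrics on binary calls: accuracy (TP+TN)/total, precision TP/(TP+FP),
recall TP/(TP+FN) and specificity TN/(TN+FP).  A metric whose denominator
is zero is reported as an explicit ``None`` with a reason, never a silent
NaN.  Cross-validation partitions the data into V folds (stratified by
default), trains on V-1 and tests on the held-out fold, and averages the
per-fold metrics arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "metrics",
    "vfold_split",
    "cross_validate",
    "species_accuracy",
    "METRIC_NAMES",
]

METRIC_NAMES = ("acc", "precision", "recall", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_labels(cls, y_true, y_pred, positive=1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred differ in shape")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            TP=int(np.sum(pos_t & pos_p)),
            FP=int(np.sum(~pos_t & pos_p)),
            TN=int(np.sum(~pos_t & ~pos_p)),
            FN=int(np.sum(pos_t & ~pos_p)),
        )


def metrics(counts: ConfusionCounts) -> dict:
    """The four evaluation metrics from confusion counts.

    Returns a dict with keys ``acc``, ``precision``, ``recall``,
    ``specificity`` (floats in [0, 1] or ``None``) plus ``undefined``, a
    dict mapping each undefined metric to the reason.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples (total = 0)")
    result: dict = {"undefined": {}}
    result["acc"] = (counts.TP + counts.TN) / counts.total

    def ratio(name, num, denom, denom_desc):
        if denom == 0:
            result[name] = None
            result["undefined"][name] = f"denominator {denom_desc} is zero"
        else:
            result[name] = num / denom

    ratio("precision", counts.TP, counts.TP + counts.FP, "TP+FP")
    ratio("recall", counts.TP, counts.TP + counts.FN, "TP+FN")
    ratio("specificity", counts.TN, counts.TN + counts.FP, "TN+FP")
    return result


def vfold_split(y, V: int = 10, seed: int | None = None, stratify: bool = True):
    """Partition ``len(y)`` records into V folds of near-equal size.

    Returns a list of V test-index arrays that are disjoint and jointly
    cover every record; sizes differ by at most 1.  Stratified by the
    labels in ``y`` when requested (the default — class imbalance makes
    unstratified folds degenerate at small scale).
    """
    y = np.asarray(y)
    n = len(y)
    if V < 2:
        raise ValueError("V must be >= 2")
    if V > n:
        raise ValueError(f"V={V} exceeds dataset size {n}")
    if stratify:
        splitter = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(np.zeros(n), y)]
    else:
        splitter = KFold(n_splits=V, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(np.zeros(n))]
    return folds


@dataclass
class MetricReport:
    """Per-fold metrics plus their arithmetic mean.

    ``per_fold`` holds one metrics dict per evaluated fold (see
    :func:`metrics`); ``mean`` averages each metric over the folds where it
    is defined.  ``skipped`` records folds left out (e.g. a single-class
    training portion) with reasons.
    """

    per_fold: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    @property
    def mean(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = [f[name] for f in self.per_fold if f[name] is not None]
            out[name] = float(np.mean(vals)) if vals else None
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, **{m: f[m] for m in METRIC_NAMES}}
            for i, f in enumerate(self.per_fold)
        ]
        rows.append({"fold": "mean", **self.mean})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "skipped": self.skipped,
        }


def cross_validate(
    X,
    y,
    estimator,
    V: int = 10,
    seed: int | None = None,
    stratify: bool = True,
    positive=None,
) -> MetricReport:
    """V-fold cross-validation of a classifier.

    The estimator is cloned and refitted per fold, so any preprocessing it
    owns (e.g. feature standardization) is fitted on the training portion
    only — test records never leak into scaling.  ``positive`` names the
    positive class for the confusion counts (default: the larger label).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if positive is None:
        positive = np.unique(y)[-1]
    folds = vfold_split(y, V=V, seed=seed, stratify=stratify)
    all_idx = np.arange(len(y))
    report = MetricReport()
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(np.unique(y[train_idx])) < 2:
            report.skipped.append(
                {"fold": fold_no, "reason": "single-class training portion"}
            )
            continue
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        y_pred = model.predict(X[test_idx])
        counts = ConfusionCounts.from_labels(y[test_idx], y_pred, positive=positive)
        report.per_fold.append(metrics(counts))
    return report


def species_accuracy(y_true, y_pred) -> dict:
    """Per-class accuracy for multi-class calls.

    For each class: correctly-called-in-class / true-in-class.  Also
    reports ``total`` (pooled overall correct fraction) and
    ``mean_per_class`` (unweighted mean of the per-class accuracies).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in shape")
    per_class = {}
    for cls in np.unique(y_true):
        in_class = y_true == cls
        per_class[str(cls)] = float(np.mean(y_pred[in_class] == cls))
    defined = list(per_class.values())
    return {
        "per_class": per_class,
        "total": float(np.mean(y_pred == y_true)),
        "mean_per_class": float(np.mean(defined)),
    }
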