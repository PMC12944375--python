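"""Confusion-matrix statistics, k-fold cross-validation and y-randomisation.

Six statistics summarise a binary confusion matrix:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    PRE = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2*TP / (2*TP + FP + FN)

The positive class defaults to *low* toxicity (the minority class in the
reference data); every report records the convention.  Metrics whose
denominator is zero are reported as 0 and flagged rather than NaN, so
batch reports never fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import ToxClass, ValidationError
from .models import EstimatorSpec, stratified_folds, train_estimator, _as_array, _encode

METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "F1", "MCC")


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int
    positive_class: ToxClass = ToxClass.LOW

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    ACC: float
    SEN: float
    SPE: float
    PRE: float
    F1: float
    MCC: float
    zero_denominator: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def __str__(self) -> str:
        parts = [f"{m}={getattr(self, m):.3f}" for m in METRIC_NAMES]
        if self.zero_denominator:
            parts.append(f"(zero denominator: {', '.join(self.zero_denominator)})")
        return " ".join(parts)


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_class: ToxClass = ToxClass.LOW
) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN with the stated positive class."""
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred lengths differ")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        t_pos = t == positive_class
        p_pos = p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and not p_pos:
            tn += 1
        elif p_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionMatrix(tp, tn, fp, fn, positive_class)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Evaluate the six confusion-matrix statistics exactly."""
    if cm.n < 1:
        raise ValidationError("empty confusion matrix")
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    flags: list[str] = []
    acc = _safe_div(tp + tn, cm.n, "ACC", flags)
    sen = _safe_div(tp, tp + fn, "SEN", flags)
    spe = _safe_div(tn, tn + fp, "SPE", flags)
    pre = _safe_div(tp, tp + fp, "PRE", flags)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    return MetricsReport(acc, sen, spe, pre, f1, mcc, flags)


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    n_folds: int
    seed: int
    positive_class: ToxClass = ToxClass.LOW

    def mean(self) -> dict[str, float]:
        return {m: float(np.mean([getattr(r, m) for r in self.per_fold]))
                for m in METRIC_NAMES}

    def sd(self) -> dict[str, float]:
        vals = {m: [getattr(r, m) for r in self.per_fold] for m in METRIC_NAMES}
        return {m: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                for m, v in vals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.per_fold]
        df = pd.DataFrame(rows, index=[f"fold_{i + 1}" for i in range(len(rows))])
        df.loc["mean"] = self.mean()
        df.loc["sd"] = self.sd()
        return df


def kfold_cv(
    X,
    y,
    spec: EstimatorSpec | str,
    params: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
    positive_class: ToxClass = ToxClass.LOW,
) -> CVReport:
    """Stratified k-fold cross-validation of one hyperparameter candidate.

    Each fold serves once as the validation set; the six statistics are
    computed per fold from that fold's confusion matrix, then averaged.
    """
    family = spec.family if isinstance(spec, EstimatorSpec) else spec
    params = dict(params or {})
    arr = _as_array(X)
    y_enc = _encode(y)
    fold = stratified_folds(y_enc, n_folds, seed)
    classes = [ToxClass.LOW, ToxClass.HIGH]
    reports = []
    for f in range(n_folds):
        tr, va = fold != f, fold == f
        est = train_estimator(family, params, arr[tr], y_enc[tr], seed=seed)
        pred = est.predict(arr[va])
        cm = confusion(
            [classes[v] for v in y_enc[va]],
            [classes[v] for v in pred],
            positive_class,
        )
        reports.append(metrics(cm))
    return CVReport(reports, n_folds, seed, positive_class)


@dataclass
class YRandReport:
    per_iteration: list[MetricsReport]
    n_iterations: int
    seed: int
    positive_class: ToxClass = ToxClass.LOW

    @property
    def mean_acc(self) -> float:
        return float(np.mean([r.ACC for r in self.per_iteration]))

    @property
    def sd_acc(self) -> float:
        accs = [r.ACC for r in self.per_iteration]
        return float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.MCC for r in self.per_iteration]))

    @property
    def sd_mcc(self) -> float:
        mccs = [r.MCC for r in self.per_iteration]
        return float(np.std(mccs, ddof=1)) if len(mccs) > 1 else 0.0

    def __str__(self) -> str:
        return (
            f"y-randomisation ({self.n_iterations} iterations): "
            f"ACC {self.mean_acc:.3f} ± {self.sd_acc:.3f}, "
            f"MCC {self.mean_mcc:.3f} ± {self.sd_mcc:.3f}"
        )


def y_randomization(
    X_train,
    y_train,
    X_test,
    y_test,
    spec: EstimatorSpec | str,
    params: dict | None = None,
    n_iter: int = 10,
    seed: int = 0,
    positive_class: ToxClass = ToxClass.LOW,
) -> YRandReport:
    """Refit on permuted training labels and score on the untouched test set.

    A genuine structure-activity relationship collapses under label
    permutation: mean ACC falls toward the class-prior baseline and mean
    MCC toward 0.  Permutation preserves the training class counts.
    """
    family = spec.family if isinstance(spec, EstimatorSpec) else spec
    params = dict(params or {})
    Xtr, Xte = _as_array(X_train), _as_array(X_test)
    ytr, yte = _encode(y_train), _encode(y_test)
    classes = [ToxClass.LOW, ToxClass.HIGH]
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_iter):
        y_perm = ytr[rng.permutation(len(ytr))]
        est = train_estimator(family, params, Xtr, y_perm,
                              seed=int(rng.integers(2**31 - 1)))
        pred = est.predict(Xte)
        cm = confusion(
            [classes[v] for v in yte],
            [classes[v] for v in pred],
            positive_class,
        )
        reports.append(metrics(cm))
    return YRandReport(reports, n_iter, seed, positive_class)
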