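"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, k-fold CV, DOR.

Multiclass sensitivity/specificity/F1 are macro-averaged one-vs-rest; the
binary view used for the diagnostic odds ratio collapses low + high into an
"abnormal" class against "normal".  ROC/AUC and the confusion-matrix tally
delegate to scikit-learn; the diagnostic odds ratio applies the
Haldane-Anscombe +0.5 correction when any off-diagonal cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_curve",
    "k_fold_cv",
    "diagnostic_odds_ratio",
]


@dataclass
class ConfusionMatrix:
    """Integer count matrix, rows = true classes, columns = predicted."""

    counts: np.ndarray
    classes: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def binary_view(self, positive) -> "ConfusionMatrix":
        """Collapse to [positive, rest] 2x2 counts."""
        classes = list(self.classes)
        if positive not in classes:
            raise ValueError(f"unknown positive class {positive!r}")
        i = classes.index(positive)
        tp = self.counts[i, i]
        fn = self.counts[i].sum() - tp
        fp = self.counts[:, i].sum() - tp
        tn = self.total - tp - fn - fp
        return ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), [positive, "rest"])


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float = float("nan")
    dor: float = float("nan")
    roc_points: list = field(default_factory=list)
    folds: list = field(default_factory=list)
    per_class: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true class i, predicted class j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    known = set(classes)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        unknown = set(arr.tolist()) - known
        if unknown:
            raise ValueError(f"{name} contains labels outside classes: {sorted(map(str, unknown))}")
    counts = _skm.confusion_matrix(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(counts, list(classes))


def _binary_rates(tp, fn, fp, tn, flags):
    def _safe(num, den, name):
        if den == 0:
            flags.append(f"zero denominator for {name}; reported 0")
            return 0.0
        return num / den

    sens = _safe(tp, tp + fn, "sensitivity")
    spec = _safe(tn, tn + fp, "specificity")
    prec = _safe(tp, tp + fp, "precision")
    f1 = _safe(2 * prec * sens, prec + sens, "f1") if (prec + sens) > 0 else 0.0
    return sens, spec, f1


def classification_metrics(cm: ConfusionMatrix, positive=None) -> MetricsReport:
    """Sensitivity, specificity, accuracy and F1 from a confusion matrix.

    With ``positive`` given (or a 2x2 matrix) the rates are the plain binary
    definitions; otherwise each class is treated one-vs-rest and the rates
    are macro-averaged (per-class values are reported alongside).  Cells
    with a zero denominator yield 0 with a warning flag rather than NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    accuracy = float(np.trace(cm.counts)) / cm.total
    if positive is not None or len(cm.classes) == 2:
        bv = cm if len(cm.classes) == 2 and positive is None else cm.binary_view(positive)
        (tp, fn), (fp, tn) = bv.counts
        sens, spec, f1 = _binary_rates(tp, fn, fp, tn, flags)
        if flags:
            warnings.warn("; ".join(flags), stacklevel=2)
        return MetricsReport(sens, spec, accuracy, f1, flags=flags)
    per_class = {}
    for cls in cm.classes:
        (tp, fn), (fp, tn) = cm.binary_view(cls).counts
        per_class[cls] = _binary_rates(tp, fn, fp, tn, flags)
    sens = float(np.mean([v[0] for v in per_class.values()]))
    spec = float(np.mean([v[1] for v in per_class.values()]))
    f1 = float(np.mean([v[2] for v in per_class.values()]))
    if flags:
        warnings.warn("; ".join(flags), stacklevel=2)
    return MetricsReport(
        sens,
        spec,
        accuracy,
        f1,
        per_class={c: {"sensitivity": v[0], "specificity": v[1], "f1": v[2]} for c, v in per_class.items()},
        flags=flags,
    )


def roc_curve(scores, labels, positive=1):
    """Threshold-sweep ROC points and trapezoidal AUC.

    ``scores`` are positive-class probabilities.  Ties step simultaneously;
    the AUC equals the Mann-Whitney U statistic normalized by n1 * n0.
    Returns ``(points, auc)`` with points a list of (fpr, tpr) pairs.
    """
    labels = np.asarray(labels)
    y = (labels == positive).astype(int) if labels.dtype != bool else labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_curve needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def k_fold_cv(X, y, estimator, k: int = 5, seed: int = 0):
    """Stratified k-fold cross-validation, retraining per fold.

    The estimator is cloned for every fold; if it exposes a ``seed``
    parameter, each fold gets a fold-index-derived seed so retraining is
    reproducible yet independent across folds.  Returns (per-fold
    accuracies, mean).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = np.asarray(X)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = clone(estimator)
        if "seed" in est.get_params():
            est.set_params(seed=seed * 1000 + fold)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return accs, float(np.mean(accs))


def diagnostic_odds_ratio(cm: ConfusionMatrix):
    """DOR = (TP * TN) / (FP * FN) on a binary confusion matrix.

    Any zero off-diagonal cell triggers the Haldane-Anscombe +0.5 correction
    on all four cells; the returned flag says whether it was applied.
    Returns ``(dor, corrected)``.
    """
    if cm.counts.shape != (2, 2):
        raise ValueError("diagnostic_odds_ratio needs a binary confusion matrix")
    (tp, fn), (fp, tn) = cm.counts.astype(float)
    corrected = fp == 0 or fn == 0
    if corrected:
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
    return float((tp * tn) / (fp * fn)), bool(corrected)
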