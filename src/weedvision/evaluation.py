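"""Confusion matrices, accuracy, per-class sensitivity, ROC/AUC and
repetition statistics.

Class order is fixed as (1 rice, 2 narrow-leaf weed, 3 wide-leaf weed);
confusion rows are actual classes, columns predicted. Overall accuracy is
100 x trace / total, rounded half-up to two decimals to mirror tabulated
reporting. ROC curves are one-vs-rest threshold sweeps on continuous
class scores with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

CLASSES = (1, 2, 3)


def confusion(actual, predicted, classes=CLASSES) -> np.ndarray:
    """counts[a][p] over the fixed class order; rows actual, cols predicted."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValueError("label sequences must have equal length")
    if actual.size == 0:
        return np.zeros((len(classes), len(classes)), dtype=int)
    valid = set(classes)
    if not (set(actual) <= valid and set(predicted) <= valid):
        raise ValueError(f"labels outside class set {classes}")
    return _sk_confusion(actual, predicted, labels=list(classes))


def overall_accuracy(cm: np.ndarray) -> float:
    """100 x trace / total, half-up rounded to 2 decimals."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    pct = float(100.0 * np.trace(cm) / total)
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def class_sensitivity(cm: np.ndarray, cls: int, classes=CLASSES) -> float:
    """Recall of one class: diagonal count over the actual row total."""
    cm = np.asarray(cm)
    k = classes.index(cls)
    row = cm[k].sum()
    if row == 0:
        raise ValueError(f"no actual samples of class {cls}: sensitivity undefined")
    return float(cm[k, k] / row)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, actual, cls: int) -> ROCCurve:
    """One-vs-rest ROC of class ``cls`` from per-sample class scores."""
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual, dtype=int)
    positives = (actual == cls).astype(int)
    if positives.sum() == 0 or positives.sum() == len(positives):
        raise ValueError("need at least one positive and one negative sample")
    fpr, tpr, thr = _sk_roc(positives, scores)
    return ROCCurve(thr, fpr, tpr, float(_sk_auc(fpr, tpr)))


def repetition_stats(accuracies) -> tuple[float, float]:
    """Sample mean and sample standard deviation over repeated runs."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 repetitions")
    return float(acc.mean()), float(acc.std(ddof=1))


def metrics_report(actual, predicted, scores=None, classes=CLASSES) -> dict:
    """Bundle of confusion matrix, accuracy, sensitivities and AUCs."""
    cm = confusion(actual, predicted, classes)
    report = {
        "confusion_matrix": cm.tolist(),
        "overall_accuracy": overall_accuracy(cm),
        "sensitivity": {},
        "auc": {},
    }
    for k, c in enumerate(classes):
        if cm[k].sum() > 0:
            report["sensitivity"][str(c)] = class_sensitivity(cm, c, classes)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        for k, c in enumerate(classes):
            try:
                report["auc"][str(c)] = roc_curve(scores[:, k], actual, c).auc
            except ValueError:
                pass
    return report
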