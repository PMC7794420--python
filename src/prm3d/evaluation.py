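"""Classification performance metrics: confusion matrix, rates, ROC and AUC.

COPD is the positive class throughout; a predicted probability exactly at
the threshold counts as positive.  The primary report pools the held-out
predictions of all cross-validation folds; a per-fold table can be computed
by calling these functions fold by fold.  Undefined ratios (zero
denominator) are reported as 0 with a warning, so degenerate inputs never
raise mid-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io import logger


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    specificity: float
    confusion: ConfusionMatrix | None = None
    roc: list[tuple[float, float]] = dc_field(default_factory=list)
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "specificity": self.specificity,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.confusion is not None:
            d.update(tp=self.confusion.tp, fn=self.confusion.fn,
                     fp=self.confusion.fp, tn=self.confusion.tn)
        return d


def confusion(predictions: list[tuple[float, int]] | np.ndarray,
              threshold: float = 0.5) -> ConfusionMatrix:
    """Counts from (P(COPD), label) pairs; label 1 = COPD.

    ``p >= threshold`` predicts COPD (ties positive).
    """
    arr = np.asarray(predictions, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no predictions")
    p, y = arr[:, 0], arr[:, 1].astype(int)
    pred = p >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, precision, sensitivity, F1 and specificity from counts."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return EvalReport(
        accuracy=(cm.tp + cm.tn) / cm.n,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        specificity=_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        confusion=cm,
    )


def roc_auc(predictions: list[tuple[float, int]] | np.ndarray
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a full threshold sweep, plus trapezoidal AUC.

    The trapezoidal AUC equals the Mann–Whitney probability that a random
    COPD subject scores above a random non-COPD subject (ties half-weighted).
    """
    arr = np.asarray(predictions, dtype=np.float64)
    p, y = arr[:, 0], arr[:, 1].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(y, p, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def evaluate_predictions(probs: np.ndarray, labels: np.ndarray,
                         threshold: float = 0.5) -> EvalReport:
    """Full report (threshold metrics + ROC/AUC) from pooled predictions."""
    preds = np.column_stack([probs, labels])
    report = metrics(confusion(preds, threshold))
    if len(np.unique(labels)) == 2:
        report.roc, report.auc = roc_auc(preds)
    return report


def per_fold_table(probs: np.ndarray, labels: np.ndarray, folds: np.ndarray):
    """Metrics per fold plus their unweighted mean (pandas DataFrame).

    Complements the pooled report: averaging fold-level rates and pooling
    the predictions give slightly different numbers when folds are uneven.
    """
    import pandas as pd

    rows = []
    for fold in np.unique(folds):
        sel = folds == fold
        rep = evaluate_predictions(probs[sel], labels[sel])
        row = {"fold": int(fold), **rep.as_dict()}
        row.pop("tp", None); row.pop("fn", None)
        row.pop("fp", None); row.pop("tn", None)
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean().to_dict()
    df = pd.concat([df, pd.DataFrame([{"fold": "mean", **mean}])],
                   ignore_index=True)
    return df
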