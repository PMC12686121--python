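"""Binary-classification evaluation: confusion counts, the four classic
indicators (sensitivity, precision, accuracy, F1) and the ROC/AUC.

Metrics are computed from the confusion counts by their defining formulas;
a zero denominator yields NaN together with an entry in ``undefined`` rather
than a silent 0.  The AUC is trapezoidal integration of the ROC curve over
all score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    roc_points: np.ndarray  # (n, 2) array of (FPR, TPR)
    auc: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
            "undefined": list(self.undefined),
        }


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity, precision, accuracy and F1 from confusion counts."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    out = {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "precision": ratio(tp, tp + fp, "precision"),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "f1"),
    }
    out["undefined"] = tuple(undefined)
    return out


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all thresholds and the trapezoidal AUC.

    Degenerate cases (all scores equal) reduce to the two-point diagonal,
    AUC 0.5.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y_true, scores)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """Full report from true labels and classifier scores/probabilities."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    m = metrics_from_counts(tp, tn, fp, fn)
    points, auc = roc_auc(y_true, scores)
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=m["sensitivity"], precision=m["precision"],
        accuracy=m["accuracy"], f1=m["f1"],
        roc_points=points, auc=auc, undefined=m["undefined"],
    )
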