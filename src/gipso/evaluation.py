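"""Binary classification metrics for the anomaly-detection task.

The positive class (label 1) is anomalous activity.  Besides the standard
confusion-matrix arithmetic — per-class precision/recall/F1, accuracy,
macro and support-weighted aggregates — this module provides the error-rate
objective (1 - accuracy) minimized during tuning, Cohen's kappa
kappa = (z_o - z_e) / (1 - z_e) tracked as the class-imbalance-robust
indicator, ROC/PR curve points, and a reconstruction routine that recovers
the integer confusion matrix behind a printed classification report — used
to tie published report rows back to exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion_matrix",
    "classification_report",
    "cohen_kappa",
    "error_rate",
    "reconstruct_confusion",
    "curve_points",
    "report_frame",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 counts; class 1 (anomalous) is the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def support(self) -> tuple[int, int]:
        """Actual class sizes (normal, anomalous) — the row sums."""
        return (self.tn + self.fp, self.fn + self.tp)


@dataclass(frozen=True)
class ClassificationReport:
    precision: tuple[float, float]  # (normal, anomalous)
    recall: tuple[float, float]
    f1: tuple[float, float]
    support: tuple[int, int]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionMatrix:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionMatrix(
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tp=int(np.sum((yt == 1) & (yp == 1))),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{what} undefined: zero denominator")
    return num / den


def classification_report(cm: ConfusionMatrix) -> ClassificationReport:
    """Per-class precision/recall/F1 with macro and support-weighted
    aggregates.  Degenerate (zero-support or never-predicted) classes raise
    rather than silently reporting 0."""
    s0, s1 = cm.support
    prec0 = _safe_div(cm.tn, cm.tn + cm.fn, "normal-class precision")
    prec1 = _safe_div(cm.tp, cm.tp + cm.fp, "anomalous-class precision")
    rec0 = _safe_div(cm.tn, s0, "normal-class recall")
    rec1 = _safe_div(cm.tp, s1, "anomalous-class recall")
    f1_0 = _safe_div(2 * prec0 * rec0, prec0 + rec0, "normal-class F1")
    f1_1 = _safe_div(2 * prec1 * rec1, prec1 + rec1, "anomalous-class F1")
    acc = _safe_div(cm.tn + cm.tp, cm.total, "accuracy")
    w0, w1 = s0 / cm.total, s1 / cm.total
    return ClassificationReport(
        precision=(prec0, prec1),
        recall=(rec0, rec1),
        f1=(f1_0, f1_1),
        support=(s0, s1),
        accuracy=acc,
        macro_precision=(prec0 + prec1) / 2,
        macro_recall=(rec0 + rec1) / 2,
        macro_f1=(f1_0 + f1_1) / 2,
        weighted_precision=w0 * prec0 + w1 * prec1,
        weighted_recall=w0 * rec0 + w1 * rec1,
        weighted_f1=w0 * f1_0 + w1 * f1_1,
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (z_o - z_e) / (1 - z_e), where z_o is the
    observed agreement (accuracy) and z_e the expected agreement from the
    marginal products."""
    n = cm.total
    if n == 0:
        raise ZeroDivisionError("kappa undefined on an empty matrix")
    zo = (cm.tn + cm.tp) / n
    pred0, pred1 = cm.tn + cm.fn, cm.fp + cm.tp
    s0, s1 = cm.support
    ze = (s0 * pred0 + s1 * pred1) / (n * n)
    if ze == 1.0:
        raise ZeroDivisionError("kappa undefined: degenerate single-class marginals")
    return (zo - ze) / (1.0 - ze)


def error_rate(cm: ConfusionMatrix) -> float:
    """The tuning objective: 1 - accuracy."""
    return 1.0 - _safe_div(cm.tn + cm.tp, cm.total, "accuracy")


def reconstruct_confusion(
    precision_by_class: tuple[float, float],
    recall_by_class: tuple[float, float],
    support_by_class: tuple[int, int],
    tol: float = 5e-7,
) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind a printed report row.

    Exhaustively searches the integer diagonal counts (correct normals in
    0..support0, correct anomalies in 0..support1), picks the pair minimizing
    the summed absolute deviation from the printed recalls, and verifies that
    the printed precisions are reproduced to the printed (6-decimal)
    precision.  Raises if no integer matrix is consistent.
    """
    s0, s1 = support_by_class
    r0, r1 = recall_by_class
    tn_grid = np.arange(s0 + 1)
    tp_grid = np.arange(s1 + 1)
    tn = int(tn_grid[np.argmin(np.abs(tn_grid / s0 - r0))])
    tp = int(tp_grid[np.argmin(np.abs(tp_grid / s1 - r1))])
    if abs(tn / s0 - r0) > tol or abs(tp / s1 - r1) > tol:
        raise ValueError(
            "no integer confusion matrix reproduces the printed recalls "
            f"({r0}, {r1}) at supports ({s0}, {s1})"
        )
    cm = ConfusionMatrix(tn=tn, fp=s0 - tn, fn=s1 - tp, tp=tp)
    p0 = cm.tn / (cm.tn + cm.fn)
    p1 = cm.tp / (cm.tp + cm.fp)
    if abs(p0 - precision_by_class[0]) > tol or abs(p1 - precision_by_class[1]) > tol:
        raise ValueError(
            "reconstructed matrix is inconsistent with the printed precisions: "
            f"got ({p0:.6f}, {p1:.6f}), printed {precision_by_class}"
        )
    return cm


def curve_points(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """ROC and PR points from a sweep over the unique score thresholds.

    Returns (roc, pr): roc rows are (fpr, tpr) ascending in fpr, pr rows are
    (recall, precision).  Predictions at a threshold are score >= threshold.
    """
    yt = np.asarray(y_true)
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise ValueError("length mismatch")
    n_pos = int(yt.sum())
    n_neg = len(yt) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present in y_true")
    thresholds = np.unique(sc)[::-1]
    roc = [(0.0, 0.0)]
    pr = []
    for thr in thresholds:
        pred = sc >= thr
        tp = int(np.sum(pred & (yt == 1)))
        fp = int(np.sum(pred & (yt == 0)))
        roc.append((fp / n_neg, tp / n_pos))
        if tp + fp:
            pr.append((tp / n_pos, tp / (tp + fp)))
    roc.append((1.0, 1.0))
    return np.array(sorted(set(roc))), np.array(pr)


def report_frame(report: ClassificationReport) -> pd.DataFrame:
    """Tabular layout of a report: per-class rows plus accuracy/macro/weighted
    columns, ready for CSV export."""
    return pd.DataFrame(
        {
            "metric": ["precision", "recall", "f1"],
            "normal": [report.precision[0], report.recall[0], report.f1[0]],
            "anomalous": [report.precision[1], report.recall[1], report.f1[1]],
            "accuracy": [report.accuracy] * 3,
            "macro_avg": [
                report.macro_precision,
                report.macro_recall,
                report.macro_f1,
            ],
            "weighted_avg": [
                report.weighted_precision,
                report.weighted_recall,
                report.weighted_f1,
            ],
        }
    )
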