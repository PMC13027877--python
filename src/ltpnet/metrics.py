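"""Pixel-level evaluation: confusion counts, the five headline metrics,
and PR/ROC curves with trapezoidal AUCs.

The IoU reported here is the foreground (lesion) IoU computed on counts
aggregated over all evaluated pixels, which makes the algebraic identity
``iou = dsc / (2 - dsc)`` hold exactly for any confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import InputError, ShapeError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "segmentation_metrics",
    "pr_roc",
    "Curves",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    miou: float
    dsc: float
    acc: float
    spe: float
    sen: float
    auc_pr: float | None = None
    auc_roc: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _as_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise InputError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Exact pixel counts aggregated over everything passed in."""
    pred = _as_binary(pred, "prediction")
    gt = _as_binary(gt, "ground truth")
    if pred.shape != gt.shape:
        raise ShapeError(f"prediction {pred.shape} vs ground truth {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def segmentation_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive pixels in ground truth")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative pixels in ground truth")
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else 1.0
    miou = c.tp / (c.tp + c.fp + c.fn) if (c.tp + c.fp + c.fn) else 1.0
    return MetricsReport(miou=miou, dsc=dsc, acc=acc, spe=spe, sen=sen)


@dataclass(frozen=True)
class Curves:
    """Threshold sweep: one row per distinct score, plus the end points."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc_pr: float
    auc_roc: float


def pr_roc(scores, labels) -> Curves:
    """PR and ROC curves over the unique score values, with trapezoidal AUCs.

    Predicted positive iff score >= threshold, matching the mask rule.
    """
    scores = np.ravel(np.asarray(scores, dtype=float))
    labels = _as_binary(np.ravel(labels), "labels")
    if scores.shape != labels.shape:
        raise ShapeError("scores and labels must have matching sizes")
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise UndefinedMetricError("curves undefined: ground truth contains one class only")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # collapse ties: evaluate only at the last index of each distinct score
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(sorted_labels)[idx].astype(float)
    fp = (idx + 1) - tp
    tpr = tp / pos
    fpr = fp / neg
    precision = tp / (tp + fp)
    recall = tpr
    # prepend the (0, 0) operating point (threshold above every score)
    tpr_c = np.concatenate([[0.0], tpr])
    fpr_c = np.concatenate([[0.0], fpr])
    rec_c = np.concatenate([[0.0], recall])
    prec_c = np.concatenate([[1.0 if precision.size == 0 else precision[0]], precision])
    auc_roc = float(np.trapezoid(tpr_c, fpr_c))
    auc_pr = float(np.trapezoid(prec_c, rec_c))
    return Curves(
        thresholds=sorted_scores[idx],
        precision=precision,
        recall=recall,
        tpr=tpr,
        fpr=fpr,
        auc_pr=auc_pr,
        auc_roc=auc_roc,
    )
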