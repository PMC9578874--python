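"""Binary-classification evaluation: confusion counts, the four scalar
metrics, and the ROC curve with trapezoidal AUC.

The positive class is 1 = fatigued throughout. Metrics whose denominator
is empty (e.g. precision with no positive predictions) return 0.0 and the
affected metric name is listed in the ``flags`` of the result rather than
propagating a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, InvalidDataError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")
        if self.n == 0:
            raise InvalidArgumentError("confusion counts must cover at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1) plus the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels and hard binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise InvalidArgumentError("labels and predictions must be equal-length 1-D")
    if y.size == 0:
        raise InvalidArgumentError("empty inputs")
    for arr, name in ((y, "labels"), (p, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise InvalidArgumentError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Recall, precision, accuracy and f1 from confusion counts.

    recall = TP/(TP+FN); precision = TP/(TP+FP); accuracy = (TP+TN)/n;
    f1 = harmonic mean of recall and precision. 0/0 cases return 0 and are
    flagged.
    """
    flags: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = (c.tp + c.tn) / c.n
    if recall + precision == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return {
        "recall": recall,
        "precision": precision,
        "accuracy": accuracy,
        "f1": f1,
        "flags": tuple(flags),
    }


def roc_auc(labels, scores) -> RocCurve:
    """ROC curve by threshold sweep over unique scores; trapezoidal AUC.

    Equal scores are grouped into a single step so ties contribute a sloped
    segment, making the trapezoidal area equal to the pairwise concordance
    probability P(s+ > s-) + 0.5 P(s+ = s-).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise InvalidArgumentError("labels and scores must be equal-length 1-D")
    if not np.isin(y, (0, 1)).all():
        raise InvalidArgumentError("labels must be binary 0/1")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise InvalidDataError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]

    # Collapse runs of equal score into one step.
    distinct = np.flatnonzero(np.diff(s_sorted)) + 1
    ends = np.concatenate((distinct, [s_sorted.size]))
    tp = np.cumsum(y_sorted)[ends - 1]
    fp = ends - tp
    tpr = np.concatenate(([0.0], tp / n_pos, [1.0]))
    fpr = np.concatenate(([0.0], fp / n_neg, [1.0]))
    thresholds = np.concatenate(([np.inf], s_sorted[ends - 1], [-np.inf]))
    # Deduplicate the trailing point if the sweep already reached (1,1).
    if tpr[-2] == 1.0 and fpr[-2] == 1.0:
        tpr, fpr, thresholds = tpr[:-1], fpr[:-1], thresholds[:-1]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
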