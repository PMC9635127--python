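"""Confusion-matrix metrics, ROC/AUC and AUPRC for imbalanced binary data.

Conventions: a score >= threshold predicts the positive class; specificity
is TN/(TN+FP); MCC returns 0 whenever any factor of its denominator is zero;
AUC is the trapezoidal area under the ROC curve and is asserted internally
to match the Mann-Whitney U statistic (ties counted one half); AUPRC uses
the step-wise average-precision rule rather than trapezoidal interpolation,
which is known to be optimistic on precision-recall curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one item")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScoredLabels:
    """Parallel true labels (0/1) and real-valued scores in [0, 1]."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise ValueError("labels and scores must be parallel 1-D arrays")
        if self.labels.size < 1:
            raise ValueError("need at least one scored item")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


def confusion_at_threshold(data: ScoredLabels, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix with the score >= threshold rule."""
    pred = data.scores >= threshold
    pos = data.labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def basic_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); an empty denominator gives NaN."""
    acc = (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else float("nan")
    return acc, sens, spec


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    factors = [
        cm.tp + cm.fp,
        cm.tp + cm.fn,
        cm.tn + cm.fp,
        cm.tn + cm.fn,
    ]
    if any(f == 0 for f in factors):
        return 0.0
    num = cm.tp * cm.tn - cm.fp * cm.fn
    return float(num / np.sqrt(np.prod([float(f) for f in factors])))


def _check_two_classes(data: ScoredLabels) -> None:
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("ROC/AUC need at least one member of each class")


def roc_curve(data: ScoredLabels) -> np.ndarray:
    """(FPR, TPR) points at every distinct threshold, plus both endpoints.

    Returned as an (m, 2) array ordered by increasing FPR (and TPR), from
    (0, 0) to (1, 1). Ties in score move together, so a dataset with a
    single distinct score yields just the two endpoints.
    """
    _check_two_classes(data)
    order = np.argsort(-data.scores, kind="stable")
    labels = data.labels[order]
    scores = data.scores[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[scores[1:] != scores[:-1], True]
    tpr = tps[last_of_run] / data.n_pos
    fpr = fps[last_of_run] / data.n_neg
    pts = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:  # pragma: no cover - always ends at (1,1)
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def auc(data: ScoredLabels) -> float:
    """Area under the ROC curve.

    Computed twice — trapezoid over :func:`roc_curve` and as the normalised
    Mann-Whitney statistic with ties counted one half — and the two are
    required to agree to 1e-9, catching any drift between the curve and the
    ranking view of the same quantity.
    """
    pts = roc_curve(data)
    trapezoid = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    # Mann-Whitney via midranks
    ranks = _midranks(data.scores)
    u = ranks[data.labels == 1].sum() - data.n_pos * (data.n_pos + 1) / 2.0
    mw = u / (data.n_pos * data.n_neg)
    if abs(trapezoid - mw) > 1e-9:
        raise AssertionError(
            f"trapezoidal AUC {trapezoid!r} disagrees with Mann-Whitney {mw!r}"
        )
    return trapezoid


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def auprc(data: ScoredLabels) -> float:
    """Area under the precision-recall curve by the average-precision rule.

    AP = sum_k (R_k - R_{k-1}) * P_k over descending-score thresholds, with
    tied scores entering together.
    """
    if data.n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-data.scores, kind="stable")
    labels = data.labels[order]
    scores = data.scores[order]
    tps = np.cumsum(labels)
    preds = np.arange(1, labels.size + 1)
    last_of_run = np.r_[scores[1:] != scores[:-1], True]
    precision = tps[last_of_run] / preds[last_of_run]
    recall = tps[last_of_run] / data.n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def summarize(data: ScoredLabels, threshold: float = 0.5) -> dict[str, float]:
    """The six headline metrics at one threshold, as a plain dict."""
    cm = confusion_at_threshold(data, threshold)
    acc, sens, spec = basic_metrics(cm)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": auc(data),
        "mcc": mcc(cm),
        "auprc": auprc(data),
    }
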