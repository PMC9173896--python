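"""Confusion-matrix metrics, stratified splitting and ROC/PR curves.

Melanoma is the positive class throughout.  Per-class precision,
recall and F-score are computed from the 2x2 confusion matrix, the
"average" row of a report is the unweighted (macro) mean over the two
classes, and accuracy is shared by both orientations.  Percentages are
rounded half-up to two decimals at report time only; the unrounded
values are retained alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix2",
    "ClassMetrics",
    "MetricsReport",
    "stratified_split",
    "confusion",
    "metrics",
    "roc_points",
    "pr_points",
    "MELANOMA",
    "BENIGN",
]

MELANOMA = "melanoma"
BENIGN = "benign"


def round2(value: float) -> float:
    """Round half-up to 2 decimals (report convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix2:
    """Counts with melanoma as the positive class."""

    tp: int  # melanoma predicted melanoma
    fn: int  # melanoma predicted benign
    fp: int  # benign predicted melanoma
    tn: int  # benign predicted benign

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f_score: float

    def rounded(self) -> "ClassMetrics":
        return ClassMetrics(
            round2(self.precision), round2(self.recall), round2(self.f_score)
        )


@dataclass
class MetricsReport:
    confusion: ConfusionMatrix2
    accuracy: float
    melanoma: ClassMetrics
    benign: ClassMetrics
    macro: ClassMetrics
    zero_division_flag: bool = False
    roc: list[tuple[float, float]] = field(default_factory=list)  # (FPR, TPR)
    pr: list[tuple[float, float]] = field(default_factory=list)  # (recall, precision)

    def as_table(self) -> dict:
        """Rows Melanoma/Benign/Average with percent cells rounded
        half-up to 2 decimals, mirroring a standard results table."""
        acc = round2(self.accuracy)
        rows = {}
        for name, cm in (("Melanoma", self.melanoma), ("Benign", self.benign),
                         ("Average", self.macro)):
            r = cm.rounded()
            rows[name] = {
                "Accuracy": acc,
                "Precision": r.precision,
                "Recall": r.recall,
                "F-score": r.f_score,
            }
        return rows


def stratified_split(
    labels, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split: round(fraction * n_class) indices go to train.

    Returns (train_indices, test_indices); disjoint and exhaustive,
    deterministic given the seed.  Refuses single-class inputs and
    degenerate splits that leave either side empty.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("stratified split requires both classes present")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    if train.size == 0 or test.size == 0:
        raise ValueError("split leaves an empty train or test set")
    return train, test


def confusion(true_labels, predicted_labels) -> ConfusionMatrix2:
    """2x2 confusion counts; labels are 'melanoma' / 'benign' strings."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    pos_t = true_labels == MELANOMA
    pos_p = predicted_labels == MELANOMA
    return ConfusionMatrix2(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _prf(tp: int, fp: int, fn: int) -> tuple[ClassMetrics, bool]:
    flag = False

    def safe(num: float, den: float) -> float:
        nonlocal flag
        if den == 0:
            flag = True
            return 0.0
        return num / den

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    f_score = safe(2 * precision * recall, precision + recall)
    return (
        ClassMetrics(100 * precision, 100 * recall, 100 * f_score),
        flag,
    )


def metrics(cm: ConfusionMatrix2) -> MetricsReport:
    """Per-class and macro-averaged percent metrics from a 2x2 matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    mel, flag_m = _prf(cm.tp, cm.fp, cm.fn)
    ben, flag_b = _prf(cm.tn, cm.fn, cm.fp)
    flag = flag_m or flag_b
    if flag:
        warnings.warn(
            "zero-denominator metric reported as 0", RuntimeWarning, stacklevel=2
        )
    macro = ClassMetrics(
        (mel.precision + ben.precision) / 2,
        (mel.recall + ben.recall) / 2,
        (mel.f_score + ben.f_score) / 2,
    )
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricsReport(
        confusion=cm,
        accuracy=accuracy,
        melanoma=mel,
        benign=ben,
        macro=macro,
        zero_division_flag=flag,
    )


def _check_scores(true_labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = (np.asarray(true_labels) == MELANOMA).astype(int)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.unique(y).size < 2:
        raise ValueError("curves require both classes in the truth labels")
    return y, s


def roc_points(true_labels, scores) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) points from a threshold sweep."""
    from sklearn.metrics import roc_curve

    y, s = _check_scores(true_labels, scores)
    fpr, tpr, _ = roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(true_labels, scores) -> list[tuple[float, float]]:
    """Precision-recall curve as (recall, precision) points."""
    from sklearn.metrics import precision_recall_curve

    y, s = _check_scores(true_labels, scores)
    precision, recall, _ = precision_recall_curve(y, s)
    return list(zip(recall.tolist(), precision.tolist()))


def auc_of(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under a curve given as sorted-by-x points."""
    xs, ys = zip(*sorted(points))
    return float(np.trapezoid(ys, xs))
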