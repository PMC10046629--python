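"""Segmentation and classification metrics, fold statistics, reports.

Pixel metrics: accuracy (TP+TN)/total, IoU TP/(TP+FN+FP) and Dice
2TP/(2TP+FN+FP); the two overlap scores obey DSC = 2*IoU/(1+IoU) and
both score 1 when prediction and truth are both empty, so non-tumor
images reward correct empty predictions. Classification metrics come
from a 3x3 confusion matrix (rows true, columns predicted, class order
non-tumor / single / double) reduced one-vs-rest per class and averaged
with true-class-frequency weights; overall accuracy is trace/total.
Percentages are kept at full precision internally and rounded half-up
to two decimals only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PixelMetrics",
    "ClasswiseMetrics",
    "FoldStatistics",
    "pixel_metrics",
    "segmentation_metrics",
    "confusion_matrix",
    "classwise_metrics",
    "fold_statistics",
    "percent",
    "write_confusion",
    "plot_confusion",
]


def percent(x: float, decimals: int = 2) -> float:
    """Fraction -> percentage, decimal half-up rounding (97.5 % stays 97.5)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PixelMetrics:
    accuracy: float
    iou: float
    dice: float


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> PixelMetrics:
    """Accuracy/IoU/Dice of one binary mask pair; empty-vs-empty scores 1."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    acc = (tp + tn) / (tp + tn + fp + fn)
    if tp + fp + fn == 0:
        return PixelMetrics(accuracy=acc, iou=1.0, dice=1.0)
    iou = tp / (tp + fn + fp)
    dice = 2 * tp / (2 * tp + fn + fp)
    return PixelMetrics(accuracy=acc, iou=iou, dice=dice)


def segmentation_metrics(preds: list[np.ndarray], truths: list[np.ndarray],
                         pooled: bool = False) -> PixelMetrics:
    """Test-set segmentation scores.

    By default metrics are computed per image then averaged (the
    segmentation norm); ``pooled=True`` instead accumulates pixel counts
    over the whole set first.
    """
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, non-empty prediction/truth lists")
    if pooled:
        pred = np.concatenate([np.asarray(p).ravel() for p in preds])
        truth = np.concatenate([np.asarray(t).ravel() for t in truths])
        return pixel_metrics(pred, truth)
    per = [pixel_metrics(p, t) for p, t in zip(preds, truths)]
    return PixelMetrics(accuracy=float(np.mean([m.accuracy for m in per])),
                        iou=float(np.mean([m.iou for m in per])),
                        dice=float(np.mean([m.dice for m in per])))


def confusion_matrix(true_labels: np.ndarray, pred_labels: np.ndarray,
                     n_classes: int = 3) -> np.ndarray:
    """Rows = true class, columns = predicted class."""
    m = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(true_labels), np.asarray(pred_labels)):
        m[int(t), int(p)] += 1
    return m


@dataclass(frozen=True)
class ClasswiseMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        return {k: percent(getattr(self, k), decimals)
                for k in ("accuracy", "precision", "recall", "specificity", "f1")}


def _one_vs_rest(m: np.ndarray, c: int) -> ConfusionCounts:
    tp = int(m[c, c])
    fn = int(m[c].sum() - tp)
    fp = int(m[:, c].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classwise_metrics(confusion: np.ndarray) -> ClasswiseMetrics:
    """Weighted one-vs-rest metrics from a multiclass confusion matrix.

    Weights are true-class frequencies (row sums), which for balanced
    test sets reduce to the plain mean — and make weighted recall equal
    overall accuracy (trace/total) whenever row sums are equal.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    weights = m.sum(axis=1) / total
    precision = recall = specificity = f1 = 0.0
    for c in range(m.shape[0]):
        cc = _one_vs_rest(m, c)
        p = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else 0.0
        r = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0
        s = cc.tn / (cc.tn + cc.fp) if cc.tn + cc.fp else 0.0
        f = 2 * cc.tp / (2 * cc.tp + cc.fn + cc.fp) if cc.tp + cc.fn + cc.fp else 0.0
        precision += weights[c] * p
        recall += weights[c] * r
        specificity += weights[c] * s
        f1 += weights[c] * f
    return ClasswiseMetrics(accuracy=float(np.trace(m) / total),
                            precision=float(precision), recall=float(recall),
                            specificity=float(specificity), f1=float(f1))


@dataclass(frozen=True)
class FoldStatistics:
    mean: float
    std: float          # sample STD over folds (ddof=1)
    t_stat: float | None
    p_value: float | None
    degenerate: bool    # zero-variance paired differences (or < 2 folds)


def fold_statistics(per_fold: list[float],
                    baseline: list[float] | None = None) -> FoldStatistics:
    """Mean/STD over folds and a two-sided paired t-test versus a baseline."""
    values = np.asarray(per_fold, dtype=float)
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if baseline is None:
        return FoldStatistics(mean, std, None, None, False)
    base = np.asarray(baseline, dtype=float)
    if base.shape != values.shape:
        raise ValueError("model and baseline need equal fold counts")
    if values.size < 2:
        return FoldStatistics(mean, std, None, None, True)
    diffs = values - base
    if np.isclose(diffs.std(ddof=1), 0.0, atol=1e-12):
        # zero-variance differences: the paired t statistic is undefined.
        # Identical fold-for-fold -> p = 1; a constant non-zero shift is the
        # t -> +/-inf limit -> p = 0. Both are flagged degenerate.
        if np.isclose(diffs.mean(), 0.0, atol=1e-12):
            return FoldStatistics(mean, std, 0.0, 1.0, True)
        return FoldStatistics(mean, std, float(np.sign(diffs.mean()) * np.inf),
                              0.0, True)
    t, p = stats.ttest_rel(values, base)
    return FoldStatistics(mean, std, float(t), float(p), False)


# --- report output ---------------------------------------------------------

_CLASS_NAMES = ("non_tumor", "single_tumor", "double_tumor")


def write_confusion(confusion: np.ndarray, path) -> None:
    pd.DataFrame(confusion, index=list(_CLASS_NAMES),
                 columns=list(_CLASS_NAMES)).to_csv(path)


def plot_confusion(confusion: np.ndarray, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(confusion, cmap="Blues")
    for (i, j), v in np.ndenumerate(np.asarray(confusion)):
        ax.text(j, i, str(int(v)), ha="center", va="center")
    ax.set_xticks(range(len(_CLASS_NAMES)), _CLASS_NAMES, rotation=30)
    ax.set_yticks(range(len(_CLASS_NAMES)), _CLASS_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
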