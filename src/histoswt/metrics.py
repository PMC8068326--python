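"""Evaluation statistics for grading and segmentation.

Classification of the three histological grades is scored with one-vs-rest
ROC analysis.  *Micro*-averaging pools TP/FP/FN/TN over the K binary
sub-problems at each threshold before forming TPR and FPR; *macro*-averaging
computes per-class rates and averages them.  Two macro variants are provided:

``variant="curve"``
    The per-class TPR and FPR are averaged pointwise on the shared threshold
    grid and the AUC of the averaged parametric curve is returned.
``variant="mean"``
    The unweighted mean of the per-class one-vs-rest AUCs (the variant a
    pairwise concordance count reproduces exactly).

The two are not interchangeable in general — averaging curves over a
threshold parameter is not the same operation as averaging areas — so the
choice is explicit.

Segmentation is scored per class from one-vs-rest confusion counts:
IOU (Jaccard), Dice/F1, accuracy, precision, sensitivity and specificity,
with mIOU the unweighted mean of per-class IOU.  Cohen's kappa measures
chance-corrected agreement between two raters.  Fold-level results are
aggregated as mean +/- population standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import multilabel_confusion_matrix, roc_curve

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "MetricReport",
    "auc_micro",
    "auc_macro",
    "binary_auc",
    "confusion",
    "segmentation_suite",
    "cohen_kappa",
    "aggregate_folds",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _check_scores(truth, scores):
    truth = np.asarray(truth, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2:
        raise ValueError("scores must be an N x K matrix")
    n, k = scores.shape
    if truth.shape != (n,):
        raise ValueError("truth must have one entry per score row")
    if truth.min() < 0 or truth.max() >= k:
        raise ValueError("truth labels out of range [0, K)")
    return truth, scores


def binary_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Trapezoidal AUC of a single binary problem (ties traverse diagonally)."""
    y = np.asarray(y)
    if y.min() == y.max():
        raise UndefinedMetricError("binary AUC needs both a positive and a negative")
    fpr, tpr, _ = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr))


def auc_micro(truth, scores) -> float:
    """Micro-averaged one-vs-rest ROC-AUC.

    The K binary problems are pooled: TPR and FPR at each threshold are
    computed from summed TP/FN and FP/TN counts, and the AUC of the pooled
    curve is integrated by the trapezoid rule.
    """
    truth, scores = _check_scores(truth, scores)
    n, k = scores.shape
    onehot = np.zeros((n, k), dtype=np.int64)
    onehot[np.arange(n), truth] = 1
    pooled_y = onehot.ravel()
    if pooled_y.min() == pooled_y.max():
        raise UndefinedMetricError("pooled one-vs-rest labels are degenerate")
    return binary_auc(pooled_y, scores.ravel())


def auc_macro(truth, scores, variant: str = "curve") -> float:
    """Macro-averaged one-vs-rest ROC-AUC (see module docstring for variants)."""
    truth, scores = _check_scores(truth, scores)
    n, k = scores.shape
    for i in range(k):
        if not np.any(truth == i):
            raise UndefinedMetricError(f"class {i} absent from truth")
        if np.all(truth == i):
            raise UndefinedMetricError(f"class {i} has no negatives")
    if variant == "mean":
        return float(np.mean([binary_auc((truth == i).astype(int), scores[:, i])
                              for i in range(k)]))
    if variant != "curve":
        raise ValueError(f"unknown macro-AUC variant {variant!r}")
    # shared threshold grid: every observed score, swept from above the max
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = np.zeros((k, thresholds.size))
    fpr = np.zeros((k, thresholds.size))
    for i in range(k):
        pos = truth == i
        s = scores[:, i]
        above = s[:, None] >= thresholds[None, :]
        tpr[i] = above[pos].mean(axis=0)
        fpr[i] = above[~pos].mean(axis=0)
    tpr_macro = tpr.mean(axis=0)
    fpr_macro = fpr.mean(axis=0)
    return float(np.trapezoid(tpr_macro, fpr_macro))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN/TN counts over a set of scored units."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def __post_init__(self) -> None:
        totals = self.tp + self.fp + self.fn + self.tn
        if np.unique(totals).size > 1:
            raise ValueError("per-class counts must all sum to the same total")

    @property
    def k(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred, truth, k: int) -> ConfusionCounts:
    """One-vs-rest confusion counts per class for label planes or vectors."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same shape")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= k:
            raise ValueError(f"{name} labels out of range [0, {k})")
    m = multilabel_confusion_matrix(truth, pred, labels=np.arange(k))
    # sklearn layout: [[tn, fp], [fn, tp]] per class
    return ConfusionCounts(tp=m[:, 1, 1], fp=m[:, 0, 1], fn=m[:, 1, 0], tn=m[:, 0, 0])


def _safe_div(num, den, name):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(f"{name} undefined for classes {list(np.flatnonzero(~ok))} "
                      "(zero denominator); excluded from aggregation", RuntimeWarning)
    return out


def segmentation_suite(cc: ConfusionCounts) -> dict[str, float | np.ndarray]:
    """The six per-class segmentation measures plus mIOU.

    Undefined ratios (zero denominator) are reported as NaN with a warning and
    excluded from class-averaged aggregates, rather than silently coerced to 0.
    """
    tp, fp, fn, tn = (a.astype(np.float64) for a in (cc.tp, cc.fp, cc.fn, cc.tn))
    per_class = {
        "iou": _safe_div(tp, tp + fp + fn, "IOU"),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
        "acc": _safe_div(tp + tn, tp + tn + fp + fn, "ACC"),
        "precision": _safe_div(tp, tp + fp, "Precision"),
        "sensitivity": _safe_div(tp, tp + fn, "Sensitivity"),
        "specificity": _safe_div(tn, tn + fp, "Specificity"),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        miou = float(np.nanmean(per_class["iou"]))
    return {"per_class": per_class, "miou": miou,
            **{name: float(np.nanmean(v)) for name, v in per_class.items()}}


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal-product chance agreement.

    Perfect agreement with degenerate marginals (p_e == 1) is defined as 1.0.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1-D sequences")
    labels = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = float(sum((np.mean(a == lab)) * (np.mean(b == lab)) for lab in labels))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class MetricReport:
    """Mean +/- sigma per metric across folds, with raw per-fold values kept."""

    per_fold: list[dict[str, float]] = field(default_factory=list)

    @property
    def metrics(self) -> dict[str, tuple[float, float]]:
        if not self.per_fold:
            return {}
        keys = set(self.per_fold[0])
        for d in self.per_fold[1:]:
            if set(d) != keys:
                raise ValueError("inconsistent metric keys across folds")
        out = {}
        for key in sorted(keys):
            vals = np.array([d[key] for d in self.per_fold], dtype=np.float64)
            # population (divide-by-n) standard deviation
            out[key] = (float(vals.mean()), float(vals.std()))
        return out

    def mean(self, key: str) -> float:
        return self.metrics[key][0]

    def sigma(self, key: str) -> float:
        return self.metrics[key][1]

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "summary": {k: {"mean": m, "sigma": s} for k, (m, s) in self.metrics.items()},
        }


def aggregate_folds(per_fold: list[dict[str, float]]) -> MetricReport:
    """Aggregate per-fold metric dictionaries into a MetricReport."""
    if not per_fold:
        raise ValueError("need at least one fold")
    report = MetricReport(per_fold=list(per_fold))
    report.metrics  # validates key consistency eagerly
    return report
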