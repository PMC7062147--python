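"""Evaluation metrics: angle error, classification scores, fold averaging.

Angle regression is scored by the mean absolute error between actual (AJ)
and predicted (PJ) joint angle, reported as a percentage of the actual
angle's dynamic range (the normalization is configurable), plus the Pearson
correlation between the traces.  Classification is scored with one-vs-rest
true/false positive/negative counts per class — precision TP/(TP+FP),
recall TP/(TP+FN), F1 their harmonic mean, accuracy (TP+TN)/total x 100 —
alongside the overall multiclass accuracy and a row-normalized confusion
matrix.  Fold-level reports are aggregated as mean +/- sample standard
deviation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .movements import N_CLASSES


def absolute_error(aj: np.ndarray, pj: np.ndarray) -> np.ndarray:
    """Signed elementwise error AJ - PJ (absolute value taken downstream)."""
    aj = np.asarray(aj, dtype=float)
    pj = np.asarray(pj, dtype=float)
    if aj.shape != pj.shape:
        raise ValueError(f"shape mismatch: {aj.shape} vs {pj.shape}")
    return aj - pj


def mae_percent(aj: np.ndarray, pj: np.ndarray,
                normalization: str = "range") -> float:
    """Mean absolute error as a percentage.

    ``range`` (default): mean |AJ-PJ| / (max(AJ) - min(AJ)) x 100, invariant
    to a common affine rescaling of both traces.  ``max``: normalize by
    max |AJ|.  ``none``: plain MAE in degrees (no percent scaling).
    """
    err = np.abs(absolute_error(aj, pj))
    if err.size == 0:
        raise ValueError("empty input")
    if normalization == "none":
        return float(err.mean())
    if normalization == "range":
        denom = float(np.max(aj) - np.min(aj))
        if denom <= 0:
            raise ValueError("constant actual angle: range normalization "
                             "is undefined")
    elif normalization == "max":
        denom = float(np.max(np.abs(aj)))
        if denom <= 0:
            raise ValueError("all-zero actual angle: max normalization "
                             "is undefined")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(err.mean() / denom * 100.0)


def _ovr_counts(y_true: np.ndarray, y_pred: np.ndarray, cls: int):
    tp = int(np.sum((y_true == cls) & (y_pred == cls)))
    fp = int(np.sum((y_true != cls) & (y_pred == cls)))
    fn = int(np.sum((y_true == cls) & (y_pred != cls)))
    tn = int(np.sum((y_true != cls) & (y_pred != cls)))
    return tp, fp, fn, tn


def classification_metrics(y_true, y_pred, positive_class: int | None = None,
                           n_classes: int = N_CLASSES):
    """One-vs-rest precision, recall, F1 and accuracy.

    With ``positive_class`` given, returns that class's
    ``(precision, recall, f1, accuracy)`` where accuracy is the one-vs-rest
    (TP+TN)/total x 100.  With ``positive_class=None``, returns the
    macro-averaged ``(precision, recall, f1, accuracy)`` where accuracy is
    the overall multiclass percent correct.  A class absent from ``y_true``
    has undefined recall: it is reported as NaN with a warning, and macro
    averages skip it.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")

    def one(cls: int):
        tp, fp, fn, tn = _ovr_counts(y_true, y_pred, cls)
        if tp + fn == 0:
            warnings.warn(f"class {cls} absent from y_true: recall undefined",
                          RuntimeWarning, stacklevel=3)
            return np.nan, np.nan, np.nan, np.nan
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        accuracy = (tp + tn) / (tp + fp + fn + tn) * 100.0
        return precision, recall, f1, accuracy

    if positive_class is not None:
        return one(int(positive_class))
    per_class = [one(c) for c in range(n_classes)]
    arr = np.asarray(per_class, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = np.nanmean(arr[:, :3], axis=0)
    overall_acc = float(np.mean(y_true == y_pred) * 100.0)
    return float(macro[0]), float(macro[1]), float(macro[2]), overall_acc


def per_class_metrics(y_true, y_pred, n_classes: int = N_CLASSES) -> dict:
    """Per-class precision/recall/F1/OVR-accuracy lists plus overall accuracy."""
    cols = {"precision": [], "recall": [], "f1": [], "ovr_accuracy": []}
    for c in range(n_classes):
        p, r, f, a = classification_metrics(y_true, y_pred, positive_class=c)
        cols["precision"].append(p)
        cols["recall"].append(r)
        cols["f1"].append(f)
        cols["ovr_accuracy"].append(a)
    cols["accuracy"] = float(
        np.mean(np.asarray(y_true) == np.asarray(y_pred)) * 100.0
    )
    return cols


def confusion_matrix_percent(y_true, y_pred,
                             n_classes: int = N_CLASSES) -> np.ndarray:
    """Row-normalized confusion matrix in percent (rows sum to 100).

    Row i, column j is the percentage of true-class-i segments predicted as
    class j.  A class with no true segments yields a NaN row and a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = np.zeros((n_classes, n_classes), dtype=float)
    np.add.at(counts, (y_true, y_pred), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        warnings.warn("empty true-class row in confusion matrix",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts / row_sums * 100.0


def pearson_corr(a, b) -> float:
    """Pearson correlation coefficient between two equal-length traces."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must share a shape")
    return float(stats.pearsonr(a, b).statistic)


@dataclasses.dataclass
class MetricsReport:
    """Fold-level or aggregated metrics.

    Scalar fields carry mean +/- sd across folds (sd is 0 for a single
    fold); ``confusion`` rows are percentages summing to 100; per-class
    lists are indexed by the movement-class code.
    """

    mae_percent: float
    accuracy: float
    pearson_r: float
    mae_percent_sd: float = 0.0
    accuracy_sd: float = 0.0
    pearson_r_sd: float = 0.0
    pearson_r_raw: float = float("nan")   # before EIA smoothing
    precision: list = dataclasses.field(default_factory=list)
    recall: list = dataclasses.field(default_factory=list)
    f1: list = dataclasses.field(default_factory=list)
    confusion: list = dataclasses.field(default_factory=list)
    n_folds: int = 1
    per_fold: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


def fold_report(y_true, y_pred, aj, pj, pj_raw=None,
                mae_normalization: str = "range") -> MetricsReport:
    """Build a single-fold report from labels and concatenated angle traces."""
    per_cls = per_class_metrics(y_true, y_pred)
    conf = confusion_matrix_percent(y_true, y_pred)
    return MetricsReport(
        mae_percent=mae_percent(aj, pj, mae_normalization),
        accuracy=per_cls["accuracy"],
        pearson_r=pearson_corr(aj, pj),
        pearson_r_raw=(pearson_corr(aj, pj_raw)
                       if pj_raw is not None else float("nan")),
        precision=per_cls["precision"],
        recall=per_cls["recall"],
        f1=per_cls["f1"],
        confusion=conf.tolist(),
    )


def aggregate_folds(reports: list[MetricsReport]) -> MetricsReport:
    """Mean +/- sample sd across folds for every scalar metric.

    Confusion matrices are averaged elementwise then re-normalized so each
    row sums to 100.  With a single fold the sd is 0 (with a warning).
    """
    if not reports:
        raise ValueError("no fold reports to aggregate")
    if len(reports) == 1:
        warnings.warn("aggregating a single fold: sd reported as 0",
                      RuntimeWarning, stacklevel=2)

    def mean_sd(values):
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd

    mae, mae_sd = mean_sd([r.mae_percent for r in reports])
    acc, acc_sd = mean_sd([r.accuracy for r in reports])
    r_mean, r_sd = mean_sd([r.pearson_r for r in reports])
    raw_vals = [r.pearson_r_raw for r in reports]
    raw_mean = (float(np.mean(raw_vals))
                if np.all(np.isfinite(raw_vals)) else float("nan"))
    conf = np.mean([np.asarray(r.confusion, dtype=float) for r in reports],
                   axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = conf / conf.sum(axis=1, keepdims=True) * 100.0
    agg_pc = {
        key: np.nanmean([np.asarray(getattr(r, key), dtype=float)
                         for r in reports], axis=0).tolist()
        for key in ("precision", "recall", "f1")
    }
    return MetricsReport(
        mae_percent=mae, mae_percent_sd=mae_sd,
        accuracy=acc, accuracy_sd=acc_sd,
        pearson_r=r_mean, pearson_r_sd=r_sd,
        pearson_r_raw=raw_mean,
        confusion=conf.tolist(),
        n_folds=len(reports),
        per_fold=[r.to_dict() for r in reports],
        **agg_pc,
    )
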