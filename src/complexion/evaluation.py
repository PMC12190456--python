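"""Classification metrics, model-comparison statistics and ROI analyses.

Per-class precision, recall and F1 come from the confusion matrix via

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R)

with macro averages taken as unweighted means over the classes for which
the metric is defined (0/0 cells are reported as undefined and excluded
from the macro rather than coerced to zero, which would penalise classes
absent from small fixtures).  Model comparisons use the paired t-test and
the paired Cohen's d with the conventional large-effect threshold d > 0.8.
ROI association is quantified by the Pearson correlation of raw prediction
codes, and ROI contribution by normalised gain importances of a fitted
gradient-boosting meta-learner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .labels import N_CLASSES


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        self.counts = c

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()


def confusion_matrix(true_codes, predicted_codes, k: int = N_CLASSES) -> ConfusionMatrix:
    """Tally true/predicted ordinal codes (values 1..k) into a K x K matrix."""
    t = np.asarray(true_codes, dtype=int)
    p = np.asarray(predicted_codes, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted sequences must have equal length")
    if t.size and not ((1 <= t.min()) and (t.max() <= k) and (1 <= p.min()) and (p.max() <= k)):
        raise ValueError(f"codes must lie in 1..{k}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1 plus overall accuracy.

    Undefined (0/0) per-class entries are NaN and excluded from macros.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = np.where(
            np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
            2 * precision * recall / (precision + recall),
            np.where(np.isnan(precision) | np.isnan(recall), np.nan, 0.0),
        )
    accuracy = float(tp.sum() / cm.total) if cm.total else float("nan")
    return MetricsReport(
        precision, recall, f1,
        float(np.nanmean(precision)) if not np.isnan(precision).all() else float("nan"),
        float(np.nanmean(recall)) if not np.isnan(recall).all() else float("nan"),
        float(np.nanmean(f1)) if not np.isnan(f1).all() else float("nan"),
        accuracy,
    )


@dataclass
class StatTestResult:
    t: float
    p: float
    d: float
    n: int

    @property
    def large_effect(self) -> bool:
        return abs(self.d) > 0.8


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on fold-paired accuracy sequences.

    t = mean(a-b) / (sd(a-b) / sqrt(n)), sd with n-1 denominator; p from the
    t distribution with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired sequences must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise ValueError("degenerate variance: all paired differences identical and nonzero")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def cohens_d(a, b, paired: bool = True) -> float:
    """Effect size; paired form is mean(a-b) / sd(a-b) (ddof=1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired sequences must have equal length")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            if diff.mean() == 0:
                return 0.0
            raise ValueError("degenerate variance: identical nonzero differences")
        return float(diff.mean() / sd)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("degenerate variance: pooled sd is zero")
    return float((a.mean() - b.mean()) / pooled)


def compare_methods(a, b) -> StatTestResult:
    """Paired t-test + Cohen's d between two fold-accuracy sequences."""
    t, p = paired_ttest(a, b)
    d = cohens_d(a, b, paired=True)
    return StatTestResult(t, p, d, len(a))


@dataclass
class CorrelationMatrix:
    """ROI x ROI Pearson coefficients; NaN marks undefined (constant) pairs."""

    rois: tuple
    values: np.ndarray

    def absolute(self) -> "CorrelationMatrix":
        """Magnitude view (mirrors heatmaps drawn on a 0..1 scale)."""
        return CorrelationMatrix(self.rois, np.abs(self.values))


def roi_correlation(table) -> CorrelationMatrix:
    """Pearson r between raw (unscaled) per-ROI prediction-code columns."""
    codes = np.asarray(table.codes, dtype=float)
    if codes.shape[0] < 2:
        raise ValueError("correlation needs at least 2 rows")
    n_roi = codes.shape[1]
    out = np.full((n_roi, n_roi), np.nan)
    sds = codes.std(axis=0)
    for i in range(n_roi):
        for j in range(n_roi):
            if i == j:
                out[i, j] = 1.0 if sds[i] > 0 else np.nan
            elif sds[i] > 0 and sds[j] > 0:
                out[i, j] = float(np.corrcoef(codes[:, i], codes[:, j])[0, 1])
    return CorrelationMatrix(tuple(table.rois), out)


def roi_importance(meta_model, table=None) -> np.ndarray:
    """Gain-based ROI importances of a boosting meta-model, normalised to 1.

    Reported in the table's ROI column order.
    """
    imp = meta_model.importances()
    if table is not None and imp.size != len(table.rois):
        raise ValueError("importance length does not match the table's ROI count")
    return imp
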