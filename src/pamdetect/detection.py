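"""Threshold detection and ROC evaluation.

A feature series becomes a binary detection by comparing each window's
value against a cutoff (strictly greater-than for the ``high_is_positive``
polarity, strictly less-than for ``low_is_positive``). Cutoffs come from
the feature's median, median + M * MAD (median absolute deviation), a fixed
value, or the ROC-optimal point — the threshold whose (FPR, TPR) lies
closest to the perfect-detector corner (0, 1).

Evaluation against ground truth uses the standard confusion counts,
TPR = TP/(TP+FN) and FPR = FP/(FP+TN), a threshold-sweep ROC over the
distinct observed feature values, trapezoidal AUC, and the accuracy /
precision / recall / F1 battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSeries

__all__ = [
    "LabelSeries",
    "ConfusionCounts",
    "ROCCurve",
    "MetricReport",
    "ThresholdConfig",
    "read_labels",
    "label_by_energy",
    "threshold_value",
    "detect",
    "confusion",
    "rates",
    "roc_curve",
    "auc",
    "roc_optimal_threshold",
    "metrics",
    "pct",
]


@dataclass(frozen=True)
class LabelSeries:
    """Binary per-window labels (1 = call present) with optional zone tags."""

    labels: np.ndarray
    zones: np.ndarray | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.size and not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    per_zone: dict[str, tuple[int, int]] | None = None  # zone -> (tp, fp)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep: descending cutoffs with their (FPR, TPR) points.

    Sentinels at both ends force the (0, 0) and (1, 1) endpoints; tied
    feature values share one point.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


@dataclass(frozen=True)
class MetricReport:
    """Accuracy/precision/recall/F1 as fractions in [0, 1] (see :func:`pct`
    for the 2-decimal percentage formatting used in reports)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None


@dataclass(frozen=True)
class ThresholdConfig:
    method: str = "median"  # median | median_plus_M_dev | roc_optimal | fixed
    M: float = 0.0
    polarity: str = "high_is_positive"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.method not in {"median", "median_plus_M_dev", "roc_optimal", "fixed"}:
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.polarity not in {"high_is_positive", "low_is_positive"}:
            raise ValueError(f"unknown polarity {self.polarity!r}")


def pct(x: float) -> float:
    """Fraction -> percentage rounded half-up to 2 decimals (table style)."""
    return float(Decimal(repr(x * 100.0)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def read_labels(path: str | Path) -> LabelSeries:
    """Read a ``segment,label[,zone]`` CSV written by the synthesis module."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    zones = None
    if "zone" in df.columns:
        zones = df["zone"].where(df["zone"].notna(), None).to_numpy(dtype=object)
    return LabelSeries(labels=df["label"].to_numpy(), zones=zones)


def label_by_energy(energy_series: np.ndarray, threshold: float) -> LabelSeries:
    """Energy-threshold ground-truth surrogate: label 1 where energy is
    strictly above ``threshold`` (the operator-labelling stand-in)."""
    e = np.asarray(energy_series, dtype=float)
    return LabelSeries(labels=(e > threshold).astype(int))


def _values(features: FeatureSeries | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureSeries):
        return features.values
    return np.asarray(features, dtype=float)


def threshold_value(
    features: FeatureSeries | np.ndarray,
    config: ThresholdConfig,
    labels: LabelSeries | None = None,
) -> float:
    """Compute the detection cutoff for ``features`` under ``config``."""
    v = _values(features)
    if v.size == 0:
        raise ValueError("empty feature series")
    if config.method == "median":
        return float(np.median(v))
    if config.method == "median_plus_M_dev":
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        return med + config.M * mad
    if config.method == "fixed":
        if config.value is None:
            raise ValueError("fixed method requires a value")
        return float(config.value)
    if labels is None:
        raise ValueError("roc_optimal threshold requires ground-truth labels")
    return roc_optimal_threshold(v, labels, polarity=config.polarity)


def detect(
    features: FeatureSeries | np.ndarray,
    cutoff: float,
    polarity: str = "high_is_positive",
) -> LabelSeries:
    """Binary decision per window: strictly above (or below) the cutoff."""
    v = _values(features)
    if polarity == "high_is_positive":
        pred = v > cutoff
    elif polarity == "low_is_positive":
        pred = v < cutoff
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return LabelSeries(labels=pred.astype(int))


def confusion(
    pred: LabelSeries,
    truth: LabelSeries,
    zones: np.ndarray | None = None,
) -> ConfusionCounts:
    """Confusion counts, with per-zone TP/FP when zone tags are given."""
    p, t = pred.labels, truth.labels
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} labels")
    if zones is None:
        zones = truth.zones
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    per_zone = None
    if zones is not None:
        per_zone = {}
        for z in dict.fromkeys(z for z in zones if z is not None):
            m = zones == z
            per_zone[str(z)] = (
                int(np.sum((p == 1) & (t == 1) & m)),
                int(np.sum((p == 1) & (t == 0) & m)),
            )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, per_zone=per_zone)


def rates(c: ConfusionCounts) -> tuple[float, float]:
    """(TPR, FPR); an empty class yields a rate of 0 rather than an error."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else 0.0
    return tpr, fpr


def _sweep(v: np.ndarray, t: np.ndarray, polarity: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cutoffs (distinct values bracketed by sentinels) and their rates."""
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    distinct = np.unique(v)
    if polarity == "high_is_positive":
        cuts = np.concatenate([[np.inf], distinct[::-1], [-np.inf]])
    else:
        cuts = np.concatenate([[-np.inf], distinct, [np.inf]])
    tpr = np.empty(cuts.size)
    fpr = np.empty(cuts.size)
    for k, c in enumerate(cuts):
        pred = v > c if polarity == "high_is_positive" else v < c
        tpr[k] = np.sum(pred & (t == 1)) / n_pos
        fpr[k] = np.sum(pred & (t == 0)) / n_neg
    return cuts, tpr, fpr


def roc_curve(
    features: FeatureSeries | np.ndarray,
    truth: LabelSeries,
    polarity: str = "high_is_positive",
) -> ROCCurve:
    """ROC sweep over every distinct observed feature value."""
    v = _values(features)
    t = truth.labels
    if v.size != t.size:
        raise ValueError("features and labels differ in length")
    if t.sum() == 0 or t.sum() == t.size:
        raise ValueError("ROC requires at least one positive and one negative")
    cuts, tpr, fpr = _sweep(v, t, polarity)
    return ROCCurve(thresholds=cuts, tpr=tpr, fpr=fpr)


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def roc_optimal_threshold(
    features: FeatureSeries | np.ndarray,
    truth: LabelSeries,
    polarity: str = "high_is_positive",
) -> float:
    """Cutoff whose (FPR, TPR) point is closest to (0, 1).

    Ties break toward higher TPR, then lower FPR. Candidates are the
    observed feature values plus one cutoff beyond the extreme value (the
    all-positive decision); together these realise every achievable
    partition, so the result matches an exhaustive midpoint search.
    """
    v = _values(features)
    t = truth.labels
    cuts, tpr, fpr = _sweep(v, t, polarity)
    # replace the infinite sentinels with finite cutoffs realising the
    # same partitions (+inf duplicates the extreme-value cutoff's point)
    if polarity == "high_is_positive":
        cuts = np.concatenate([[v.max() + 1.0], cuts[1:-1], [v.min() - 1.0]])
    else:
        cuts = np.concatenate([[v.min() - 1.0], cuts[1:-1], [v.max() + 1.0]])
    d2 = fpr**2 + (1.0 - tpr) ** 2
    # lexicographic: distance, then -tpr, then fpr
    order = np.lexsort((fpr, -tpr, d2))
    return float(cuts[order[0]])


def metrics(c: ConfusionCounts, roc_auc: float | None = None) -> MetricReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Undefined ratios (zero denominators) are reported as 0.
    """
    total = c.total
    accuracy = (c.tp + c.tn) / total if total else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1, auc=roc_auc)
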