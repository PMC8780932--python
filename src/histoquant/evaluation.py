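"""Segmentation agreement against hand-traced reference masks.

All metrics are functions of the four confusion-matrix cells, counted over
pixels:

* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
* Youden's J = sensitivity + specificity - 1  (informedness)
* F-score = 2 TP / (2 TP + FP + FN)  (harmonic mean of precision and recall)
* MCC = (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Counts are accumulated as exact integers; only the final division is floating
point. Undefined metrics (zero denominators) are returned as NaN with a flag,
except MCC, which by the documented convention is 0 whenever a denominator
factor vanishes (a constant prediction carries no information, so the
chance-level value is the honest report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CONSENSUS_RULES = ("intersection", "majority")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_matrix(
    predicted: np.ndarray,
    reference: np.ndarray,
    evaluate_region: np.ndarray | None = None,
) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted mask against a reference."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape:
        raise ConfigurationError(
            f"shape mismatch: predicted {pred.shape} vs reference {ref.shape}"
        )
    if evaluate_region is not None:
        region = np.asarray(evaluate_region, dtype=bool)
        if region.shape != pred.shape:
            raise ConfigurationError("evaluate_region shape mismatch")
        pred = pred[region]
        ref = ref[region]
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else math.nan


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else math.nan


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else math.nan


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total > 0 else math.nan


def youden_j(c: ConfusionCounts) -> float:
    """sensitivity + specificity - 1; NaN if either term is undefined."""
    se, sp = sensitivity(c), specificity(c)
    if math.isnan(se) or math.isnan(sp):
        return math.nan
    return se + sp - 1.0


def f_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom > 0 else math.nan


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is zero.

    Computed with exact integer arithmetic in numerator and radicand, so it is
    overflow-safe for arbitrarily large pixel counts.
    """
    tp, fp, tn, fn = int(c.tp), int(c.fp), int(c.tn), int(c.fn)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def mcc_degenerate(c: ConfusionCounts) -> bool:
    return (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn) == 0


@dataclass(frozen=True)
class MetricSet:
    """All metrics for one confusion matrix, with per-metric defined flags."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    youden_j: float
    f_score: float
    mcc: float
    flags: tuple[str, ...]  # names of undefined/degenerate metrics

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricSet":
        values = {
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "precision": precision(c),
            "accuracy": accuracy(c),
            "youden_j": youden_j(c),
            "f_score": f_score(c),
            "mcc": mcc(c),
        }
        flags = tuple(k for k, v in values.items() if isinstance(v, float) and math.isnan(v))
        if mcc_degenerate(c):
            flags = flags + ("mcc",)
        return cls(counts=c, flags=flags, **values)


# ---------------------------------------------------------------------------
# consensus and batch evaluation
# ---------------------------------------------------------------------------

def consensus_standard(
    masks: Sequence[np.ndarray], rule: str = "intersection"
) -> np.ndarray:
    """Combine several annotators' masks into one reference.

    ``intersection`` (default): a pixel is positive iff every annotator marked
    it. ``majority`` is offered for larger panels: positive iff more than half
    of the annotators marked it.
    """
    if rule not in CONSENSUS_RULES:
        raise ConfigurationError(f"unknown consensus rule {rule!r}")
    if len(masks) < 2:
        raise ConfigurationError("consensus needs at least 2 masks")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ConfigurationError("consensus masks must share one shape")
    if rule == "intersection":
        out = arrs[0].copy()
        for a in arrs[1:]:
            out &= a
        return out
    votes = np.sum(arrs, axis=0)
    return votes * 2 > len(arrs)


def evaluate_method(
    predicted: Mapping[str, np.ndarray],
    reference: Mapping[str, np.ndarray],
    evaluate_region: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, MetricSet]:
    """Score a method over paired predicted/reference masks.

    Returns a per-image metrics table plus the pooled (micro-averaged)
    MetricSet over entrywise-summed counts — which is *not* the mean of the
    per-image metrics.
    """
    missing_ref = sorted(set(predicted) - set(reference))
    missing_pred = sorted(set(reference) - set(predicted))
    if missing_ref or missing_pred:
        raise ConfigurationError(
            f"unmatched image ids — no reference for: {missing_ref}; "
            f"no prediction for: {missing_pred}"
        )
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for image_id in sorted(predicted):
        region = evaluate_region.get(image_id) if evaluate_region else None
        c = confusion_matrix(predicted[image_id], reference[image_id], region)
        pooled = pooled + c
        rows.append(_metric_row(image_id, MetricSet.from_counts(c)))
    pooled_metrics = MetricSet.from_counts(pooled)
    rows.append(_metric_row("pooled", pooled_metrics))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS), pooled_metrics


METRIC_COLUMNS = [
    "image_id",
    "TP",
    "FP",
    "TN",
    "FN",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "youden_j",
    "f_score",
    "mcc",
    "flags",
]


def _metric_row(image_id: str, m: MetricSet) -> dict:
    return {
        "image_id": image_id,
        "TP": m.counts.tp,
        "FP": m.counts.fp,
        "TN": m.counts.tn,
        "FN": m.counts.fn,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "precision": m.precision,
        "accuracy": m.accuracy,
        "youden_j": m.youden_j,
        "f_score": m.f_score,
        "mcc": m.mcc,
        "flags": ";".join(m.flags),
    }
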