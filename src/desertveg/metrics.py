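"""Pixelwise segmentation metrics against ground-truth masks.

All metrics derive from the 2x2 confusion table with green vegetation as
the positive class:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* F1        = 2 * precision * recall / (precision + recall)
* IoU       = TP / (TP + FP + FN)   (Jaccard)

F1 and IoU are tied by the identity ``F1 = 2 IoU / (1 + IoU)``. A ratio
with a zero denominator (or TP = 0 with errors present, which forces the
last four metrics to 0) is reported as 0 and flagged as undefined rather
than raising.

For multi-image test sets both aggregations are reported: *pooled* (micro —
counts summed over images, then one metric set) and the per-image *mean*
(macro). The two differ whenever vegetation prevalence varies across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "metrics",
    "evaluate_masks",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float
    undefined: tuple[str, ...] = ()  # metrics whose ratio had denominator 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN of two same-shaped binary masks (True = green)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size == 0:
        raise InputError("empty masks")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five metrics of a confusion table; zero denominators flagged."""
    if c.total == 0:
        raise InputError("confusion counts are all zero")
    undefined: list[str] = []
    accuracy = (c.tp + c.tn) / c.total
    precision = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", undefined)
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, "iou", undefined)
    return MetricsReport(accuracy, precision, recall, f1, iou, tuple(undefined))


def evaluate_masks(
    preds: dict[str, np.ndarray], truths: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-image metrics plus pooled (micro) and mean (macro) summary rows.

    ``preds`` and ``truths`` map image identifiers to binary masks and must
    cover the same identifiers. The returned frame is indexed by image id
    with the extra rows ``"pooled"`` and ``"mean"``.
    """
    missing = sorted(set(preds) ^ set(truths))
    if missing:
        raise InputError(f"prediction/truth sets differ on: {missing}")
    if not preds:
        raise InputError("no mask pairs to evaluate")

    rows = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for name in sorted(preds):
        c = confusion_counts(preds[name], truths[name])
        pooled = pooled + c
        rows[name] = metrics(c).as_dict()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean(axis=0)
    table.loc["pooled"] = metrics(pooled).as_dict()
    table.index.name = "image"
    return table
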