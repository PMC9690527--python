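"""Confusion-matrix metrics for binary segmentation.

Tumor is the positive class. Besides accuracy, precision, F1, IoU and
Dice, two recall variants are reported: ``recall_standard`` is the usual
sensitivity TP/(TP+FN); ``recall_paper`` is the negative-class ratio
TN/(TN+FN) used by some published metric panels, kept so results remain
comparable with that convention (F1 here follows the same panel and is
computed from precision and ``recall_paper``).

Degenerate 0/0 ratios: a comparison of two empty masks scores 1 (perfect
agreement); one-sided emptiness scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .preprocess import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall_paper: float
    recall_standard: float
    f1: float
    iou: float
    dsc: float
    sett_seconds: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion tally with tumor = positive."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.pixels.astype(bool)
    q = truth.pixels.astype(bool)
    return ConfusionCounts(tp=int(np.sum(p & q)), tn=int(np.sum(~p & ~q)),
                           fp=int(np.sum(p & ~q)), fn=int(np.sum(~p & q)))


def _ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def metrics(counts: ConfusionCounts,
            sett_seconds: float | None = None) -> MetricsReport:
    """Compute the full metric panel from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    both_empty = (tp + fp == 0) and (tp + fn == 0)
    accuracy = _ratio(tp + tn, counts.total, both_empty)
    precision = _ratio(tp, tp + fp, both_empty)
    recall_paper = _ratio(tn, tn + fn, tn + fn == 0)
    recall_standard = _ratio(tp, tp + fn, both_empty)
    f1 = _ratio(2 * precision * recall_paper, precision + recall_paper,
                both_empty)
    union = tp + fp + fn
    iou = _ratio(tp, union, both_empty)
    dsc = _ratio(2 * tp, 2 * tp + fp + fn, both_empty)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall_paper=recall_paper,
                         recall_standard=recall_standard, f1=f1,
                         iou=iou, dsc=dsc, sett_seconds=sett_seconds)


def evaluate_pair(pred: BinaryMask, truth: BinaryMask) -> MetricsReport:
    return metrics(confusion(pred, truth))


def sett(epoch_times) -> float:
    """Single-epoch training time: the mean of per-epoch wall times (s)."""
    times = np.asarray(list(epoch_times), dtype=float)
    if times.size == 0:
        raise ValueError("need at least one epoch timing")
    return float(times.mean())


def evaluate_dataset(pairs) -> pd.DataFrame:
    """Per-slice metric table plus an unweighted mean row.

    ``pairs`` is an iterable of (name, predicted BinaryMask, truth
    BinaryMask). The last row (name ``"mean"``) averages each metric over
    slices.
    """
    rows = []
    for name, pred, truth in pairs:
        rows.append(dict(slice=name, **evaluate_pair(pred, truth).as_dict()))
    if not rows:
        raise ValueError("no slices to evaluate")
    table = pd.DataFrame(rows).drop(columns=["sett_seconds"])
    mean_row = table.drop(columns=["slice"]).mean()
    table = pd.concat(
        [table, pd.DataFrame([dict(slice="mean", **mean_row.to_dict())])],
        ignore_index=True)
    return table
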