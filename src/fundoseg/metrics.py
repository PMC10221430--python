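"""Segmentation overlap metrics: pixel confusion counts, Dice, Jaccard.

Dice (F1) = 2TP / (2TP + FP + FN), Jaccard (IoU) = TP / (TP + FP + FN),
with TP/FP/FN counted over pixels between a predicted and a ground-truth
binary mask.  The two are linked by DC = 2J / (1 + J).  Dataset-level
reporting defaults to per-image averaging; a pooled-pixel variant is
available via ``pooled=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel tallies between two equal-shape binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _empty_both(counts: ConfusionCounts) -> bool:
    return counts.tp == 0 and counts.fp == 0 and counts.fn == 0


def dice(counts: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); both-empty masks score 1.0 with a warning."""
    if _empty_both(counts):
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * counts.tp / (2.0 * counts.tp + counts.fp + counts.fn)


def jaccard(counts: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); both-empty masks score 1.0 with a warning."""
    if _empty_both(counts):
        warnings.warn("both masks empty: Jaccard defined as 1.0", stacklevel=2)
        return 1.0
    return counts.tp / float(counts.tp + counts.fp + counts.fn)


@dataclass
class MetricsReport:
    structure: str
    per_image: pd.DataFrame  # columns image_id, dice, jaccard
    mean_dice: float
    mean_jaccard: float

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def to_csv(self, path) -> None:
        table = self.per_image.copy()
        table.insert(1, "structure", self.structure)
        summary = pd.DataFrame(
            [{"image_id": "MEAN", "structure": self.structure,
              "dice": self.mean_dice, "jaccard": self.mean_jaccard}]
        )
        pd.concat([table, summary], ignore_index=True).to_csv(
            path, index=False, float_format="%.6f"
        )


def evaluate(pairs, structure: str = "", image_ids=None, pooled: bool = False) -> MetricsReport:
    """Score a list of (predicted mask, truth mask) pairs.

    Per-image Dice/Jaccard with their arithmetic means; with
    ``pooled=True`` the means are replaced by scores of the summed
    confusion counts over all pixels.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot evaluate an empty list of mask pairs")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(pairs))]
    rows = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for image_id, (pred, truth) in zip(image_ids, pairs):
        counts = confusion_counts(pred, truth)
        pooled_counts = pooled_counts + counts
        rows.append({"image_id": image_id, "dice": dice(counts), "jaccard": jaccard(counts)})
    table = pd.DataFrame.from_records(rows)
    if pooled:
        mean_dc, mean_j = dice(pooled_counts), jaccard(pooled_counts)
    else:
        mean_dc, mean_j = float(table["dice"].mean()), float(table["jaccard"].mean())
    return MetricsReport(structure=structure, per_image=table,
                         mean_dice=mean_dc, mean_jaccard=mean_j)
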