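"""Heatmap-annotation overlap: Dice and IoU scores.

Quantifies how well a model-attention heatmap (e.g. a class-activation map)
agrees with a lesion annotation.  Heatmap generation is out of scope — the
functions consume heatmaps as arrays, binarise them at a fraction of their
maximum, and score the overlap against the annotation mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .image import BinaryMask

__all__ = ["Heatmap", "OverlapScore", "threshold_heatmap", "overlap", "overlap_summary"]


@dataclass(frozen=True, eq=False)
class Heatmap:
    """Non-negative H x W attention values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected H x W array, got shape {arr.shape}")
        if arr.min() < 0:
            raise ValueError("heatmap values must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def max_value(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class OverlapScore:
    """Dice and IoU in [0, 1]; ``both_empty`` flags the degenerate convention.

    The two scores are algebraically linked: ``dice = 2 * iou / (1 + iou)``.
    """

    dice: float
    iou: float
    both_empty: bool = False


def threshold_heatmap(h: Heatmap, frac_of_max: float = 0.5) -> BinaryMask:
    """Pixel true iff its value >= ``frac_of_max`` times the heatmap maximum."""
    if not 0.0 < frac_of_max <= 1.0:
        raise ValueError("frac_of_max must lie in (0, 1]")
    if h.max_value <= 0.0:
        raise ValueError("cannot threshold an all-zero heatmap")
    return BinaryMask(h.values >= frac_of_max * h.max_value)


def overlap(a: BinaryMask, b: BinaryMask) -> OverlapScore:
    """Dice = 2|A∩B| / (|A|+|B|); IoU = |A∩B| / |A∪B|.

    Two empty masks score 1 by convention, flagged via ``both_empty`` so the
    case cannot silently inflate batch summaries.
    """
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    inter = int((a.values & b.values).sum())
    union = int((a.values | b.values).sum())
    total = a.area + b.area
    if union == 0:
        return OverlapScore(1.0, 1.0, both_empty=True)
    return OverlapScore(2.0 * inter / total, inter / union)


def overlap_summary(
    pairs: Iterable[tuple[BinaryMask, BinaryMask]],
) -> dict[str, float]:
    """Mean and standard deviation of Dice/IoU over mask pairs."""
    dices, ious = [], []
    n_both_empty = 0
    for a, b in pairs:
        s = overlap(a, b)
        n_both_empty += int(s.both_empty)
        dices.append(s.dice)
        ious.append(s.iou)
    dices_arr, ious_arr = np.asarray(dices), np.asarray(ious)
    return {
        "n": len(dices),
        "n_both_empty": n_both_empty,
        "dice_mean": float(dices_arr.mean()),
        "dice_sd": float(dices_arr.std(ddof=1)) if len(dices) > 1 else 0.0,
        "iou_mean": float(ious_arr.mean()),
        "iou_sd": float(ious_arr.std(ddof=1)) if len(ious) > 1 else 0.0,
    }
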