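"""Segmentation and thickness evaluation: Dice, sensitivity, specificity,
mean absolute error, and Pearson correlation.

All pixel-wise metrics treat the second mask (the manual segmentation or
phantom ground truth) as the reference. Dice is 2·TP / (2·TP + FP + FN); by
convention it is 1.0 when both masks are empty, and the flag recording that
convention travels with the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, UndefinedCorrelationError
from .images import RNFLMask


@dataclass(frozen=True)
class SegmentationMetrics:
    dice: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    empty_convention_used: bool = False

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "empty_convention_used": self.empty_convention_used,
        }


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, RNFLMask):
        return mask.pixels
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ContractError("masks must be binary")
    return arr.astype(bool)


def segmentation_metrics(pred, truth) -> SegmentationMetrics:
    """Pixel-wise confusion counts and overlap metrics of pred against truth.

    Sensitivity (true-positive rate) and specificity (true-negative rate)
    use the truth mask as reference; an empty truth yields sensitivity NaN
    unless the prediction is also empty.
    """
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ContractError(f"mask dimensions differ: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    denom = 2 * tp + fp + fn
    if denom == 0:
        dice, empty = 1.0, True
    else:
        dice, empty = 2.0 * tp / denom, False
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else (1.0 if empty else float("nan"))
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return SegmentationMetrics(
        dice=dice,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        empty_convention_used=empty,
    )


def mae(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Mean absolute error between paired estimates and ground truths."""
    e = np.asarray(estimates, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if e.shape != t.shape or e.ndim != 1 or e.size == 0:
        raise ContractError("estimates and truths must be equal-length non-empty 1-D sequences")
    return float(np.mean(np.abs(e - t)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ContractError("x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ContractError("Pearson correlation requires at least 3 points")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(xa, ya).statistic)
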