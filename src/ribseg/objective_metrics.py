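"""Compound segmentation loss and detection metrics.

The training objective mixes pixelwise binary cross-entropy with the
logarithm of a smoothed soft Dice coefficient:

    L = (1 - theta) * L_CE - theta * log(Dice)

All loss functions accept either plain ndarrays or autograd tensors
(``ribseg.nn.Tensor``), so the exact same formulas drive training and
stand in tests against hand-computed values.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .nn import Tensor

EPS = 1e-7  # probability clamp before logarithms


@dataclasses.dataclass
class LossConfig:
    """theta mixes cross-entropy (0) and log-Dice (1); smooth stabilises the
    Dice ratio on empty masks."""

    theta: float = 0.2
    smooth: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0,1], got {self.theta}")
        if self.smooth <= 0:
            raise ValueError(f"smooth must be positive, got {self.smooth}")


def _as_compatible(pred, truth):
    truth = truth.data if isinstance(truth, Tensor) else np.asarray(truth)
    shape = pred.shape if isinstance(pred, Tensor) else np.asarray(pred).shape
    if tuple(shape) != truth.shape:
        raise ValueError(f"shape mismatch: pred {tuple(shape)} vs truth "
                         f"{truth.shape}")
    return truth.astype(np.float32)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _clamp(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def _mean(x):
    return x.mean() if isinstance(x, Tensor) else np.mean(x)


def _sum(x):
    return x.sum() if isinstance(x, Tensor) else np.sum(x)


def cross_entropy_loss(pred, truth):
    """Mean pixelwise binary cross-entropy.

    Probabilities are clamped to [EPS, 1-EPS] so exactly confident
    predictions stay finite.
    """
    truth = _as_compatible(pred, truth)
    p = _clamp(pred, EPS, 1.0 - EPS)
    return -_mean(truth * _log(p) + (1.0 - truth) * _log(1.0 - p))


def dice_coeff(pred, truth, smooth: float = 1.0):
    """Smoothed (soft) Dice: (2*sum(y*p) + smooth) / (sum(y) + sum(p) + smooth).

    With binary `pred` this is the hard Dice overlap; with probabilities it
    is the differentiable soft variant used inside the loss.
    """
    truth = _as_compatible(pred, truth)
    intersection = _sum(pred * truth)
    return (2.0 * intersection + smooth) / (_sum(pred) + _sum(truth) + smooth)


def compound_loss(pred, truth, config: LossConfig = LossConfig()):
    """(1 - theta) * cross-entropy - theta * log(smoothed Dice)."""
    theta = config.theta
    if theta == 0.0:
        return cross_entropy_loss(pred, truth)
    log_dice = _log(dice_coeff(pred, truth, config.smooth))
    if theta == 1.0:
        return -log_dice
    return (1.0 - theta) * cross_entropy_loss(pred, truth) - theta * log_dice


@dataclasses.dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    dice: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    def to_csv_row(self) -> str:
        return (f"{self.tp},{self.fp},{self.fn},{self.precision:.6f},"
                f"{self.recall:.6f},{self.f1:.6f},{self.dice:.6f}")

    CSV_HEADER = "tp,fp,fn,precision,recall,f1,dice"


def detection_metrics(tp: int, fp: int, fn: int,
                      dice: float = float("nan")) -> MetricsReport:
    """Precision/recall/F1 from lesion-level counts.

    Zero-denominator convention: a ratio whose denominator is zero is 0
    (reachable only with tp == 0).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2.0 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricsReport(tp=int(tp), fp=int(fp), fn=int(fn),
                         precision=precision, recall=recall, f1=f1, dice=dice)


def aggregate_pixel_dice(preds, truths, smooth: float = 0.0) -> float:
    """Pixel Dice over a whole dataset: sums pooled across images before the
    ratio (not a per-image mean).  `smooth=0` gives the raw overlap ratio;
    the 0/0 case (no foreground anywhere) returns 1.0."""
    inter = 0.0
    total = 0.0
    for p, t in zip(preds, truths):
        p = np.asarray(p, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        if p.shape != t.shape:
            raise ValueError("pred/truth shape mismatch")
        inter += float((p * t).sum())
        total += float(p.sum() + t.sum())
    if total + smooth == 0:
        return 1.0
    return (2.0 * inter + smooth) / (total + smooth)
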