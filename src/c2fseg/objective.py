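"""Compound binary cross-entropy + soft Dice loss and its analytic gradient.

The training objective for both stages is

    L = w1 * L_BCE + w2 * L_Dice

with L_BCE the voxel-mean binary cross-entropy and L_Dice the soft Dice loss
1 - (2*sum(y*p) + s) / (sum(y) + sum(p) + s).  The BCE term penalizes false
positives and false negatives voxelwise; the Dice term handles the extreme
foreground/background imbalance of mandible volumes.  Both weights default
to 0.5.

``loss_gradient`` is the closed-form dL/dp used to seed backpropagation; it
is also verified in the test suite against symbolic differentiation and
central finite differences.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["LossWeights", "bce_loss", "dice_loss", "combined_loss", "loss_gradient"]

DEFAULT_EPS = 1e-7      # probability clip inside BCE, keeps the loss finite
DEFAULT_SMOOTH = 1e-6   # Dice smoothing; makes empty/empty a perfect score


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the compound loss: ``omega1`` (BCE), ``omega2`` (Dice)."""

    omega1: float = 0.5
    omega2: float = 0.5
    smooth: float = DEFAULT_SMOOTH

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0 or self.omega1 + self.omega2 <= 0:
            raise ValueError("weights must be >= 0 with a positive sum")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")


def _check(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """Mean binary cross-entropy; ``pred`` is clipped to [eps, 1-eps]."""
    pred, target = _check(pred, target)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log1p(-p)))


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = DEFAULT_SMOOTH) -> float:
    """Soft Dice loss ``1 - (2*sum(y*p) + s) / (sum(y) + sum(p) + s)``."""
    pred, target = _check(pred, target)
    inter = float(np.sum(target * pred))
    denom = float(np.sum(target) + np.sum(pred)) + smooth
    if denom == 0.0:
        return 0.0
    return 1.0 - (2.0 * inter + smooth) / denom


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  weights: LossWeights = LossWeights()) -> float:
    """``omega1 * BCE + omega2 * Dice``."""
    return (weights.omega1 * bce_loss(pred, target)
            + weights.omega2 * dice_loss(pred, target, weights.smooth))


def loss_gradient(pred: np.ndarray, target: np.ndarray,
                  weights: LossWeights = LossWeights()) -> np.ndarray:
    """Closed-form per-voxel gradient dL/dp of :func:`combined_loss`.

    For voxel j with N voxels total, intersection I = sum(y*p), smoothing s
    and D = sum(y) + sum(p) + s:

        dL/dp_j = -(w1/N) * (y_j/p_j - (1-y_j)/(1-p_j))
                  - w2 * (2*y_j*D - (2*I + s)) / D**2

    Requires ``pred`` strictly inside (0, 1).
    """
    pred, target = _check(pred, target)
    if pred.min() <= 0.0 or pred.max() >= 1.0:
        raise ValueError("loss_gradient requires pred strictly inside (0, 1)")
    n = pred.size
    g_bce = -(target / pred - (1.0 - target) / (1.0 - pred)) / n
    inter = np.sum(target * pred)
    d = np.sum(target) + np.sum(pred) + weights.smooth
    g_dice = -(2.0 * target * d - (2.0 * inter + weights.smooth)) / (d * d)
    return weights.omega1 * g_bce + weights.omega2 * g_dice
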