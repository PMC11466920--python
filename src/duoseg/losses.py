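"""Compound segmentation loss: L = 0.5 * L_BCE + L_Dice.

Binary cross entropy is averaged over pixels; the Dice term is the soft Dice
loss ``1 - (2*sum(p*g) + 1) / (sum(p) + sum(g) + 1)`` with a smoothing
constant of 1 in numerator and denominator so empty masks stay well-defined.
The 0.5 weight applies to the cross-entropy term only.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError
from .nn import Tensor

__all__ = ["bce_loss", "dice_loss", "combined_loss"]

_EPS = 1e-7


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_shapes(prob: Tensor, gt: Tensor) -> None:
    if prob.shape != gt.shape:
        raise ShapeError(f"prediction shape {prob.shape} != target shape {gt.shape}")


def bce_loss(prob: Tensor, gt) -> Tensor:
    """Mean binary cross entropy; probabilities are clamped away from {0,1}."""
    gt = _as_tensor(gt)
    _check_shapes(prob, gt)
    p = prob.clip(_EPS, 1.0 - _EPS)
    ll = gt * p.log() + (1.0 - gt) * (1.0 - p).log()
    return -ll.mean()


def dice_loss(prob: Tensor, gt, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss over the whole batch."""
    gt = _as_tensor(gt)
    _check_shapes(prob, gt)
    inter = (prob * gt).sum()
    total = prob.sum() + gt.sum()
    return 1.0 - (2.0 * inter + smooth) / (total + smooth)


def combined_loss(prob: Tensor, gt) -> Tensor:
    """0.5 * BCE + Dice — the training objective."""
    return 0.5 * bce_loss(prob, gt) + dice_loss(prob, gt)
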