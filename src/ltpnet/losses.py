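"""Hybrid BCE + Dice training objective.

``loss = lambda1 * L_bce + lambda2 * L_dice`` with both weights 1 by
default.  BCE is the mean pixelwise binary cross-entropy on epsilon-
clamped probabilities; the Dice term is
``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError
from .nn import Tensor, as_tensor, ops

__all__ = ["LossWeights", "bce_loss", "dice_loss", "hybrid_loss", "EPS"]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("loss weights must be finite")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


def _check(probs, gt):
    probs, gt = as_tensor(probs), as_tensor(gt)
    if probs.shape != gt.shape:
        raise ShapeError(f"prediction {probs.shape} vs target {gt.shape}")
    return probs, gt


def bce_loss(probs, gt, eps: float = EPS) -> Tensor:
    probs, gt = _check(probs, gt)
    p = ops.clip(probs, eps, 1.0 - eps)
    ll = ops.add(ops.mul(gt, ops.log(p)), ops.mul(1.0 - gt, ops.log(1.0 - p)))
    return -ops.mean(ll)


def dice_loss(probs, gt, eps: float = EPS) -> Tensor:
    probs, gt = _check(probs, gt)
    inter = ops.sum(ops.mul(probs, gt))
    denom = ops.add(ops.sum(probs), ops.sum(gt))
    return 1.0 - ops.div(2.0 * inter + eps, ops.add(denom, eps))


def hybrid_loss(probs, gt, weights: LossWeights | None = None) -> Tensor:
    """Weighted sum of the BCE and Dice terms (weights default to 1 and 1)."""
    weights = weights or LossWeights()
    return ops.add(
        ops.mul(bce_loss(probs, gt), weights.lambda1),
        ops.mul(dice_loss(probs, gt), weights.lambda2),
    )
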