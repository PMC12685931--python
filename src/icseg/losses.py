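"""Training loss: squared-denominator DICE plus weighted binary cross-entropy."""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = ["LossConfig", "dice_loss_sq", "bce_loss", "combined_loss"]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    dice_weight: float = 1.0
    bce_weight: float = 0.25
    dice_variant: str = "squared_denominator"

    def __post_init__(self):
        if self.dice_weight < 0 or self.bce_weight < 0:
            raise ValueError("loss weights must be nonnegative")


def dice_loss_sq(pred, target):
    """1 - 2 sum(p t) / (sum p^2 + sum t^2), the squared-denominator DICE.

    Zero for a perfect binary match; the epsilon guard maps the empty-vs-empty
    case to 0 and total misses to 1.
    """
    if np.size(target) == 0:
        raise ValueError("empty rasters have no DICE loss")
    inter = anp.sum(pred * target)
    denom = anp.sum(pred ** 2) + anp.sum(target ** 2)
    return 1.0 - (2.0 * inter + _EPS) / (denom + _EPS)


def bce_loss(pred, target):
    """Mean binary cross-entropy over pixels, with probability clipping."""
    p = anp.clip(pred, _EPS, 1.0 - _EPS)
    return -anp.mean(target * anp.log(p) + (1.0 - target) * anp.log(1.0 - p))


def combined_loss(pred, target, cfg: LossConfig = LossConfig()):
    return cfg.dice_weight * dice_loss_sq(pred, target) + cfg.bce_weight * bce_loss(pred, target)
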