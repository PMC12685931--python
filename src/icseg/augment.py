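"""Episode-level data augmentation.

Each augmentation fires independently with probability ``p_a`` per episode.
Geometric transforms (flips, rotation) are applied with identical parameters
to every image *and* mask of the episode so that query/support semantics stay
aligned; photometric transforms (contrast, intensity flip, blur, noise)
touch images only.  The mask-edge augmentation swaps every target in the
episode for its 1-px inner boundary band (mask minus its erosion), turning a
region task into a contour task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import Episode

__all__ = ["AugmentConfig", "augment", "mask_edge"]

ALL_AUGMENTATIONS = (
    "hflip", "vflip", "rotation", "contrast", "intensity_flip",
    "blur", "noise", "mask_edge",
)


@dataclass(frozen=True)
class AugmentConfig:
    probabilities: dict = field(
        default_factory=lambda: {name: 0.25 for name in ALL_AUGMENTATIONS})
    max_rotation_deg: float = 30.0
    noise_sigma_range: tuple = (0.0, 0.05)
    blur_sigma_range: tuple = (0.5, 1.5)
    contrast_gamma_range: tuple = (0.7, 1.4)


def mask_edge(mask: np.ndarray) -> np.ndarray:
    """1-px inner boundary band: mask & ~erosion(mask), 3x3 structuring
    element.  A filled n x n square maps to its 4n - 4 perimeter pixels."""
    m = mask > 0.5
    er = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return (m & ~er).astype(float)


def _geom(img, flip_h, flip_v, angle, order):
    out = img
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=order,
                             mode="constant", cval=float(np.min(out)))
    return np.ascontiguousarray(out)


def augment(episode: Episode, cfg: AugmentConfig, rng) -> Episode:
    """Return an augmented copy of the episode (the input is untouched)."""
    p = cfg.probabilities
    fire = {name: rng.random() < p.get(name, 0.0) for name in ALL_AUGMENTATIONS}
    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg) if fire["rotation"] else 0.0
    gamma = rng.uniform(*cfg.contrast_gamma_range)
    blur_sigma = rng.uniform(*cfg.blur_sigma_range)
    noise_sigma = rng.uniform(*cfg.noise_sigma_range)

    def do_image(img):
        out = _geom(img, fire["hflip"], fire["vflip"], angle, order=1)
        if fire["contrast"]:
            out = np.clip(out, 0.0, 1.0) ** gamma
        if fire["intensity_flip"]:
            out = 1.0 - out
        if fire["blur"]:
            out = ndimage.gaussian_filter(out, blur_sigma)
        if fire["noise"]:
            out = out + rng.normal(0.0, noise_sigma, out.shape)
        return np.clip(out, 0.0, 1.0)

    def do_mask(msk):
        out = _geom(msk, fire["hflip"], fire["vflip"], angle, order=0)
        out = (out > 0.5).astype(float)
        if fire["mask_edge"]:
            out = mask_edge(out)
        return out

    return Episode(
        query_image=do_image(episode.query_image),
        support_images=np.stack([do_image(im) for im in episode.support_images]),
        support_masks=np.stack([do_mask(mk) for mk in episode.support_masks]),
        query_mask=None if episode.query_mask is None else do_mask(episode.query_mask),
        task_id=episode.task_id,
    )
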