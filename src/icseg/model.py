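"""Full in-context segmenter: three encoders + attention core + decoder.

An :class:`Episode` — one query image plus S support (image, mask) pairs —
is the unit of both training and inference.  The forward pass:

1. the Segmentation Encoder embeds the query (skips at strides 2..32);
2. the Support Set Encoder embeds image+mask pairs (cross skips at 32/16/8);
3. the Attention Mapper Encoder embeds the query, its EMA twin embeds the
   support *images only*, both at strides 8/16/32;
4. the Cross Attention Mapper computes the coarse (stride-32) attention map
   with registry tokens;
5. the decoder fuses everything into a per-pixel sigmoid mask, upsampling
   the attention map on the way with top-K refinement.

Because the attention pathway never sees masks, re-targeting the same images
to a different structure only requires re-running the support encoder and
decoder — the attention map is reusable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .attention import coarse_attention_raw, init_mapper_params, init_upsampler_params
from .decoder import _flat_q, _flat_s, decode_raw, init_decoder_params
from .encoders import (EMAState, EncoderConfig, build_encoder_params, count_params,
                       ema_init, ema_update, encode_support, encoder_forward)

__all__ = ["Episode", "SegmentationPrediction", "ModelConfig", "InContextSegmenter"]


@dataclass
class Episode:
    """One query image, its ground truth (optional at inference) and S
    support pairs.  All rasters are (H, W) float in [0, 1]; masks binary."""

    query_image: np.ndarray
    support_images: np.ndarray  # (S, H, W)
    support_masks: np.ndarray   # (S, H, W), binary
    query_mask: Optional[np.ndarray] = None
    task_id: Optional[str] = None

    def __post_init__(self):
        if len(self.support_images) != len(self.support_masks):
            raise ValueError("episode needs equally many support images and masks")
        if len(self.support_images) < 1:
            raise ValueError("episode needs at least one support pair")

    @property
    def S(self) -> int:
        return len(self.support_images)


@dataclass
class SegmentationPrediction:
    """Sigmoid mask plus optional per-stage attention maps (stride, A, mass)."""

    mask: np.ndarray
    stage_attention: Optional[list] = None


@dataclass
class ModelConfig:
    image_size: int = 256
    preset: str = "full"
    stage_widths: Optional[tuple] = None
    stage_depths: Optional[tuple] = None
    n_registry_tokens: int = 4
    ema_decay: float = 0.999
    base_top_k: int = 8  # inference default; training schedules override

    def encoder_config(self, in_channels: int) -> EncoderConfig:
        if self.stage_widths is not None or self.stage_depths is not None:
            base = EncoderConfig.from_preset(self.preset, in_channels)
            return EncoderConfig(
                in_channels=in_channels,
                stage_widths=self.stage_widths or base.stage_widths,
                stage_depths=self.stage_depths or base.stage_depths,
                preset=self.preset)
        return EncoderConfig.from_preset(self.preset, in_channels)


def init_model_params(config: ModelConfig, rng) -> dict:
    w = config.encoder_config(1).stage_widths
    d32, d16, d8 = w[3], w[2], w[1]
    return {
        "seg": build_encoder_params(config.encoder_config(1), rng),
        "sup": build_encoder_params(config.encoder_config(2), rng),
        "attn": build_encoder_params(config.encoder_config(1), rng),
        "mapper": init_mapper_params(d32, config.n_registry_tokens, rng),
        "ups": [init_upsampler_params(d16, d16, rng),
                init_upsampler_params(d8, d8, rng)],
        "dec": init_decoder_params(w, rng),
    }


def model_forward(params, ema_shadow, query_image, support_images, support_masks,
                  base_top_k: int = 8, collect_attention: bool = False,
                  refine: bool = True, zero_attention: bool = False):
    """Pure traced forward pass -> (probs (H, W), stage attention list).

    ``ema_shadow`` holds the EMA twin of the attention encoder; it is passed
    separately from ``params`` so it never receives gradients.

    ``zero_attention=True`` is a diagnostic ablation that blanks the coarse
    attention map (all mass to the registry): since the Support Set Encoder
    is the only pathway from support masks to the output and it is modulated
    solely by A, the prediction must then be mask-independent.
    """
    S = len(support_images)
    q = np.asarray(query_image)
    size = q.shape[-1]
    h32 = size // 32
    seg_pyr = encoder_forward(params["seg"], q.reshape(1, 1, size, size))
    sup_pyr = encode_support(params["sup"], support_images, support_masks)
    attn_q_pyr = encoder_forward(params["attn"], q.reshape(1, 1, size, size))
    attn_s_pyr = encode_support(ema_shadow, support_images)
    A, reg_mass = coarse_attention_raw(
        params["mapper"], _flat_q(attn_q_pyr[32]), _flat_s(attn_s_pyr[32]))
    if zero_attention:
        A = A * 0.0
        reg_mass = reg_mass * 0.0 + 1.0
    return decode_raw(params["dec"], params["ups"], seg_pyr, sup_pyr,
                      attn_q_pyr, attn_s_pyr, A, reg_mass, S,
                      base_top_k=base_top_k, collect_attention=collect_attention,
                      refine=refine)


class InContextSegmenter:
    """Stateful wrapper: parameters, EMA state, config, checkpointing."""

    def __init__(self, config: ModelConfig = None, seed: int = 0,
                 params: dict = None, ema: EMAState = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.params = params if params is not None else init_model_params(self.config, rng)
        self.ema = ema if ema is not None else ema_init(self.params["attn"],
                                                        self.config.ema_decay)

    # -- inference ---------------------------------------------------------

    def predict(self, episode: Episode, top_k: Optional[int] = None,
                collect_attention: bool = False) -> SegmentationPrediction:
        k = self.config.base_top_k if top_k is None else top_k
        probs, attn = model_forward(
            self.params, self.ema.shadow, episode.query_image,
            episode.support_images, episode.support_masks,
            base_top_k=k, collect_attention=collect_attention)
        return SegmentationPrediction(
            mask=np.asarray(probs),
            stage_attention=attn if collect_attention else None)

    # -- EMA ---------------------------------------------------------------

    def update_ema(self):
        self.ema = ema_update(self.ema, self.params["attn"])

    def n_params(self) -> int:
        return count_params(self.params)

    # -- checkpointing -----------------------------------------------------

    def save(self, path):
        from .io import save_checkpoint

        save_checkpoint(path, self)

    @classmethod
    def load(cls, path) -> "InContextSegmenter":
        from .io import load_checkpoint

        return load_checkpoint(path)
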