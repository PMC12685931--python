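"""Segmentation decoder: Provided-Attention fusion and five decoding stages.

The only pathway from support-set *masks* to the prediction runs through the
Support Set Encoder, and its features enter the decoder exclusively via
Provided-Attention blocks

    x_i^q := x_i^q + (A_i . X^s) W_p + b_p

modulated by the (mask-independent) attention map A.  Stage 1 fuses at
stride 32 with the coarse attention map; stages 2 and 3 upsample A (strides
16 and 8) with attention-upsampler blocks; stages 4 and 5 use only query
skip connections; a final skip-free stage restores full resolution and a 1x1
projector with a sigmoid produces the mask.  Query features are upscaled
between stages by 3x3 stride-2 transposed convolutions.  Every inner
residual block ends in a zero-initialized layer, so the whole decoder is an
identity-plus-nothing at initialization, and all block inputs come through
LayerNorm (z-score over channel/height/width per sample).
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .attention import effective_top_k, upsample_attention
from .nn import conv2d, conv_transpose2d_x2, gelu, he_init, layer_norm, sigmoid

__all__ = [
    "init_pa_params",
    "provided_attention_apply",
    "init_decoder_params",
    "decode_raw",
]


def init_pa_params(d: int) -> dict:
    """Projection of the Provided-Attention block; zero-initialized so the
    block is exactly the identity at the start of training."""
    return {"W_p": np.zeros((d, d)), "b_p": np.zeros(d)}


def provided_attention_apply(X_q, A, X_s, params):
    """Residual attention-weighted support injection, row-wise.

    X_q: (R, d) query features; A: (R, M) attention; X_s: (M, d) support
    features with M = S * rows'.
    """
    if A.shape[1] != X_s.shape[0]:
        raise ValueError("attention columns must match support feature rows")
    if A.shape[0] != X_q.shape[0]:
        raise ValueError("attention rows must match query feature rows")
    return X_q + anp.dot(anp.dot(A, X_s), params["W_p"]) + params["b_p"]


def _res_block_p(rng, c):
    return {
        "c1": {"w": he_init(rng, (c, c, 3, 3)), "b": np.zeros(c)},
        # zero-init: the residual contribution vanishes at initialization
        "c2": {"w": np.zeros((c, c, 1, 1)), "b": np.zeros(c)},
    }


def _res_block_fwd(p, x):
    h = layer_norm(x)
    h = conv2d(h, p["c1"]["w"], p["c1"]["b"])
    h = gelu(h)
    h = conv2d(h, p["c2"]["w"], p["c2"]["b"])
    return x + h


def _upconv_p(rng, c_in, c_out):
    return {"w": he_init(rng, (c_out, c_in, 3, 3)), "b": np.zeros(c_out)}


def init_decoder_params(stage_widths, rng) -> dict:
    """Decoder parameters; channel widths mirror the encoder stages."""
    w = list(stage_widths)
    w0 = w[0]  # stem width (skips at strides 2 and 4)
    return {
        "pa": [init_pa_params(w[3]), init_pa_params(w[2]), init_pa_params(w[1])],
        "res": [
            _res_block_p(rng, w[3]),
            _res_block_p(rng, w[2]),
            _res_block_p(rng, w[1]),
            _res_block_p(rng, w0),
            _res_block_p(rng, w0),
        ],
        "up": [
            _upconv_p(rng, w[3], w[2]),  # 32 -> 16
            _upconv_p(rng, w[2], w[1]),  # 16 -> 8
            _upconv_p(rng, w[1], w0),    # 8 -> 4
            _upconv_p(rng, w0, w0),      # 4 -> 2
        ],
        "head": {
            "up": _upconv_p(rng, w0, w0),  # 2 -> 1
            "proj": {"w": he_init(rng, (1, w0, 1, 1)), "b": np.zeros(1)},
        },
    }


def _flat_q(fmap):
    """(1, C, h, w) -> (h*w, C), row-major over (h, w)."""
    _, C, h, w = fmap.shape
    return anp.reshape(anp.transpose(fmap[0], (1, 2, 0)), (h * w, C))


def _flat_s(fmap):
    """(S, C, h, w) -> (S*h*w, C); support examples concatenated in order."""
    S, C, h, w = fmap.shape
    return anp.reshape(anp.transpose(fmap, (0, 2, 3, 1)), (S * h * w, C))


def _unflat_q(x, h, w):
    R, C = x.shape
    return anp.transpose(anp.reshape(x, (1, h, w, C)), (0, 3, 1, 2))


def decode_raw(dec, ups, seg_pyr, sup_pyr, attn_q_pyr, attn_s_pyr,
               A, registry_mass, S: int, base_top_k: int = 8,
               collect_attention: bool = False, refine: bool = True):
    """Full decoding pass; returns (probability map (H, W), attention maps).

    ``A`` is the coarse attention map at stride 32 with its registry mass;
    ``ups`` is the pair of attention-upsampler parameter sets used at strides
    16 and 8 with effective top-K of ``4*base_top_k`` and ``16*base_top_k``.
    """
    stages_attn = []
    h32 = seg_pyr[32].shape[2]
    # ---- stage 1: fuse at stride 32 with the coarse map, no upscaling
    x = _flat_q(seg_pyr[32])
    x = provided_attention_apply(x, A, _flat_s(sup_pyr[32]), dec["pa"][0])
    x = _unflat_q(x, h32, h32)
    x = _res_block_fwd(dec["res"][0], x)
    if collect_attention:
        stages_attn.append((32, A, registry_mass))
    # ---- stages 2 and 3: upsample attention, upscale, fuse
    cur_A, cur_mass, cur_reg = A, None, registry_mass
    h, w = h32, h32
    for i, stride in enumerate((16, 8)):
        x = conv_transpose2d_x2(x, dec["up"][i]["w"], dec["up"][i]["b"])
        x = x + seg_pyr[stride]
        K = effective_top_k(base_top_k, i + 1)
        cur_A, cur_mass = upsample_attention(
            cur_A, ups[i],
            _flat_q(attn_q_pyr[stride]), _flat_s(attn_s_pyr[stride]),
            S, h, w, K,
            registry_mass=cur_reg, refine=refine)
        cur_reg = None  # mass now carried explicitly by the rows of A
        h, w = 2 * h, 2 * w
        xf = _flat_q(x)
        xf = provided_attention_apply(xf, cur_A, _flat_s(sup_pyr[stride]),
                                      dec["pa"][i + 1])
        x = _unflat_q(xf, h, w)
        x = _res_block_fwd(dec["res"][i + 1], x)
        if collect_attention:
            stages_attn.append((stride, cur_A, cur_mass))
    # ---- stages 4 and 5: query skips only
    for i, stride in enumerate((4, 2)):
        x = conv_transpose2d_x2(x, dec["up"][i + 2]["w"], dec["up"][i + 2]["b"])
        x = x + seg_pyr[stride]
        x = _res_block_fwd(dec["res"][i + 3], x)
    # ---- final stage: no skip connections, upsample to full resolution
    x = conv_transpose2d_x2(x, dec["head"]["up"]["w"], dec["head"]["up"]["b"])
    x = gelu(x)
    x = conv2d(x, dec["head"]["proj"]["w"], dec["head"]["proj"]["b"])
    probs = sigmoid(x[0, 0])
    return probs, stages_attn
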