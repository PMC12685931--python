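"""Differentiable building blocks on top of ``autograd``/NumPy.

Every operation here is a pure function of (parameters, inputs) built from
``autograd.numpy`` primitives, so that reverse-mode differentiation of a whole
model forward pass "just works".  Convolutions are expressed as im2col
gather + matmul; spatial resampling is expressed as multiplication with
precomputed 1-D interpolation matrices (which keeps it linear and exactly
differentiable, including through the learnable nearest/bilinear mix used by
the attention upsampler).

Parameters are plain nested dicts of ``numpy`` arrays.  Nothing in this module
keeps state.
"""

from __future__ import annotations

from functools import lru_cache

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import erf

__all__ = [
    "gelu",
    "elu",
    "sigmoid",
    "softmax",
    "layer_norm",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2d_x2",
    "upsample2x",
    "interp_matrix_2x",
    "resize_matrix",
    "he_init",
    "tree_map",
    "tree_like",
]

_SQRT2 = np.sqrt(2.0)


def gelu(x):
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def elu(x):
    """ELU with alpha=1; ``1 + elu(x) > 0`` for all finite x."""
    return anp.where(x > 0, x, anp.expm1(anp.minimum(x, 0.0)))


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(logits, axis=-1):
    z = logits - anp.max(logits, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def layer_norm(x, axes=(1, 2, 3), eps=1e-6):
    """Plain z-score over the given axes, independently per sample.

    Follows the convention that normalization runs jointly over channel,
    height and width; no learnable affine terms, so the output is exactly
    zero-mean / unit-variance (up to eps) — skip connections emitted from
    these layers are therefore normalized by construction.
    """
    mu = anp.mean(x, axis=axes, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=axes, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps)


@lru_cache(maxsize=None)
def _gather_indices(H, W, k, stride, pad):
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    ri = np.arange(Ho)[:, None, None, None] * stride + np.arange(k)[None, :, None, None]
    ci = np.arange(Wo)[None, None, :, None] * stride + np.arange(k)[None, None, None, :]
    return ri, ci, Ho, Wo


def _im2col(x, k, stride, pad):
    N, C, H, W = x.shape
    if pad:
        x = anp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    ri, ci, Ho, Wo = _gather_indices(H, W, k, stride, pad)
    cols = x[:, :, ri, ci]  # (N, C, Ho, k, Wo, k)
    return cols, Ho, Wo


def conv2d(x, w, b, stride=1, pad=None):
    """2-D convolution (cross-correlation), x: (N,C,H,W), w: (O,C,k,k)."""
    O, C, k, _ = w.shape
    if pad is None:
        pad = k // 2
    cols, Ho, Wo = _im2col(x, k, stride, pad)
    N = x.shape[0]
    cols = anp.reshape(anp.transpose(cols, (0, 2, 4, 1, 3, 5)), (N, Ho, Wo, C * k * k))
    out = anp.dot(cols, anp.reshape(w, (O, C * k * k)).T) + b
    return anp.transpose(out, (0, 3, 1, 2))


def depthwise_conv2d(x, w, b, stride=1, pad=None):
    """Per-channel conv, x: (N,C,H,W), w: (C,k,k)."""
    C, k, _ = w.shape
    if pad is None:
        pad = k // 2
    cols, Ho, Wo = _im2col(x, k, stride, pad)  # (N, C, Ho, k, Wo, k)
    out = anp.einsum("nchkwl,ckl->nchw", cols, w)
    return out + b[None, :, None, None]


def _interleave_zeros(x, axis):
    """Insert a zero after every element along axis (size n -> 2n)."""
    z = anp.zeros(x.shape)
    y = anp.stack([x, z], axis=axis + 1)
    shape = list(x.shape)
    shape[axis] *= 2
    return anp.reshape(y, shape)


def conv_transpose2d_x2(x, w, b):
    """Transposed conv, kernel 3, stride 2, doubling H and W exactly.

    Implemented as zero-stuffing (x placed at even coordinates) followed by a
    regular 3x3 convolution; equivalent to a stride-2 transposed convolution
    with output padding 1.  w: (O, C, 3, 3) acting on x: (N, C, H, W).
    """
    up = _interleave_zeros(_interleave_zeros(x, 2), 3)
    return conv2d(up, w, b, stride=1, pad=1)


@lru_cache(maxsize=None)
def interp_matrix_2x(n, mode):
    """(2n, n) matrix M so that M @ v upsamples v by 2 (half-pixel centers)."""
    out = np.zeros((2 * n, n))
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    if mode == "nearest":
        # for factor 2 the half-pixel source positions are -0.25, 0.25, 0.75,
        # ... so nearest-source is floor(i/2) for every output index i
        idx = np.clip(np.arange(2 * n) // 2, 0, n - 1)
        out[np.arange(2 * n), idx] = 1.0
    elif mode == "linear":
        lo = np.clip(np.floor(src).astype(int), 0, n - 1)
        hi = np.clip(lo + 1, 0, n - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        t[src > n - 1] = 0.0
        out[np.arange(2 * n), lo] += 1.0 - t
        out[np.arange(2 * n), hi] += t
    else:  # pragma: no cover
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return out


def resize_matrix(n_out, n_in, mode="linear"):
    """General 1-D resize matrix (n_out, n_in), half-pixel convention."""
    out = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    if mode == "nearest":
        idx = np.clip(np.floor(src + 0.5).astype(int), 0, n_in - 1)
        out[np.arange(n_out), idx] = 1.0
    else:
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        t[src > n_in - 1] = 0.0
        out[np.arange(n_out), lo] += 1.0 - t
        out[np.arange(n_out), hi] += t
    return out


def upsample2x(x, mh, mw):
    """Apply (2H,H) and (2W,W) interpolation matrices to the last two axes."""
    y = anp.tensordot(x, mh.T, axes=([x.ndim - 2], [0]))  # (..., W, 2H)
    y = anp.moveaxis(y, -1, -2)  # (..., 2H, W)
    y = anp.tensordot(y, mw.T, axes=([y.ndim - 1], [0]))  # (..., 2H, 2W)
    return y


def he_init(rng, shape, fan_in=None):
    if fan_in is None:
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


def tree_map(fn, tree, *rest):
    """Map a function over nested dict/list structures of arrays."""
    if isinstance(tree, dict):
        return {k: tree_map(fn, tree[k], *(r[k] for r in rest)) for k in tree}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(fn, t, *(r[i] for r in rest)) for i, t in enumerate(tree))
    return fn(tree, *rest)


def tree_like(tree, fill=0.0):
    return tree_map(lambda a: np.full_like(np.asarray(a, dtype=float), fill), tree)
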