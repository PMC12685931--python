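"""Cross-attention mapper and hierarchical attention upsampling.

The coarse attention map relates every query location at the coarsest
encoder level (stride 32) to every support-set location:

    A_i = softmax( x_i^q W_Q W_K^T [X^s, t^s]^T / (delta * T) )[: S*H*W]

where delta = 0.1 d scales the logits, T = exp(tau) is a learnable,
always-positive softmax temperature, and t^s are learnable registry tokens —
synthetic keys that let a query location park probability mass "nowhere in
the support set"; their (discarded) mass makes each retained row sum <= 1.

The attention upsampler doubles the resolution of an attention map without
recomputing attention at the finer scale.  Both axes are interpolated with a
learnable mix c*nearest + (1-c)*bilinear, the per-row attention mass is
preserved by renormalization, and only the top-K entries per row are refined
by a small feed-forward network acting on (attention value, query feature,
support feature); the refinement factor 1 + ELU(y) is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval

from .nn import elu, gelu, he_init, interp_matrix_2x, sigmoid, softmax


@primitive
def _scatter_rows(values, idx, cols):
    """Dense (rows, cols) matrix with values[r, k] placed at column idx[r, k].

    Top-K indices are unique within a row, so no accumulation collisions."""
    rows, K = idx.shape
    out = np.zeros((rows, cols))
    out[np.arange(rows)[:, None], idx] = values
    return out


defvjp(_scatter_rows,
       lambda ans, values, idx, cols: lambda g: g[np.arange(idx.shape[0])[:, None], idx])

__all__ = [
    "CoarseAttentionMap",
    "init_mapper_params",
    "init_upsampler_params",
    "mapper_temperature",
    "upsampler_mix",
    "compute_coarse_attention",
    "coarse_attention_raw",
    "upsample_attention",
    "topk_select",
    "renormalize_to_mass",
    "effective_top_k",
]


@dataclass
class CoarseAttentionMap:
    """Dense (H*W, S*H*W) attention matrix plus discarded registry mass.

    Flattening is row-major over (H, W); support examples are concatenated in
    their given order along columns.  Row sums plus registry mass equal 1.
    """

    A: np.ndarray
    registry_mass: np.ndarray
    S: int
    H: int
    W: int

    @property
    def mass(self):
        return 1.0 - self.registry_mass


def init_mapper_params(d: int, n_registry: int, rng) -> dict:
    """W_Q/W_K projections, log-temperature tau (T = e^tau, init 1) and
    registry tokens.  delta = 0.1 d is recomputed from d, never stored."""
    return {
        "W_Q": he_init(rng, (d, d)),
        "W_K": he_init(rng, (d, d)),
        "tau": np.zeros(()),
        "registry": rng.standard_normal((n_registry, d)) / np.sqrt(d),
    }


def mapper_temperature(params):
    return anp.exp(params["tau"])


def coarse_attention_raw(params, query_feats, support_feats):
    """Traced core of the mapper softmax: returns (A, registry_mass).

    query_feats: (R, d) rows of the flattened coarse query feature map;
    support_feats: (M, d) flattened support features (M = S*H*W).  Support
    masks never enter this computation.
    """
    d = query_feats.shape[1]
    if support_feats.shape[1] != d or params["W_Q"].shape[0] != d:
        raise ValueError("feature dimensionality mismatch with mapper parameters")
    delta = 0.1 * d
    temp = mapper_temperature(params)
    keys = anp.concatenate([support_feats, params["registry"]], axis=0)
    logits = anp.dot(anp.dot(query_feats, params["W_Q"]),
                     anp.dot(keys, params["W_K"]).T) / (delta * temp)
    probs = softmax(logits, axis=1)
    M = support_feats.shape[0]
    A = probs[:, :M]
    registry_mass = anp.sum(probs[:, M:], axis=1)
    return A, registry_mass


def compute_coarse_attention(params, query_feats, support_feats,
                             S: int, H: int, W: int) -> CoarseAttentionMap:
    """Public wrapper returning a :class:`CoarseAttentionMap`."""
    qf = np.asarray(query_feats, dtype=float)
    sf = np.asarray(support_feats, dtype=float)
    if not (np.all(np.isfinite(qf)) and np.all(np.isfinite(sf))):
        raise ValueError("non-finite features passed to the attention mapper")
    if sf.shape[0] != S * H * W:
        raise ValueError("support feature count does not match S*H*W")
    A, reg = coarse_attention_raw(params, qf, sf)
    return CoarseAttentionMap(A=np.asarray(A), registry_mass=np.asarray(reg),
                              S=S, H=H, W=W)


# ---------------------------------------------------------------------------
# upsampler


def init_upsampler_params(d_query: int, d_support: int, rng) -> dict:
    """Mix logit u (c = logistic(u), init 0.5) and the refinement FFN.

    The FFN takes (attention value, query feature, support feature), has one
    GELU hidden layer of width d_query, and a zero-initialized scalar output
    so refinement starts as the identity (1 + ELU(0) = 1).
    """
    d_in = 1 + d_query + d_support
    hidden = max(d_query, 4)
    return {
        "u": np.zeros(()),
        "ffn": {
            "w1": he_init(rng, (d_in, hidden), fan_in=d_in),
            "b1": np.zeros(hidden),
            "w2": np.zeros((hidden, 1)),
            "b2": np.zeros(1),
        },
    }


def upsampler_mix(params):
    """The learnable nearest/bilinear mixing coefficient c in [0, 1]."""
    return sigmoid(params["u"])


def topk_select(row, K: int):
    """Indices of the K largest weights; ties go to the lower flattened
    support index (stable sort on the negated row)."""
    row = np.asarray(getval(row))
    K = min(int(K), row.shape[-1])
    order = np.argsort(-row, axis=-1, kind="stable")
    return order[..., :K]


def renormalize_to_mass(A, target_mass, eps: float = 1e-12):
    """Scale each row of A so its sum equals target_mass; zero rows stay zero."""
    if np.any(getval(target_mass) < -1e-12):
        raise ValueError("attention mass must be nonnegative")
    rowsum = anp.sum(A, axis=1)
    safe = anp.where(rowsum > eps, rowsum, 1.0)
    scale = anp.where(rowsum > eps, target_mass / safe, 0.0)
    return A * scale[:, None]


def _mix_matrix(n, c):
    return c * interp_matrix_2x(n, "nearest") + (1.0 - c) * interp_matrix_2x(n, "linear")


def _upsample_support_axis(A, S, H, W, mh, mw):
    """(R, S*H*W) -> (R, S*2H*2W) by interpolating each support tile."""
    R = A.shape[0]
    t = anp.reshape(A, (R * S, H, W))
    t = anp.einsum("oh,nhw,pw->nop", mh, t, mw)
    return anp.reshape(t, (R, S * 2 * H * 2 * W))


def _upsample_query_axis(A, H, W, mh, mw):
    """(H*W, C) -> (2H*2W, C) by interpolating the query grid."""
    C = A.shape[1]
    t = anp.reshape(A, (H, W, C))
    t = anp.einsum("oh,hwc,pw->opc", mh, t, mw)
    return anp.reshape(t, (2 * H * 2 * W, C))


def upsample_attention(A, params, query_feats_next, support_feats_next,
                       S: int, H: int, W: int, K: int,
                       registry_mass=None, refine: bool = True):
    """One attention-upsampler stage: (H*W, S*H*W) -> (2H*2W, S*2H*2W).

    Steps, in order: (1) per-row attention mass from A (or 1 - registry mass
    at the coarse level); (2) support-axis interpolation with the learnable
    c-mix; (3) query-axis interpolation likewise; (4) row renormalization to
    the upsampled mass; (5) top-K refinement A_ij *= 1 + ELU(y_FFN); (6) row
    renormalization again.  Non-top-K entries keep their interpolated values.

    query_feats_next: (2H*2W, dq) and support_feats_next: (S*2H*2W, ds) come
    from the matching finer level of the attention mapper encoder and its EMA
    twin.  Returns (A_up, mass_up).
    """
    cols = S * 2 * H * 2 * W
    if K > cols:
        import warnings

        warnings.warn(f"top-K={K} exceeds {cols} support locations; clamping")
        K = cols
    if K < 1:
        raise ValueError("top-K must be >= 1")
    # step 1: attention mass
    mass = anp.sum(A, axis=1) if registry_mass is None else 1.0 - registry_mass
    c = upsampler_mix(params)
    mh, mw = _mix_matrix(H, c), _mix_matrix(W, c)
    # steps 2-3: separable c-mixed interpolation of both axes
    A2 = _upsample_support_axis(A, S, H, W, mh, mw)
    A2 = _upsample_query_axis(A2, H, W, mh, mw)
    # step 4: upsample the mass the same way and restore row sums
    mass_up = anp.reshape(
        anp.einsum("oh,hw,pw->op", mh, anp.reshape(mass, (H, W)), mw),
        (2 * H * 2 * W,))
    A2 = renormalize_to_mass(A2, mass_up)
    if refine:
        # step 5: refine the K strongest support locations of each row
        rows = 2 * H * 2 * W
        idx = topk_select(A2, K)  # (rows, K)
        r = np.arange(rows)[:, None]
        vals = A2[r, idx]
        q = query_feats_next[np.repeat(np.arange(rows), K)]
        s = support_feats_next[idx.ravel()]
        ff = params["ffn"]
        inp = anp.concatenate([anp.reshape(vals, (-1, 1)), q, s], axis=1)
        y = anp.dot(gelu(anp.dot(inp, ff["w1"]) + ff["b1"]), ff["w2"]) + ff["b2"]
        factor = 1.0 + elu(anp.reshape(y, (rows, K)))
        # scatter the multiplicative update back without in-place assignment
        A2 = A2 + _scatter_rows(vals * (factor - 1.0), idx, cols)
        # step 6: restore row sums once more
        A2 = renormalize_to_mass(A2, mass_up)
    return A2, mass_up


def effective_top_k(base_k: int, upsampler_stage: int) -> int:
    """K quadruples at each successive upsampler stage (1-indexed): with the
    inference base of 8 this yields 32 refined locations at stride 16 and
    128 at stride 8."""
    if base_k < 1:
        raise ValueError("base top-K must be >= 1")
    return base_k * 4 ** upsampler_stage
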