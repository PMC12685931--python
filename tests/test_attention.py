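"""Cross-attention mapper and attention upsampler against independent oracles."""

import numpy as np
import pytest

from icseg.attention import (compute_coarse_attention, coarse_attention_raw,
                             effective_top_k, init_mapper_params,
                             init_upsampler_params, renormalize_to_mass,
                             topk_select, upsample_attention, upsampler_mix)
from icseg.nn import interp_matrix_2x


def scalar_attention_oracle(params, qf, sf):
    """Element-wise softmax evaluation of the attention formula."""
    d = qf.shape[1]
    delta = 0.1 * d
    T = np.exp(params["tau"])
    keys = np.vstack([sf, params["registry"]])
    A = np.zeros((qf.shape[0], sf.shape[0]))
    reg = np.zeros(qf.shape[0])
    for i in range(qf.shape[0]):
        logits = np.array([(qf[i] @ params["W_Q"]) @ (params["W_K"].T @ keys[j])
                           / (delta * T) for j in range(len(keys))])
        e = np.exp(logits - logits.max())
        pr = e / e.sum()
        A[i] = pr[: sf.shape[0]]
        reg[i] = pr[sf.shape[0]:].sum()
    return A, reg


def dense_upsample_oracle(A, c, S, H, W):
    """Dense interpolate-and-renormalize without any top-K shortcut."""
    M = {n: c * interp_matrix_2x(n, "nearest") + (1 - c) * interp_matrix_2x(n, "linear")
         for n in {H, W}}
    R = A.shape[0]
    t = A.reshape(R * S, H, W)
    t = np.einsum("oh,nhw,pw->nop", M[H], t, M[W]).reshape(R, S * 4 * H * W)
    t = t.reshape(H, W, -1)
    t = np.einsum("oh,hwc,pw->opc", M[H], t, M[W]).reshape(4 * H * W, S * 4 * H * W)
    mass = A.sum(1).reshape(H, W)
    mu = np.einsum("oh,hw,pw->op", M[H], mass, M[W]).ravel()
    rs = t.sum(1)
    scale = np.where(rs > 1e-12, mu / np.where(rs > 1e-12, rs, 1.0), 0.0)
    return t * scale[:, None], mu


class TestCoarseAttention:
    def test_rows_sum_to_one_without_registry(self, rng):
        p = init_mapper_params(4, 0, rng)
        A, reg = coarse_attention_raw(p, rng.standard_normal((6, 4)),
                                      rng.standard_normal((12, 4)))
        np.testing.assert_allclose(np.asarray(A).sum(1), 1.0, atol=1e-6)
        assert np.all(np.asarray(reg) == 0)

    def test_symmetric_two_way_softmax_with_registry(self):
        # one support location and one registry token with the same logit
        p = init_mapper_params(2, 1, np.random.default_rng(0))
        p["W_Q"] = np.eye(2)
        p["W_K"] = np.eye(2)
        p["tau"] = np.zeros(())
        sf = np.array([[1.0, 0.0]])
        p["registry"] = np.array([[1.0, 0.0]])
        cam = compute_coarse_attention(p, np.array([[1.0, 0.0]]), sf, S=1, H=1, W=1)
        np.testing.assert_allclose(cam.A, [[0.5]], atol=1e-12)
        np.testing.assert_allclose(cam.registry_mass, [0.5], atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        S, H, W, d = 2, 2, 2, 3
        p = init_mapper_params(d, 4, rng)
        qf = rng.standard_normal((H * W, d))
        sf = rng.standard_normal((S * H * W, d))
        cam = compute_coarse_attention(p, qf, sf, S, H, W)
        A_or, reg_or = scalar_attention_oracle(p, qf, sf)
        np.testing.assert_allclose(cam.A, A_or, atol=1e-6)
        np.testing.assert_allclose(cam.registry_mass, reg_or, atol=1e-6)

    def test_mass_conservation_per_row(self, rng):
        p = init_mapper_params(5, 3, rng)
        cam = compute_coarse_attention(p, rng.standard_normal((4, 5)),
                                       rng.standard_normal((8, 5)), 2, 2, 2)
        np.testing.assert_allclose(cam.A.sum(1) + cam.registry_mass, 1.0, atol=1e-5)

    def test_support_permutation_equivariance(self, rng):
        S, H, W, d = 2, 2, 2, 4
        p = init_mapper_params(d, 2, rng)
        qf = rng.standard_normal((H * W, d))
        sf = rng.standard_normal((S * H * W, d))
        cam = compute_coarse_attention(p, qf, sf, S, H, W)
        # swap the two support examples: column blocks swap, registry mass fixed
        swapped = np.concatenate([sf[H * W:], sf[:H * W]], axis=0)
        cam2 = compute_coarse_attention(p, qf, swapped, S, H, W)
        np.testing.assert_allclose(cam2.A[:, :H * W], cam.A[:, H * W:], atol=1e-12)
        np.testing.assert_allclose(cam2.registry_mass, cam.registry_mass, atol=1e-12)

    def test_registry_monotonicity(self, rng):
        """Raising a registry token's logit strictly drains support mass."""
        d = 3
        p = init_mapper_params(d, 1, rng)
        qf = rng.standard_normal((2, d))
        sf = rng.standard_normal((4, d))
        base = compute_coarse_attention(p, qf, sf, 1, 2, 2).mass
        # shift the token so its key-projected logit for row 0 strictly grows
        u = qf[0] @ p["W_Q"]
        p2 = {**p, "registry": p["registry"] + u @ np.linalg.inv(p["W_K"])}
        boosted = compute_coarse_attention(p2, qf, sf, 1, 2, 2).mass
        assert boosted[0] < base[0]

    def test_dimension_mismatch_and_nonfinite_rejected(self, rng):
        p = init_mapper_params(4, 0, rng)
        with pytest.raises(ValueError):
            compute_coarse_attention(p, rng.standard_normal((2, 3)),
                                     rng.standard_normal((4, 3)), 1, 2, 2)
        bad = np.full((2, 4), np.nan)
        with pytest.raises(ValueError):
            compute_coarse_attention(p, bad, rng.standard_normal((4, 4)), 1, 2, 2)


class TestTopK:
    def test_simple_and_tie_and_oracle(self, rng):
        np.testing.assert_array_equal(topk_select(np.array([0.1, 0.7, 0.2]), 2), [1, 2])
        np.testing.assert_array_equal(topk_select(np.ones(4), 2), [0, 1])
        row = rng.random(50)
        np.testing.assert_array_equal(topk_select(row, 5), np.argsort(-row)[:5])


class TestRenormalize:
    def test_proportional_zero_row_and_random(self, rng):
        # proportional scaling: row sum 4 scaled to mass 0.5 -> entries 0.25
        out = renormalize_to_mass(np.array([[2.0, 2.0]]), np.array([0.5]))
        np.testing.assert_allclose(out, [[0.25, 0.25]])
        out = renormalize_to_mass(np.zeros((1, 3)), np.array([0.3]))
        np.testing.assert_array_equal(out, np.zeros((1, 3)))
        A = rng.random((5, 7))
        mass = rng.random(5)
        out = np.asarray(renormalize_to_mass(A, mass))
        np.testing.assert_allclose(out.sum(1), mass, atol=1e-6)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            renormalize_to_mass(np.ones((1, 2)), np.array([-0.1]))


class TestUpsampler:
    def _params(self, rng, dq=5, ds=5):
        return init_upsampler_params(dq, ds, rng)

    def test_uniform_map_stays_uniform_with_full_mass(self, rng):
        S, H, W = 1, 2, 2
        p = self._params(rng)
        p["u"] = np.array(50.0)  # c -> 1 (pure nearest)
        A = np.full((H * W, S * H * W), 1.0 / (S * H * W))
        qn = rng.standard_normal((4 * H * W, 5))
        sn = rng.standard_normal((S * 4 * H * W, 5))
        A2, m2 = upsample_attention(A, p, qn, sn, S, H, W, K=S * 4 * H * W)
        np.testing.assert_allclose(np.asarray(A2), 1.0 / (S * 4 * H * W), atol=1e-9)
        np.testing.assert_allclose(np.asarray(m2), 1.0, atol=1e-9)

    @pytest.mark.parametrize("S,H,W", [(1, 2, 2), (2, 4, 4), (2, 3, 4)])
    def test_matches_dense_oracle_with_full_k(self, rng, S, H, W):
        p = self._params(rng)
        A = rng.random((H * W, S * H * W))
        A = A / A.sum(1, keepdims=True) * rng.random(H * W)[:, None]
        qn = rng.standard_normal((4 * H * W, 5))
        sn = rng.standard_normal((S * 4 * H * W, 5))
        A2, m2 = upsample_attention(A, p, qn, sn, S, H, W, K=S * 4 * H * W)
        c = float(upsampler_mix(p))
        A_or, m_or = dense_upsample_oracle(A, c, S, H, W)
        np.testing.assert_allclose(np.asarray(A2), A_or, atol=1e-5)
        np.testing.assert_allclose(np.asarray(m2), m_or, atol=1e-5)

    def test_mass_conserved_even_with_nonzero_refinement(self, rng):
        S, H, W = 2, 4, 4
        p = self._params(rng)
        p["ffn"]["w2"] = rng.standard_normal(p["ffn"]["w2"].shape)  # non-identity
        A = rng.random((H * W, S * H * W))
        qn = rng.standard_normal((4 * H * W, 5))
        sn = rng.standard_normal((S * 4 * H * W, 5))
        A2, m2 = upsample_attention(A, p, qn, sn, S, H, W, K=6)
        np.testing.assert_allclose(np.asarray(A2).sum(1), np.asarray(m2), atol=1e-5)
        assert np.all(np.asarray(A2) >= -1e-12)  # 1 + ELU(y) > 0 keeps weights nonnegative

    def test_oversized_k_clamped_with_warning(self, rng):
        S, H, W = 1, 2, 2
        p = self._params(rng)
        A = np.full((H * W, S * H * W), 0.25)
        qn = rng.standard_normal((4 * H * W, 5))
        sn = rng.standard_normal((S * 4 * H * W, 5))
        with pytest.warns(UserWarning):
            upsample_attention(A, p, qn, sn, S, H, W, K=10_000)

    def test_zero_mass_row_stays_zero(self, rng):
        S, H, W = 1, 2, 2
        p = self._params(rng)
        A = np.zeros((H * W, S * H * W))
        A[1:] = 0.1
        qn = rng.standard_normal((4 * H * W, 5))
        sn = rng.standard_normal((S * 4 * H * W, 5))
        A2, _ = upsample_attention(A, p, qn, sn, S, H, W, K=2)
        # upsampled rows fed only by the zero coarse row remain exactly zero
        assert np.asarray(A2)[0].sum() == pytest.approx(0.0, abs=1e-12)


def test_effective_top_k_chain():
    """Base K=8 refines 32 locations at stride 16 and 128 at stride 8."""
    assert [effective_top_k(8, s) for s in (1, 2)] == [32, 128]
    assert [effective_top_k(5, s) for s in (1, 2)] == [20, 80]
    with pytest.raises(ValueError):
        effective_top_k(0, 1)
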