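"""Decoder: Provided-Attention semantics, end-to-end invariances, gradients."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad
from autograd.misc import flatten

from icseg.decoder import init_pa_params, provided_attention_apply
from icseg.losses import combined_loss
from icseg.model import Episode, InContextSegmenter, ModelConfig, model_forward

SIZE = 64


class TestProvidedAttention:
    def test_zero_attention_is_identity(self, rng):
        d = 3
        p = init_pa_params(d)
        p["W_p"] = rng.standard_normal((d, d))
        Xq = rng.standard_normal((4, d))
        out = provided_attention_apply(Xq, np.zeros((4, 8)),
                                       rng.standard_normal((8, d)), p)
        np.testing.assert_allclose(out, Xq, atol=1e-12)

    def test_one_hot_attention_selects_support_row(self, rng):
        d = 3
        p = {"W_p": np.eye(d), "b_p": np.zeros(d)}
        Xq = rng.standard_normal((2, d))
        Xs = rng.standard_normal((5, d))
        A = np.zeros((2, 5))
        A[0, 3] = 1.0
        out = provided_attention_apply(Xq, A, Xs, p)
        np.testing.assert_allclose(out[0], Xq[0] + Xs[3], atol=1e-12)
        np.testing.assert_allclose(out[1], Xq[1], atol=1e-12)

    def test_matches_per_row_loop_oracle(self, rng):
        rows, m, d = 4, 8, 3
        p = {"W_p": rng.standard_normal((d, d)), "b_p": rng.standard_normal(d)}
        Xq = rng.standard_normal((rows, d))
        Xs = rng.standard_normal((m, d))
        A = rng.random((rows, m))
        out = provided_attention_apply(Xq, A, Xs, p)
        for i in range(rows):
            expected = Xq[i] + (A[i] @ Xs) @ p["W_p"] + p["b_p"]
            np.testing.assert_allclose(out[i], expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        p = init_pa_params(3)
        with pytest.raises(ValueError):
            provided_attention_apply(rng.standard_normal((2, 3)),
                                     np.zeros((2, 5)),
                                     rng.standard_normal((4, 3)), p)


class TestFullForward:
    def test_output_shape_range_and_determinism(self, tiny_model, random_episode):
        pred1 = tiny_model.predict(random_episode)
        pred2 = tiny_model.predict(random_episode)
        assert pred1.mask.shape == (SIZE, SIZE)
        assert np.all(pred1.mask > 0) and np.all(pred1.mask < 1)
        np.testing.assert_array_equal(pred1.mask, pred2.mask)

    def test_support_permutation_invariance(self, tiny_model, random_episode):
        ep = random_episode
        perm = np.array([2, 0, 3, 1])
        ep2 = Episode(query_image=ep.query_image,
                      support_images=ep.support_images[perm],
                      support_masks=ep.support_masks[perm])
        np.testing.assert_allclose(tiny_model.predict(ep).mask,
                                   tiny_model.predict(ep2).mask, atol=1e-9)

    def test_attention_ignores_support_masks(self, tiny_model, random_episode):
        """The coarse map depends on images only; re-targeting the same
        support images must leave every attention stage bit-identical."""
        ep = random_episode
        flipped = Episode(query_image=ep.query_image,
                          support_images=ep.support_images,
                          support_masks=1.0 - ep.support_masks)
        a1 = tiny_model.predict(ep, collect_attention=True).stage_attention
        a2 = tiny_model.predict(flipped, collect_attention=True).stage_attention
        for (s1, A1, _), (s2, A2, _) in zip(a1, a2):
            assert s1 == s2
            np.testing.assert_array_equal(np.asarray(A1), np.asarray(A2))

    def test_attention_stage_strides_and_shapes(self, tiny_model, random_episode):
        attn = tiny_model.predict(random_episode,
                                  collect_attention=True).stage_attention
        S = random_episode.S
        strides = [s for s, _, _ in attn]
        assert strides == [32, 16, 8]
        for stride, A, _ in attn:
            n = (SIZE // stride) ** 2
            assert np.asarray(A).shape == (n, S * n)

    def test_masks_only_reach_output_through_attention(self, random_episode):
        """With every attention map forced to zero, changing the support
        masks cannot change the prediction: the support encoder is the only
        mask pathway and it is modulated solely by A."""
        model = InContextSegmenter(ModelConfig(image_size=SIZE, preset="tiny"), seed=3)
        # make the support pathway active (PA projections are zero at init)
        r = np.random.default_rng(0)
        for pa in model.params["dec"]["pa"]:
            pa["W_p"] += r.standard_normal(pa["W_p"].shape)
        ep = random_episode
        flipped = Episode(query_image=ep.query_image,
                          support_images=ep.support_images,
                          support_masks=1.0 - ep.support_masks)
        kw = dict(base_top_k=5, zero_attention=True)
        m1, _ = model_forward(model.params, model.ema.shadow, ep.query_image,
                              ep.support_images, ep.support_masks, **kw)
        m2, _ = model_forward(model.params, model.ema.shadow, ep.query_image,
                              flipped.support_images, flipped.support_masks, **kw)
        np.testing.assert_allclose(np.asarray(m1), np.asarray(m2), atol=1e-12)
        # with attention on, the same mask change does alter the prediction
        p1 = model.predict(ep).mask
        p2 = model.predict(flipped).mask
        assert not np.allclose(p1, p2)


class TestInitializationAndGradients:
    def test_identity_at_init_residual_blocks(self):
        """Zero-initialized last layers make every inner residual block and
        Provided-Attention projection contribute exactly nothing at init."""
        m = InContextSegmenter(ModelConfig(image_size=SIZE, preset="tiny"), seed=1)
        dec = m.params["dec"]
        for pa in dec["pa"]:
            assert not pa["W_p"].any() and not pa["b_p"].any()
        for res in dec["res"]:
            assert not res["c2"]["w"].any()
        for ups in m.params["ups"]:
            assert not ups["ffn"]["w2"].any()

    def test_gradients_reach_every_component_after_one_step(self, random_episode):
        """After one optimizer step the zero-initialized projections become
        active and gradients flow to the mapper (W_Q, W_K, tau, registry),
        the upsampler (c, refine FFN), the PA projections and all three
        encoders, while the EMA twin receives none by construction."""
        from icseg.training import TrainConfig, train

        model = InContextSegmenter(ModelConfig(image_size=SIZE, preset="tiny"), seed=2)
        cfg = TrainConfig(steps=1, base_lr=1e-3, lr_halving_steps=(),
                          support_size=4, topk_schedule=((0, 5),),
                          val_every=10 ** 9, seed=0, augment=None)
        train(model, iter([random_episode]), cfg)

        def loss(params):
            probs, _ = model_forward(params, model.ema.shadow,
                                     random_episode.query_image,
                                     random_episode.support_images,
                                     random_episode.support_masks, base_top_k=5)
            return combined_loss(probs, random_episode.query_mask)

        g = grad(loss)(model.params)
        for path in [("mapper", "W_Q"), ("mapper", "W_K"), ("mapper", "tau"),
                     ("mapper", "registry")]:
            node = g
            for k in path:
                node = node[k]
            assert np.any(np.asarray(node) != 0), f"no gradient at {path}"
        for i in range(2):
            assert np.any(g["ups"][i]["u"] != 0)
            # the zero-initialized FFN output layer is the first to receive
            # gradient; the hidden layer activates once w2 becomes nonzero
            assert np.any(g["ups"][i]["ffn"]["w2"] != 0)
        for i in range(3):
            assert np.any(g["dec"]["pa"][i]["W_p"] != 0)
            assert np.any(g["dec"]["pa"][i]["b_p"] != 0)
        for enc in ("seg", "sup", "attn"):
            flat, _ = flatten(g[enc])
            assert np.any(flat != 0), f"no gradient reaches encoder {enc}"
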