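import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caencoder.encoder_vit import (EncoderConfig, SwitchNormState,
                                   attention_head, encode, init_encoder,
                                   mha_attention_weights, reduction_head,
                                   switch_norm, update_bn_state)
from _oracles import reduction_head_oracle

REDUCED = dict(n_blocks=2, n_heads=2, embed_dim=64, latent_dim=16)


class TestAttentionHead:
    def test_single_token_gets_unit_weight_and_value_row(self):
        X = np.array([[1.0, -2.0]])
        W = np.eye(2)
        O, alpha = attention_head(X, W, W, W)
        np.testing.assert_allclose(np.asarray(alpha), [[1.0]])
        np.testing.assert_allclose(np.asarray(O), X)

    def test_zero_query_weights_give_uniform_attention(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        O, alpha = attention_head(X, np.zeros((3, 3)), rng.normal(size=(3, 3)),
                                  rng.normal(size=(3, 3)))
        np.testing.assert_allclose(np.asarray(alpha), np.full((4, 4), 0.25),
                                   atol=1e-12)

    def test_score_gap_of_ln3_weights_keys_one_to_three(self):
        # tokens 0 and 1 in a 1-d key space: query row of token 1 scores
        # (0, ln 3) over the two keys -> softmax (0.25, 0.75)
        X = np.array([[0.0], [1.0]])
        O, alpha = attention_head(X, np.array([[1.0]]),
                                  np.array([[math.log(3.0)]]),
                                  np.array([[1.0]]))
        np.testing.assert_allclose(np.asarray(alpha)[1], [0.25, 0.75], atol=1e-12)

    def test_nonfinite_input_rejected(self):
        X = np.array([[np.nan, 0.0]])
        with pytest.raises(FloatingPointError):
            attention_head(X, np.eye(2), np.eye(2), np.eye(2))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=1, max_value=4),
           st.integers(min_value=1, max_value=6))
    def test_attention_rows_are_probability_vectors(self, seed, T, d):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(T, d))
        _, alpha = attention_head(X, rng.normal(size=(d, d)),
                                  rng.normal(size=(d, d)),
                                  rng.normal(size=(d, d)))
        alpha = np.asarray(alpha)
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)


class TestSwitchNorm:
    def _batch(self):
        return np.array([[1.0, 2.0, 3.0], [4.0, 0.0, -1.0]])

    @staticmethod
    def _bn(x):
        return (x - x.mean(0)) / np.sqrt(x.var(0) + 1e-5)

    @staticmethod
    def _ln(x):
        return (x - x.mean(-1, keepdims=True)) / np.sqrt(
            x.var(-1, keepdims=True) + 1e-5)

    def test_alpha_one_beta_zero_is_batch_norm(self):
        x = self._batch()
        out = switch_norm(x, SwitchNormState(alpha=1.0, beta=0.0), training=True)
        np.testing.assert_allclose(np.asarray(out), self._bn(x), atol=1e-6)

    def test_alpha_zero_beta_one_is_layer_norm(self):
        x = self._batch()
        out = switch_norm(x, SwitchNormState(alpha=0.0, beta=1.0), training=True)
        np.testing.assert_allclose(np.asarray(out), self._ln(x), atol=1e-6)

    def test_half_half_is_elementwise_mean_of_bn_and_ln(self):
        x = self._batch()
        out = switch_norm(x, SwitchNormState(alpha=0.5, beta=0.5), training=True)
        np.testing.assert_allclose(np.asarray(out),
                                   0.5 * self._bn(x) + 0.5 * self._ln(x),
                                   atol=1e-12)

    def test_inference_mode_uses_running_statistics(self):
        x = self._batch()
        state = SwitchNormState(alpha=1.0, beta=0.0,
                                running_mean=np.zeros(3), running_var=np.ones(3))
        out = switch_norm(x, state, training=False)
        np.testing.assert_allclose(np.asarray(out), x / np.sqrt(1 + 1e-5),
                                   atol=1e-9)

    def test_singleton_batch_in_training_falls_back_to_running_stats(self):
        state = SwitchNormState(alpha=1.0, beta=0.0,
                                running_mean=np.zeros(3), running_var=np.ones(3))
        x = np.array([[1.0, 2.0, 3.0]])
        out = switch_norm(x, state, training=True)
        assert np.all(np.isfinite(np.asarray(out)))


class TestReductionHead:
    def test_zero_parameters_give_zero_latent(self):
        head = [{"W": np.zeros((4, 3)), "b": np.zeros(3)},
                {"W": np.zeros((3, 3)), "b": np.zeros(3)},
                {"W": np.zeros((3, 2)), "b": np.zeros(2)}]
        np.testing.assert_array_equal(
            np.asarray(reduction_head(np.ones(4), head)), np.zeros(2))

    def test_leaky_slope_scales_negative_preactivations(self):
        head = [{"W": np.eye(2), "b": np.zeros(2)},
                {"W": np.eye(2), "b": np.zeros(2)},
                {"W": np.eye(2), "b": np.zeros(2)}]
        out = np.asarray(reduction_head(np.array([-1.0, 2.0]), head, slope=0.2))
        # two leaky layers then linear: -1 -> -0.2 -> -0.04
        np.testing.assert_allclose(out, [-0.04, 2.0])

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        head = [{"W": rng.normal(size=(5, 4)), "b": rng.normal(size=4)},
                {"W": rng.normal(size=(4, 3)), "b": rng.normal(size=3)},
                {"W": rng.normal(size=(3, 2)), "b": rng.normal(size=2)}]
        x = rng.normal(size=5)
        np.testing.assert_allclose(
            np.asarray(reduction_head(x, head, slope=0.2)),
            reduction_head_oracle(x, head, 0.2), atol=1e-6)


class TestEncode:
    def _state(self, dims=(7, 5, 4), seed=0, **over):
        cfg = EncoderConfig(**{**REDUCED, **over})
        state = init_encoder(cfg, list(dims), np.random.default_rng(seed))
        rng = np.random.default_rng(seed + 1)
        update_bn_state(state, rng.normal(size=(8, sum(dims))))
        return state, cfg

    def test_default_config_maps_to_256_dims(self):
        cfg = EncoderConfig()
        state = init_encoder(cfg, [6, 5], np.random.default_rng(0))
        z = encode(np.random.default_rng(1).normal(size=11), state, training=True)
        assert z.shape == (256,)

    def test_batched_encoding_matches_single_rows_in_inference(self):
        state, _ = self._state()
        X = np.random.default_rng(2).normal(size=(5, 16))
        Z = encode(X, state)
        # batch independence up to BLAS summation-order jitter
        for i in range(5):
            np.testing.assert_allclose(Z[i], encode(X[i], state),
                                       rtol=0, atol=1e-12)

    def test_inference_is_bitwise_deterministic(self):
        state, _ = self._state()
        x = np.random.default_rng(3).normal(size=16)
        assert encode(x, state).tobytes() == encode(x, state).tobytes()

    def test_dimension_mismatch_names_expected_layout(self):
        state, _ = self._state()
        with pytest.raises(ValueError, match=r"\[7, 5, 4\]"):
            encode(np.zeros(9), state)

    def test_small_perturbations_move_latents_continuously(self):
        state, _ = self._state()
        rng = np.random.default_rng(5)
        x = rng.normal(size=16)
        z = encode(x, state)
        delta = rng.normal(size=16)
        delta *= 1e-6 / np.linalg.norm(delta)
        assert np.linalg.norm(encode(x + delta, state) - z) < 1e-3

    def test_zero_blocks_reduce_to_projection_pool_head(self):
        state, cfg = self._state(n_blocks=0)
        x = np.random.default_rng(6).normal(size=16)
        parts = [x[:7], x[7:12], x[12:]]
        tokens = np.stack([p @ pr["W"] + pr["b"]
                           for p, pr in zip(parts, state.params["in_proj"])])
        expected = reduction_head(tokens.mean(axis=0), state.params["head"],
                                  cfg.leaky_slope)
        np.testing.assert_allclose(encode(x, state), np.asarray(expected),
                                   atol=1e-12)

    def test_chunked_token_scheme_runs_end_to_end(self):
        state, _ = self._state(token_scheme="chunked", n_tokens=4)
        z = encode(np.random.default_rng(7).normal(size=16), state)
        assert z.shape == (16,)


def test_multihead_rows_sum_to_one_across_configs():
    rng = np.random.default_rng(0)
    for n_heads in (1, 2, 4, 8):
        for T in (1, 2, 3, 4):
            D = 8 * n_heads
            attn = {"Wq": rng.normal(size=(D, D)), "Wk": rng.normal(size=(D, D))}
            X = rng.normal(size=(2, T, D))
            alpha = mha_attention_weights(attn, X, n_heads)
            np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)


def test_concatenated_head_outputs_span_embed_dim():
    cfg = EncoderConfig(**REDUCED)
    state = init_encoder(cfg, [5, 4], np.random.default_rng(0))
    blk = state.params["blocks"][0]["attn"]
    X = np.random.default_rng(1).normal(size=(3, 2, cfg.embed_dim))
    d_k = cfg.embed_dim // cfg.n_heads
    outs = []
    for h in range(cfg.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        O, _ = attention_head(X[0], blk["Wq"][:, sl], blk["Wk"][:, sl],
                              blk["Wv"][:, sl])
        outs.append(np.asarray(O))
    assert np.concatenate(outs, axis=-1).shape == (2, cfg.embed_dim)
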