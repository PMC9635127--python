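"""Forward operations against independent brute-force oracles, and exact
trainable-parameter accounting."""

import numpy as np
import pytest

from pssmformer import (
    ModelConfig,
    PSSMProfile,
    classifier_head,
    conv_block_forward,
    count_parameters,
    format_param_count,
    global_average_pool,
    init_weights,
    layer_norm,
    model_forward,
    multi_head_attention,
    scaled_dot_product_attention,
    transformer_encoder,
    weight_shapes,
)
from conftest import random_profile


# ---------------------------------------------------------------------------
# Independent oracles: elementwise translations of the defining equations.
# They share no code with the implementation.
# ---------------------------------------------------------------------------

def oracle_layer_norm(x, gamma, beta, eps):
    x = np.atleast_2d(np.asarray(x, float))
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        out[i] = [(v - mu) / np.sqrt(var + eps) * g + b
                  for v, g, b in zip(row, gamma, beta)]
    return out


def oracle_conv_same(x, w, b):
    L, c_in = x.shape
    c_out, _, k = w.shape
    pad = (k - 1) // 2
    y = np.zeros((L, c_out))
    for t in range(L):
        for o in range(c_out):
            acc = b[o]
            for j in range(k):
                src = t + j - pad
                if 0 <= src < L:
                    for i in range(c_in):
                        acc += x[src, i] * w[o, i, j]
            y[t, o] = acc
    return y


def oracle_attention(Q, K, V):
    l, dk = Q.shape
    out = np.zeros((l, V.shape[1]))
    for a in range(l):
        scores = np.array([sum(Q[a, m] * K[b, m] for m in range(dk)) / np.sqrt(dk)
                           for b in range(l)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for b in range(l):
            out[a] += w[b] * V[b]
    return out


def oracle_multi_head(Z, W):
    h = W["attn.wq"].shape[0]
    heads = []
    for i in range(h):
        Q = Z @ W["attn.wq"][i]
        K = Z @ W["attn.wk"][i]
        V = Z @ W["attn.wv"][i]
        heads.append(oracle_attention(Q, K, V))
    return np.hstack(heads) @ W["attn.wo"]


def oracle_encoder(Z, W, eps):
    mid = oracle_layer_norm(Z + oracle_multi_head(Z, W),
                            W["enc.ln1_gamma"], W["enc.ln1_beta"], eps)
    ffn = np.maximum(mid @ W["ffn.w1"] + W["ffn.b1"], 0) @ W["ffn.w2"] + W["ffn.b2"]
    return oracle_layer_norm(mid + ffn, W["enc.ln2_gamma"], W["enc.ln2_beta"], eps)


def _enc_weights(rng, d=20, h=5, d_ff=128):
    dk = d // h
    return {
        "attn.wq": rng.normal(size=(h, d, dk)),
        "attn.wk": rng.normal(size=(h, d, dk)),
        "attn.wv": rng.normal(size=(h, d, dk)),
        "attn.wo": rng.normal(size=(d, d)),
        "enc.ln1_gamma": rng.normal(size=d), "enc.ln1_beta": rng.normal(size=d),
        "ffn.w1": rng.normal(size=(d, d_ff)), "ffn.b1": rng.normal(size=d_ff),
        "ffn.w2": rng.normal(size=(d_ff, d)), "ffn.b2": rng.normal(size=d),
        "enc.ln2_gamma": rng.normal(size=d), "enc.ln2_beta": rng.normal(size=d),
    }


# ---------------------------------------------------------------------------
# layer norm
# ---------------------------------------------------------------------------

class TestLayerNorm:
    def test_constant_vector_collapses_to_beta(self):
        out = layer_norm(np.array([1.0, 1.0, 1.0]), np.ones(3), np.zeros(3))
        assert np.allclose(out, 0.0)

    def test_three_point_example(self):
        # population variance of [1,2,3] is 2/3 -> normalised +-sqrt(3/2)
        out = layer_norm(np.array([1.0, 2.0, 3.0]), np.ones(3), np.zeros(3), eps=0.0)
        assert np.allclose(out, [-1.22474487, 0.0, 1.22474487])

    def test_affine_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(7, 12))
        g, b = rng.normal(size=12), rng.normal(size=12)
        base = layer_norm(x, np.ones(12), np.zeros(12))
        assert np.allclose(layer_norm(x, g, b), base * g + b)

    def test_against_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(9, 20))
        g, b = rng.normal(size=20), rng.normal(size=20)
        assert np.allclose(layer_norm(x, g, b, 1e-5),
                           oracle_layer_norm(x, g, b, 1e-5), atol=1e-10)


# ---------------------------------------------------------------------------
# conv block
# ---------------------------------------------------------------------------

class TestConvBlock:
    def test_length_bookkeeping_from_minimum(self):
        """The shortest real profile (18 positions) survives three halvings."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig()
        W = init_weights(cfg, rng)
        x = rng.normal(size=(18, 20))
        lengths = []
        for b in range(3):
            x = conv_block_forward(x, W[f"conv{b}.weight"], W[f"conv{b}.bias"],
                                   W[f"conv{b}.ln_gamma"], W[f"conv{b}.ln_beta"])
            lengths.append(x.shape[0])
        assert lengths == [9, 4, 2]

    def test_zero_kernel_gives_zero_output(self):
        # conv output is the constant bias; layer norm of a constant is beta=0;
        # ReLU(0) = 0
        x = np.random.default_rng(1).normal(size=(10, 4))
        out = conv_block_forward(x, np.zeros((4, 4, 3)), np.full(4, 3.7),
                                 np.ones(4), np.zeros(4))
        assert np.allclose(out, 0.0)

    def test_against_sliding_window_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            L = int(rng.integers(4, 30))
            x = rng.normal(size=(L, 6))
            w = rng.normal(size=(5, 6, 3))
            b = rng.normal(size=5)
            g, beta = rng.normal(size=5), rng.normal(size=5)
            got = conv_block_forward(x, w, b, g, beta, pool_kernel=2, eps=1e-5)
            y = oracle_layer_norm(oracle_conv_same(x, w, b), g, beta, 1e-5)
            y = np.maximum(y, 0)
            exp = np.array([(y[2 * u] + y[2 * u + 1]) / 2 for u in range(L // 2)])
            assert np.allclose(got, exp, atol=1e-5)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            conv_block_forward(np.zeros((1, 4)), np.zeros((4, 4, 3)), np.zeros(4),
                               np.ones(4), np.zeros(4), pool_kernel=2)


# ---------------------------------------------------------------------------
# attention / encoder
# ---------------------------------------------------------------------------

class TestAttention:
    def test_single_position_returns_value(self):
        rng = np.random.default_rng(3)
        Q, K, V = (rng.normal(size=(1, 4)) for _ in range(3))
        assert np.allclose(scaled_dot_product_attention(Q, K, V), V)

    def test_identical_keys_average_values(self):
        rng = np.random.default_rng(4)
        Q = rng.normal(size=(6, 4))
        K = np.tile(rng.normal(size=(1, 4)), (6, 1))
        V = rng.normal(size=(6, 4))
        out = scaled_dot_product_attention(Q, K, V)
        assert np.allclose(out, np.tile(V.mean(axis=0), (6, 1)))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        Q, K = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        out = scaled_dot_product_attention(Q, K, np.eye(8))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_against_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        V = rng.normal(size=(3, 4))
        assert np.allclose(scaled_dot_product_attention(Q, K, V),
                           oracle_attention(Q, K, V), atol=1e-6)


class TestMultiHead:
    def test_output_shape(self):
        rng = np.random.default_rng(7)
        W = _enc_weights(rng)
        for l in (1, 2, 9):
            assert multi_head_attention(rng.normal(size=(l, 20)), W).shape == (l, 20)

    def test_single_head_reduction(self):
        rng = np.random.default_rng(8)
        W = _enc_weights(rng, d=6, h=1, d_ff=8)
        Z = rng.normal(size=(5, 6))
        direct = scaled_dot_product_attention(
            Z @ W["attn.wq"][0], Z @ W["attn.wk"][0], Z @ W["attn.wv"][0]
        ) @ W["attn.wo"]
        assert np.allclose(multi_head_attention(Z, W), direct, atol=1e-12)

    def test_against_head_by_head_oracle(self):
        rng = np.random.default_rng(9)
        W = _enc_weights(rng)
        Z = rng.normal(size=(5, 20))
        assert np.allclose(multi_head_attention(Z, W), oracle_multi_head(Z, W),
                           atol=1e-5)


class TestEncoder:
    def test_shape_preserved(self):
        rng = np.random.default_rng(10)
        W = _enc_weights(rng)
        Z = rng.normal(size=(7, 20))
        assert transformer_encoder(Z, W).shape == Z.shape

    def test_permutation_equivariance(self):
        """No positional encoding: permuting rows permutes outputs identically."""
        rng = np.random.default_rng(11)
        W = _enc_weights(rng)
        Z = rng.normal(size=(9, 20))
        perm = rng.permutation(9)
        assert np.allclose(transformer_encoder(Z[perm], W),
                           transformer_encoder(Z, W)[perm], atol=1e-10)

    def test_against_step_by_step_oracle(self):
        rng = np.random.default_rng(12)
        W = _enc_weights(rng)
        Z = rng.normal(size=(6, 20))
        assert np.allclose(transformer_encoder(Z, W, 1e-5),
                           oracle_encoder(Z, W, 1e-5), atol=1e-5)


# ---------------------------------------------------------------------------
# pooling / head / full forward
# ---------------------------------------------------------------------------

class TestPoolingAndHead:
    def test_gap_single_row_identity(self):
        row = np.arange(20.0).reshape(1, -1)
        assert np.allclose(global_average_pool(row), row[0])

    def test_gap_constant_rows(self):
        c = np.random.default_rng(13).normal(size=20)
        assert np.allclose(global_average_pool(np.tile(c, (14, 1))), c)

    def test_gap_matches_mean(self):
        x = np.random.default_rng(14).normal(size=(31, 20))
        assert np.allclose(global_average_pool(x), x.mean(axis=0), atol=1e-7)

    def test_zero_weights_give_half(self, default_config):
        W = {k: np.zeros(s) for k, s in weight_shapes(default_config).items()}
        assert classifier_head(np.ones(20), W, default_config) == 0.5

    def test_eval_mode_deterministic(self, default_config, default_weights):
        v = np.random.default_rng(15).normal(size=20)
        a = classifier_head(v, default_weights, default_config, training=False)
        b = classifier_head(v, default_weights, default_config, training=False)
        assert a == b

    def test_against_affine_oracle(self, default_config, default_weights):
        rng = np.random.default_rng(16)
        v = rng.normal(size=20)
        h = np.maximum(v @ default_weights["fc1.weight"] + default_weights["fc1.bias"], 0)
        z = h @ default_weights["fc2.weight"][:, 0] + default_weights["fc2.bias"][0]
        assert np.isclose(classifier_head(v, default_weights, default_config),
                          1 / (1 + np.exp(-z)), atol=1e-6)


class TestModelForward:
    def test_probability_range(self, default_config, default_weights):
        rng = np.random.default_rng(17)
        for length in (8, 18, 257):
            p = model_forward(random_profile(rng, length), default_config,
                              default_weights)
            assert 0.0 < p < 1.0

    def test_eval_deterministic(self, default_config, default_weights):
        prof = random_profile(np.random.default_rng(18), 50)
        assert model_forward(prof, default_config, default_weights) == model_forward(
            prof, default_config, default_weights
        )

    def test_short_profile_rejected_with_minimum(self, default_config, default_weights):
        prof = random_profile(np.random.default_rng(19), 7)
        with pytest.raises(ValueError, match="minimum 8"):
            model_forward(prof, default_config, default_weights)

    def test_very_long_profile_runs(self, default_config, default_weights):
        prof = random_profile(np.random.default_rng(20), 50_000)
        assert 0.0 < model_forward(prof, default_config, default_weights) < 1.0

    def test_ablation_flag_changes_only_encoder(self, default_config):
        cfg_off = ModelConfig(use_transformer=False)
        assert (count_parameters(default_config) - count_parameters(cfg_off)) == 6948


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

class TestParameterCount:
    def test_default_closed_form(self):
        conv = 3 * (20 * 20 * 3 + 20 + 2 * 20)
        enc = 3 * 20 * 20 + 20 * 20 + 2 * 2 * 20 + (20 * 128 + 128) + (128 * 20 + 20)
        head = (20 * 64 + 64) + (64 + 1)
        assert count_parameters(ModelConfig()) == conv + enc + head == 12137
        assert format_param_count(12137) == "12.1k"

    def test_published_ffn_width_series(self):
        sizes = {20: "7.7k", 32: "8.2k", 64: "9.5k", 80: "10.1k",
                 128: "12.1k", 200: "15.0k", 256: "17.3k"}
        for d_ff, expected in sizes.items():
            assert format_param_count(count_parameters(ModelConfig(d_ff=d_ff))) == expected

    def test_truncation_not_rounding(self):
        assert format_param_count(15089) == "15.0k"
        assert format_param_count(17385) == "17.3k"
        assert format_param_count(7709) == "7.7k"

    def test_degenerate_single_affine(self):
        cfg = ModelConfig(conv_blocks=0, use_transformer=False, fc_hidden=0)
        assert count_parameters(cfg) == 21

    def test_matches_enumerated_tensors_on_random_configs(self):
        """Exact equality with a brute-force count of constructed tensors."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            h = int(rng.choice([1, 2, 4, 5]))
            d = h * int(rng.integers(1, 8))
            blocks = int(rng.integers(0, 4))
            cfg = ModelConfig(
                in_channels=d if blocks == 0 else 20,
                conv_blocks=blocks,
                conv_channels=d,
                conv_kernel=int(rng.choice([1, 3, 5])),
                d_model=d,
                n_heads=h,
                d_ff=int(rng.integers(1, 200)),
                fc_hidden=int(rng.integers(0, 100)),
                use_transformer=bool(rng.integers(0, 2)),
            )
            W = init_weights(cfg, rng)
            assert count_parameters(cfg) == sum(w.size for w in W.values())
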