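"""Network components: positional encoding, attention (against independent
loop oracles), encoder blocks, parameter accounting."""

import numpy as np
import pytest

from mhcgt.autodiff import Tensor
from mhcgt.model import (
    EncoderBlock,
    ModelConfig,
    MultiHeadSelfAttention,
    build_model,
    closed_form_parameter_count,
    count_parameters,
    load_model,
    multi_head_self_attention,
    positional_encoding,
    save_model,
    scaled_dot_product_attention,
)

_LN_EPS = 1e-6


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(10, 4)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)  # sin 0
        np.testing.assert_allclose(pe[0, 1::2], 1.0)  # cos 0

    def test_univariate_reduces_to_sin(self):
        pe = positional_encoding(125, 1)
        assert pe.shape == (125, 1)
        assert pe[1, 0] == pytest.approx(0.841471, abs=1e-6)
        np.testing.assert_allclose(pe[:, 0], np.sin(np.arange(125)))

    def test_entries_bounded(self):
        pe = positional_encoding(50, 6)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)

    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            positional_encoding(0, 1)
        with pytest.raises(ValueError):
            positional_encoding(5, 0)


class TestScaledDotProductAttention:
    def test_zero_query_gives_uniform_weights(self, rng):
        S, d = 5, 3
        V = rng.normal(size=(S, d))
        out, w = scaled_dot_product_attention(np.zeros((S, d)), np.zeros((S, d)), V)
        np.testing.assert_allclose(w.numpy(), 1.0 / S)
        np.testing.assert_allclose(out.numpy(), np.tile(V.mean(axis=0), (S, 1)))

    def test_single_key(self):
        out, w = scaled_dot_product_attention([[1.0]], [[2.0]], [[7.0]])
        np.testing.assert_allclose(w.numpy(), [[1.0]])
        np.testing.assert_allclose(out.numpy(), [[7.0]])

    def test_two_step_hand_computation(self):
        # softmax([1, 0]) = (e/(e+1), 1/(e+1)) ≈ (0.7311, 0.2689)
        out, w = scaled_dot_product_attention(
            [[1.0], [0.0]], [[1.0], [0.0]], [[2.0], [4.0]]
        )
        e = np.e
        np.testing.assert_allclose(
            w.numpy()[0], [e / (e + 1), 1 / (e + 1)], atol=1e-6
        )
        assert out.numpy()[0, 0] == pytest.approx(
            (e / (e + 1)) * 2 + (1 / (e + 1)) * 4, abs=1e-4
        )
        assert out.numpy()[0, 0] == pytest.approx(2.5378, abs=1e-3)

    def test_shape_mismatch_names_operand(self):
        with pytest.raises(ValueError, match="operand K"):
            scaled_dot_product_attention(np.zeros((3, 2)), np.zeros((4, 2)),
                                         np.zeros((3, 2)))

    def test_weight_rows_are_probability_vectors(self, rng):
        for _ in range(100):
            S, d = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            q, k, v = rng.normal(size=(3, S, d)) * 3
            _, w = scaled_dot_product_attention(q, k, v)
            w = w.numpy()
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def _loop_mhsa_oracle(x: np.ndarray, attn: MultiHeadSelfAttention) -> np.ndarray:
    """Per-head scalar-loop reference, independent of the vectorized path."""
    S = x.shape[0]
    d = attn.key_dim
    heads = []
    for i in range(attn.num_heads):
        Q = x @ attn.w_q[i].numpy() + attn.b_q[i].numpy()
        K = x @ attn.w_k[i].numpy() + attn.b_k[i].numpy()
        V = x @ attn.w_v[i].numpy() + attn.b_v[i].numpy()
        scores = np.empty((S, S))
        for a in range(S):
            for b in range(S):
                scores[a, b] = float(Q[a] @ K[b]) / np.sqrt(d)
        A = np.empty_like(scores)
        for a in range(S):
            e = np.exp(scores[a] - scores[a].max())
            A[a] = e / e.sum()
        out = np.zeros((S, d))
        for a in range(S):
            for b in range(S):
                out[a] += A[a, b] * V[b]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ attn.w_o.numpy() + attn.b_o.numpy()


class TestMultiHeadSelfAttention:
    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            S = int(rng.integers(2, 9))
            d = int(rng.integers(1, 9))
            m = int(rng.integers(1, 4))
            n = int(rng.integers(1, 5))
            attn = MultiHeadSelfAttention(n, m, d, rng)
            x = rng.normal(size=(S, m))
            vec = multi_head_self_attention(x, attn).numpy()
            np.testing.assert_allclose(vec, _loop_mhsa_oracle(x, attn), atol=1e-5)

    def test_zero_projections_give_zero_output(self, rng):
        attn = MultiHeadSelfAttention(3, 2, 4, rng)
        for p in attn.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(6, 2))
        np.testing.assert_allclose(attn(x).numpy(), 0.0)

    def test_single_head_equals_one_sdpa_plus_projection(self, rng):
        attn = MultiHeadSelfAttention(1, 2, 5, rng)
        x = rng.normal(size=(4, 2))
        q = x @ attn.w_q[0].numpy() + attn.b_q[0].numpy()
        k = x @ attn.w_k[0].numpy() + attn.b_k[0].numpy()
        v = x @ attn.w_v[0].numpy() + attn.b_v[0].numpy()
        head, _ = scaled_dot_product_attention(q, k, v)
        expected = head.numpy() @ attn.w_o.numpy() + attn.b_o.numpy()
        np.testing.assert_allclose(attn(x).numpy(), expected, atol=1e-12)

    def test_width_mismatch_rejected(self, rng):
        attn = MultiHeadSelfAttention(2, 3, 4, rng)
        with pytest.raises(ValueError, match="num_vars"):
            attn(np.zeros((5, 2)))


def _loop_encoder_oracle(x: np.ndarray, block: EncoderBlock) -> np.ndarray:
    """Scalar step-by-step evaluation of the pre-norm block (M arbitrary)."""

    def ln(v, gamma, beta):
        mu = v.mean()
        var = ((v - mu) ** 2).mean()
        return (v - mu) / np.sqrt(var + _LN_EPS) * gamma + beta

    S, m = x.shape
    g1, b1 = block.ln1.gamma.numpy(), block.ln1.beta.numpy()
    normed = np.array([ln(x[s], g1, b1) for s in range(S)])
    attn_out = _loop_mhsa_oracle(normed, block.attn)
    y = x + attn_out
    g2, b2 = block.ln2.gamma.numpy(), block.ln2.beta.numpy()
    normed2 = np.array([ln(y[s], g2, b2) for s in range(S)])
    h = np.maximum(normed2 @ block.w_ff1.numpy() + block.b_ff1.numpy(), 0.0)
    return y + h @ block.w_ff2.numpy() + block.b_ff2.numpy()


class TestEncoderBlock:
    def test_zero_sublayers_pass_input_through(self, rng):
        cfg = ModelConfig(num_heads=2, key_dim=3, ff_dim=4, num_blocks=1,
                          seq_len=5, num_vars=2)
        block = EncoderBlock(cfg, rng)
        for p in block.attn.parameters() + [block.w_ff1, block.b_ff1,
                                            block.w_ff2, block.b_ff2]:
            p.data[...] = 0.0
        x = rng.normal(size=(5, 2))
        np.testing.assert_allclose(block(x).numpy(), x, atol=1e-12)

    @pytest.mark.parametrize("m", [1, 3])
    def test_shape_preserved(self, rng, m):
        cfg = ModelConfig(num_heads=2, key_dim=4, ff_dim=6, seq_len=7, num_vars=m)
        block = EncoderBlock(cfg, rng)
        x = rng.normal(size=(3, 7, m))
        assert block(x).shape == (3, 7, m)

    @pytest.mark.parametrize("m", [1, 2])
    def test_matches_scalar_loop_oracle(self, rng, m):
        cfg = ModelConfig(num_heads=2, key_dim=3, ff_dim=4, seq_len=4, num_vars=m)
        block = EncoderBlock(cfg, rng)
        x = rng.normal(size=(4, m)) * 0.5
        out = block(x, fast=False).numpy()
        np.testing.assert_allclose(out, _loop_encoder_oracle(x, block), atol=1e-5)

    def test_univariate_fast_path_equals_general_path(self, rng):
        cfg = ModelConfig(num_heads=3, key_dim=5, ff_dim=6, seq_len=9, num_vars=1)
        block = EncoderBlock(cfg, rng)
        # make the LN biases non-trivial so the shortcut carries real signal
        block.ln1.beta.data[...] = 0.7
        block.ln2.beta.data[...] = -0.4
        x = rng.normal(size=(2, 9, 1))
        fast = block(x, fast=True).numpy()
        general = block(x, fast=False).numpy()
        np.testing.assert_allclose(fast, general, atol=1e-10)
        # with dropout active the two paths consume the rng identically
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        fast_d = block(x, dropout_active=True, rng=r1, fast=True).numpy()
        gen_d = block(x, dropout_active=True, rng=r2, fast=False).numpy()
        np.testing.assert_allclose(fast_d, gen_d, atol=1e-10)

    def test_nonfinite_input_rejected(self, rng):
        cfg = ModelConfig(num_heads=1, key_dim=2, ff_dim=2, seq_len=3, num_vars=1)
        block = EncoderBlock(cfg, rng)
        x = np.zeros((3, 1))
        x[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            block(x)


class TestPermutationEquivariance:
    def test_encoder_is_equivariant_without_positional_encoding(self):
        cfg = ModelConfig(num_heads=2, key_dim=4, ff_dim=5, num_blocks=2,
                          seq_len=6, num_vars=3)
        model = build_model(cfg, seed=5)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 6, 3))
        perm = np.array([3, 0, 5, 1, 4, 2])
        out = model.encode(x, add_positional=False).numpy()
        out_perm = model.encode(x[:, perm, :], add_positional=False).numpy()
        np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-8)

    def test_positional_encoding_breaks_equivariance(self):
        cfg = ModelConfig(num_heads=2, key_dim=4, ff_dim=5, num_blocks=2,
                          seq_len=6, num_vars=3)
        model = build_model(cfg, seed=5)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 6, 3))
        perm = np.array([3, 0, 5, 1, 4, 2])
        out = model.encode(x, add_positional=True).numpy()
        out_perm = model.encode(x[:, perm, :], add_positional=True).numpy()
        assert np.abs(out_perm - out[:, perm, :]).max() > 1e-3


class TestFullModel:
    def test_probabilities_normalized(self, rng):
        model = build_model(seed=0)
        p = model.predict_proba(rng.uniform(0, 1, (4, 125, 1)))
        assert p.shape == (4, 7)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_forward_deterministic_without_dropout(self, rng):
        model = build_model(seed=0)
        x = rng.uniform(0, 1, (2, 125, 1))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_single_sample_forward(self, rng):
        model = build_model(seed=0)
        p = model.predict_proba(rng.uniform(0, 1, (125, 1)))
        assert p.shape == (7,)

    def test_wrong_input_shape_rejected(self, rng):
        model = build_model(seed=0)
        with pytest.raises(ValueError, match="does not match"):
            model.forward(rng.uniform(0, 1, (2, 99, 1)))

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = build_model(ModelConfig(num_blocks=1), seed=3)
        x = rng.uniform(0, 1, (3, 125, 1))
        save_model(model, str(tmp_path / "ckpt"))
        back = load_model(str(tmp_path / "ckpt"))
        np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))


class TestParameterCounting:
    def test_default_model_has_published_count(self):
        cfg = ModelConfig()
        model = build_model(cfg, seed=0)
        assert count_parameters(model) == 74_768
        assert closed_form_parameter_count(cfg) == 74_768

    def test_head_only_count(self):
        cfg = ModelConfig(num_blocks=0)
        assert closed_form_parameter_count(cfg) == 16_632  # 125·125+125+125·7+7
        assert count_parameters(build_model(cfg, seed=0)) == 16_632

    def test_positional_encoding_not_trainable(self):
        model = build_model(seed=0)
        sizes = sum(p.size for p in model.parameters())
        assert model.pe.size not in ()  # pe exists ...
        assert sizes == count_parameters(model)  # ... but is not counted
        assert not isinstance(model.pe, Tensor)  # fixed array, no gradient

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_built_count_random_configs(self, seed):
        r = np.random.default_rng(seed)
        cfg = ModelConfig(
            num_heads=int(r.integers(1, 6)),
            key_dim=int(r.integers(1, 40)),
            ff_dim=int(r.integers(1, 40)),
            num_blocks=int(r.integers(0, 5)),
            mlp_units=int(r.integers(1, 60)),
            num_classes=int(r.integers(2, 9)),
            seq_len=int(r.integers(4, 40)),
            num_vars=int(r.integers(1, 4)),
        )
        assert count_parameters(build_model(cfg, seed=0)) == \
            closed_form_parameter_count(cfg)
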