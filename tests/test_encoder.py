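"""Attention encoder: oracle equivalence, range bounds, gradients, contracts."""

import numpy as np
import pytest

from longnote.autograd import Tensor
from longnote.encoder import (EncoderConfig, EncoderParams, attention_weights,
                              classify_cls, embed_input, encode_batch,
                              encode_segment, encoder_layer, load_checkpoint,
                              prepare_segment_ids, save_checkpoint)
from longnote.nn import CLS_ID, ID_OFFSET, cross_entropy


# ----------------------------------------------------------------------
# brute-force oracle: explicit double loop over positions, straight from
# the layer definition (attention-pool, linear map, tanh)
# ----------------------------------------------------------------------

def oracle_layer(V, W, Wp, scale):
    n, D = V.shape
    out = np.zeros_like(V)
    for i in range(n):
        scores = np.array([scale * V[i] @ Wp @ V[t] for t in range(n)])
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        pooled = sum(alpha[t] * V[t] for t in range(n))
        out[i] = np.tanh(W @ pooled)
    return out


def oracle_encode(token_ids, params, config):
    x = params.token_embeddings[np.concatenate([[CLS_ID], token_ids])]
    x = x + params.positional[: len(token_ids) + 1]
    for W, Wp in zip(params.W, params.W_prime):
        x = oracle_layer(x, W, Wp, config.scale_factor)
    return x


def random_instance(rng, n_max=8, d_max=16, l_max=3):
    n = int(rng.integers(1, n_max + 1))
    D = int(rng.integers(2, d_max + 1))
    L = int(rng.integers(0, l_max + 1))
    config = EncoderConfig(layers=L, dim=D, window=n + 1, vocab_size=30)
    params = EncoderParams.init(config, int(rng.integers(1 << 30)))
    ids = rng.integers(ID_OFFSET, 30, size=n)
    return ids, params, config


def test_encoder_matches_brute_force_oracle_on_100_instances():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        ids, params, config = random_instance(rng)
        enc = encode_segment(ids, params, config)
        ref = oracle_encode(ids, params, config)
        np.testing.assert_allclose(enc.top_vectors, ref, atol=1e-6)
        np.testing.assert_allclose(enc.cls, ref[0], atol=1e-6)


def test_attention_weights_normalize_and_match_oracle():
    rng = np.random.default_rng(5)
    V = rng.normal(size=(6, 8))
    Wp = rng.normal(size=(8, 8))
    scale = 1.0 / np.sqrt(8)
    for i in range(6):
        alpha = attention_weights(i, V, Wp, scale)
        scores = np.array([scale * V[i] @ Wp @ V[t] for t in range(6)])
        ref = np.exp(scores - scores.max())
        ref /= ref.sum()
        np.testing.assert_allclose(alpha, ref, atol=1e-6)
        assert alpha.sum() == pytest.approx(1.0)
        assert (alpha > 0).all()


def test_attention_uniform_for_identical_vectors_and_singleton():
    V = np.tile(np.array([1.0, -2.0, 0.5]), (4, 1))
    alpha = attention_weights(0, V, np.eye(3), 1.0)
    np.testing.assert_allclose(alpha, 0.25)
    single = attention_weights(0, V[:1], np.eye(3), 1.0)
    np.testing.assert_allclose(single, [1.0])


def test_layer_zero_weight_and_tanh_range():
    rng = np.random.default_rng(7)
    V = rng.normal(size=(5, 4))
    out = encoder_layer(V, np.zeros((4, 4)), rng.normal(size=(4, 4)), 0.5)
    np.testing.assert_allclose(out, 0.0)
    out = encoder_layer(V, rng.normal(size=(4, 4)), rng.normal(size=(4, 4)), 0.5)
    assert np.abs(out).max() < 1.0


class TestEmbedInput:
    def test_zero_parameters_give_zero_sequence(self):
        config = EncoderConfig(layers=0, dim=4, window=8, vocab_size=10)
        params = EncoderParams.init(config, 0)
        params.token_embeddings[:] = 0.0
        params.positional[:] = 0.0
        out = embed_input([3, 4], params, config)
        np.testing.assert_allclose(out, 0.0)
        assert out.shape == (3, 4)  # CLS + two tokens

    def test_window_accounting_reserves_cls_slot(self):
        config = EncoderConfig(layers=0, dim=4, window=512, vocab_size=600)
        params = EncoderParams.init(config, 0)
        embed_input(np.arange(2, 513), params, config)  # 511 tokens fit
        with pytest.raises(ValueError, match="exceeds window"):
            embed_input(np.arange(2, 514), params, config)

    def test_positions_distinguish_repeated_ids(self):
        config = EncoderConfig(layers=0, dim=4, window=8, vocab_size=10)
        params = EncoderParams.init(config, 3)
        out = embed_input([5, 5], params, config)
        assert not np.allclose(out[1], out[2])


class TestEncodeSegment:
    def test_zero_layers_is_identity_on_embeddings(self):
        config = EncoderConfig(layers=0, dim=4, window=8, vocab_size=10)
        params = EncoderParams.init(config, 1)
        enc = encode_segment([3, 4], params, config)
        np.testing.assert_array_equal(enc.top_vectors,
                                      embed_input([3, 4], params, config))

    def test_deterministic_bitwise(self):
        config = EncoderConfig(layers=2, dim=8, window=16, vocab_size=20)
        params = EncoderParams.init(config, 1)
        a = encode_segment([3, 4, 5], params, config)
        b = encode_segment([3, 4, 5], params, config)
        np.testing.assert_array_equal(a.top_vectors, b.top_vectors)

    def test_outputs_strictly_inside_unit_box(self):
        config = EncoderConfig(layers=3, dim=8, window=16, vocab_size=20)
        params = EncoderParams.init(config, 2)
        enc = encode_segment(np.arange(2, 12), params, config)
        assert np.abs(enc.top_vectors).max() < 1.0

    def test_permutation_equivariance_without_positions(self):
        config = EncoderConfig(layers=2, dim=8, window=16, vocab_size=40)
        params = EncoderParams.init(config, 4)
        params.positional[:] = 0.0
        ids = np.array([5, 9, 13, 21])
        perm = np.array([2, 0, 3, 1])
        enc = encode_segment(ids, params, config)
        enc_p = encode_segment(ids[perm], params, config)
        # content outputs permute with the inputs; CLS output unchanged
        np.testing.assert_allclose(enc_p.top_vectors[1:], enc.top_vectors[1:][perm],
                                   atol=1e-10)
        np.testing.assert_allclose(enc_p.cls, enc.cls, atol=1e-10)


class TestClassifyCls:
    def test_tie_breaks_toward_label_zero(self):
        W1 = np.ones((2, 3))
        label, score = classify_cls(np.array([0.2, 0.1, -0.3]), W1)
        assert label == 0
        np.testing.assert_allclose(score, [0.5, 0.5])

    def test_argmax_arithmetic(self):
        W1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        label, _ = classify_cls(np.array([0.3, 0.9]), W1)
        assert label == 1

    def test_negating_readout_flips_untied_label(self):
        rng = np.random.default_rng(0)
        W1 = rng.normal(size=(2, 4))
        v = rng.normal(size=4)
        l1, _ = classify_cls(v, W1)
        l2, _ = classify_cls(v, -W1)
        assert l1 != l2


def test_batched_training_path_agrees_with_reference_path():
    config = EncoderConfig(layers=2, dim=8, window=16, vocab_size=30)
    params = EncoderParams.init(config, 9)
    tensors = {k: Tensor(v) for k, v in params.arrays().items() if k != "W1"}
    raw = [np.array([1, 2, 3, 4, 5]), np.array([7, 8])]  # raw vocab ids
    ids, lengths = prepare_segment_ids(raw, config)
    top = encode_batch(ids, lengths, tensors, config)
    for b, seq in enumerate(raw):
        ref = encode_segment(seq + ID_OFFSET, params, config)
        np.testing.assert_allclose(top.data[b, : len(seq) + 1], ref.top_vectors,
                                   atol=1e-10)


def test_full_stack_analytic_gradients_match_numeric():
    config = EncoderConfig(layers=2, dim=4, window=8, vocab_size=12)
    params = EncoderParams.init(config, 11)
    ids, lengths = prepare_segment_ids([np.array([1, 2, 3]), np.array([4])], config)
    y = np.array([1, 0])

    def loss_given(name, flat):
        arrays = {k: v.copy() for k, v in params.arrays().items()}
        arrays[name] = flat.reshape(arrays[name].shape)
        tensors = {k: Tensor(v) for k, v in arrays.items() if k != "W1"}
        top = encode_batch(ids, lengths, tensors, config)
        logits = top[:, 0, :] @ Tensor(arrays["W1"].T)
        return float(cross_entropy(logits, y).data)

    tensors = {k: Tensor(v, requires_grad=True)
               for k, v in params.arrays().items() if k != "W1"}
    top = encode_batch(ids, lengths, tensors, config)
    logits = top[:, 0, :] @ Tensor(params.W1.T)
    cross_entropy(logits, y).backward()

    eps = 1e-6
    for name in ("W_0", "W_prime_1", "positional"):
        base = params.arrays()[name].ravel().copy()
        analytic = tensors[name].grad.ravel()
        # probe a deterministic subset of coordinates
        for j in range(0, len(base), max(1, len(base) // 10)):
            xp, xm = base.copy(), base.copy()
            xp[j] += eps
            xm[j] -= eps
            num = (loss_given(name, xp) - loss_given(name, xm)) / (2 * eps)
            assert analytic[j] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_standard_block_mode_differs_and_stays_finite():
    config = EncoderConfig(layers=2, dim=8, window=16, vocab_size=30,
                           block="standard")
    params = EncoderParams.init(config, 13)
    enc = encode_segment([3, 4, 5], params, config)
    assert np.isfinite(enc.top_vectors).all()
    ref = encode_segment([3, 4, 5], params,
                         EncoderConfig(layers=2, dim=8, window=16, vocab_size=30))
    assert not np.allclose(enc.top_vectors, ref.top_vectors)


def test_checkpoint_roundtrip(tmp_path):
    config = EncoderConfig(layers=2, dim=8, window=16, vocab_size=30)
    params = EncoderParams.init(config, 17)
    save_checkpoint(tmp_path / "ckpt", params, config)
    loaded, cfg2 = load_checkpoint(tmp_path / "ckpt")
    assert cfg2 == config
    np.testing.assert_array_equal(loaded.W[1], params.W[1])
    np.testing.assert_array_equal(loaded.token_embeddings, params.token_embeddings)
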