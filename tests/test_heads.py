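"""Segment-combination heads: pooling algebra, order sensitivity, training."""

import numpy as np
import pytest

from longnote import evaluation, synth, textprep
from longnote.autograd import Tensor
from longnote.encoder import EncoderConfig, EncoderParams, SegmentEncoding, encode_segment
from longnote.heads import (EncoderDocClassifier, HeadConfig, combine_segments,
                            pad_or_truncate, predict_document)
from longnote.nn import LSTM

from conftest import run_doc_experiment


def enc_of(cls_vec, n_pos=3):
    top = np.tile(np.asarray(cls_vec, dtype=float), (n_pos, 1))
    return SegmentEncoding(top_vectors=top, cls=top[0])


class TestHeadConfig:
    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(strategy="sum_cls")

    @pytest.mark.parametrize("strategy", ["lstm_top", "concat_top"])
    def test_full_position_heads_require_frozen_encoder(self, strategy):
        with pytest.raises(ValueError, match="freeze"):
            HeadConfig(strategy=strategy, freeze_encoder=False)
        HeadConfig(strategy=strategy, freeze_encoder=True)
        HeadConfig(strategy=strategy, relax_freeze_requirement=True)


class TestCombine:
    def test_mean_of_identical_cls_vectors_is_identity(self):
        v = np.array([0.3, -0.7])
        rep = combine_segments([enc_of(v)] * 3, HeadConfig(strategy="mean_cls"))
        np.testing.assert_allclose(rep.v_d, v)
        assert rep.segments_consumed == 3

    def test_concat_cls_dimension_and_order(self):
        encs = [enc_of([i, i, i, i]) for i in (1.0, 2.0, 3.0)]
        rep = combine_segments(encs, HeadConfig(strategy="concat_cls", max_segments=3))
        assert rep.v_d.shape == (12,)
        np.testing.assert_allclose(rep.v_d[:4], 1.0)
        np.testing.assert_allclose(rep.v_d[8:], 3.0)

    def test_min_max_elementwise(self):
        encs = [enc_of([1.0, -2.0]), enc_of([0.0, 5.0])]
        mn = combine_segments(encs, HeadConfig(strategy="min_cls"))
        mx = combine_segments(encs, HeadConfig(strategy="max_cls"))
        np.testing.assert_allclose(mn.v_d, [0.0, -2.0])
        np.testing.assert_allclose(mx.v_d, [1.0, 5.0])

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            combine_segments([], HeadConfig(strategy="mean_cls"))

    def test_min_mean_max_pooling_order(self):
        rng = np.random.default_rng(0)
        encs = [enc_of(rng.normal(size=6)) for _ in range(4)]
        cfg = lambda s: HeadConfig(strategy=s)
        mn = combine_segments(encs, cfg("min_cls")).v_d
        me = combine_segments(encs, cfg("mean_cls")).v_d
        mx = combine_segments(encs, cfg("max_cls")).v_d
        assert (mn <= me + 1e-12).all() and (me <= mx + 1e-12).all()

    def test_pooling_is_permutation_invariant_lstm_and_concat_are_not(self):
        rng = np.random.default_rng(1)
        encs = [enc_of(rng.normal(size=4)) for _ in range(3)]
        rev = encs[::-1]
        for s in ("mean_cls", "min_cls", "max_cls"):
            a = combine_segments(encs, HeadConfig(strategy=s)).v_d
            b = combine_segments(rev, HeadConfig(strategy=s)).v_d
            np.testing.assert_allclose(a, b)
        cc = HeadConfig(strategy="concat_cls", max_segments=3)
        assert not np.allclose(combine_segments(encs, cc).v_d,
                               combine_segments(rev, cc).v_d)
        lstm = LSTM(4, 5, np.random.default_rng(2))
        lc = HeadConfig(strategy="lstm_cls")
        assert not np.allclose(
            combine_segments(encs, lc, lstm=lstm).v_d,
            combine_segments(rev, lc, lstm=lstm).v_d)

    def test_lstm_top_consumes_all_positions_in_order(self):
        rng = np.random.default_rng(3)
        encs = [SegmentEncoding(top_vectors=rng.normal(size=(3, 4)),
                                cls=np.zeros(4)) for _ in range(2)]
        for e in encs:
            e.cls = e.top_vectors[0]
        lstm = LSTM(4, 5, np.random.default_rng(4))
        cfg = HeadConfig(strategy="lstm_top", freeze_encoder=True)
        rep = combine_segments(encs, cfg, lstm=lstm)
        flat = np.concatenate([e.top_vectors for e in encs], axis=0)
        direct = lstm(Tensor(flat[None]), lengths=np.array([6])).data[0]
        np.testing.assert_allclose(rep.v_d, direct)

    def test_single_segment_pooled_strategies_coincide(self):
        rng = np.random.default_rng(5)
        e = enc_of(rng.normal(size=4))
        reps = [combine_segments([e], HeadConfig(strategy=s)).v_d
                for s in ("mean_cls", "min_cls", "max_cls")]
        np.testing.assert_allclose(reps[0], reps[1])
        np.testing.assert_allclose(reps[0], reps[2])
        cc = combine_segments([e], HeadConfig(strategy="concat_cls",
                                              max_segments=1)).v_d
        np.testing.assert_allclose(cc, reps[0])


class TestPadOrTruncate:
    def test_pads_with_zero_encodings(self):
        encs = [enc_of([1.0, 2.0])] * 2
        out = pad_or_truncate(encs, 4)
        assert len(out) == 4
        np.testing.assert_allclose(out[3].cls, 0.0)
        np.testing.assert_allclose(out[0].cls, [1.0, 2.0])

    def test_truncates_trailing(self):
        encs = [enc_of([float(i)]) for i in range(6)]
        out = pad_or_truncate(encs, 4)
        assert [e.cls[0] for e in out] == [0.0, 1.0, 2.0, 3.0]

    def test_exact_length_unchanged(self):
        encs = [enc_of([1.0])] * 4
        assert pad_or_truncate(encs, 4) is not encs
        assert len(pad_or_truncate(encs, 4)) == 4


@pytest.mark.parametrize("strategy", ["mean_cls", "min_cls", "max_cls",
                                      "concat_cls", "lstm_cls"])
def test_classifier_determinism_per_seed(strategy):
    rng = np.random.default_rng(8)
    X = [rng.integers(0, 20, size=rng.integers(5, 40)) for _ in range(30)]
    y = (rng.random(30) < 0.5).astype(int)
    cfg = EncoderConfig(layers=1, dim=8, window=16, vocab_size=22)
    losses = []
    for _ in range(2):
        model = EncoderDocClassifier(cfg, HeadConfig(strategy=strategy,
                                                     max_segments=3,
                                                     hidden_size=8), seed=4)
        r = np.random.default_rng(9)
        losses.append([model.train_epoch(X, y, r) for _ in range(2)])
    assert losses[0] == losses[1]


def test_single_segment_document_score_uses_plain_cls_vector():
    """For a one-segment document, mean pooling is the identity, so the
    model's score is the head classifier applied to the segment's CLS."""
    cfg = EncoderConfig(layers=2, dim=8, window=16, vocab_size=30)
    model = EncoderDocClassifier(cfg, HeadConfig(strategy="mean_cls",
                                                 max_segments=4), seed=6)
    ids = np.array([1, 2, 3])
    p = predict_document(ids, model)
    from longnote.nn import ID_OFFSET
    enc = encode_segment(ids + ID_OFFSET,
                         _params_from(model), cfg)
    logits = enc.cls @ model.classifier.W.data + model.classifier.b.data
    z = np.exp(logits - logits.max())
    assert p == pytest.approx(float(z[1] / z.sum()), abs=1e-12)


def _params_from(model):
    params = model.encoder_params
    # training tensors share storage with the parameter arrays
    for k, t in model.enc_tensors.items():
        assert t.data is params.arrays()[k]
    return params


def test_frozen_encoder_parameters_bitwise_unchanged_by_training():
    rng = np.random.default_rng(10)
    X = [rng.integers(0, 20, size=rng.integers(5, 50)) for _ in range(40)]
    y = (rng.random(40) < 0.5).astype(int)
    cfg = EncoderConfig(layers=2, dim=8, window=16, vocab_size=22)
    model = EncoderDocClassifier(cfg, HeadConfig(strategy="lstm_cls",
                                                 hidden_size=8,
                                                 freeze_encoder=True), seed=7)
    before = {k: t.data.copy() for k, t in model.enc_tensors.items()}
    head_before = model.classifier.W.data.copy()
    r = np.random.default_rng(11)
    for _ in range(3):
        model.train_epoch(X, y, r)
    for k, t in model.enc_tensors.items():
        np.testing.assert_array_equal(t.data, before[k])
    assert not np.array_equal(model.classifier.W.data, head_before)


def test_lstm_head_recovers_signal_confined_to_a_later_segment():
    """When the discriminative tokens live only in the third window, a
    recurrent head over all segments learns the label while a model that
    reads only the first window stays near chance."""
    cfg = synth.GeneratorConfig(n_docs=800, vocab_size=300, mean_length=224.0,
                                length_sigma=0.1, prevalence=0.4, beta=2.5,
                                placement="segment_k", segment_k=2, window=64,
                                n_signal_tokens=3, base_rate=0.5, seed=21)
    corpus = synth.generate_corpus(cfg)
    full, _ = run_doc_experiment(corpus, "lstm_cls", seed=21, max_segments=6)
    head_only, _ = run_doc_experiment(
        corpus, "mean_cls", seed=21, max_segments=1,
        transform=lambda ids: textprep.take_head(ids, 63).token_ids)
    assert full.test_roc.auc >= 0.85
    assert head_only.test_roc.auc <= 0.65
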