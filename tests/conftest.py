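"""Shared fixtures and experiment plumbing for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from longnote import evaluation, heads, textprep
from longnote.encoder import EncoderConfig

# property tests run derandomized so every invocation checks the same cases
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_docs(texts, labels=None, groups=None):
    labels = labels or [None] * len(texts)
    groups = groups or [f"g{i}" for i in range(len(texts))]
    return [textprep.Document(doc_id=f"d{i}", group_id=g, text=t, label=y)
            for i, (t, y, g) in enumerate(zip(texts, labels, groups))]


@pytest.fixture
def tiny_corpus():
    """Six short documents with reused words, for vocabulary tests."""
    texts = ["alpha beta gamma", "alpha beta", "alpha delta", "beta gamma",
             "alpha beta gamma delta", "gamma gamma beta"]
    return make_docs(texts)


def planted_corpus(n_docs: int, seed: int, signal_word: str = "marker",
                   doc_len: int = 20, vocab: int = 30):
    """Documents where one token perfectly determines the label."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n_docs):
        label = int(rng.random() < 0.5)
        toks = [f"w{rng.integers(vocab)}" for _ in range(doc_len)]
        if label:
            toks[rng.integers(doc_len)] = signal_word
        X.append(" ".join(toks))
        y.append(label)
    return make_docs(X, labels=y), np.array(y)


def run_doc_experiment(corpus, strategy: str, seed: int, window: int = 64,
                       max_segments: int = 6, lr: float = 3e-3,
                       transform=None, epochs: int = 5,
                       freeze: bool = False, hidden: int = 32):
    """Split / oversample / train an encoder document model; return result.

    ``transform(ids)`` optionally maps each document's token-id array
    (e.g. to its head or tail window) before training.
    """
    docs = corpus.documents
    tr, val, te = evaluation.split(docs, evaluation.SplitSpec(seed=seed))
    vocab = textprep.build_vocabulary(tr, min_doc_freq=2, n_max=1)
    y = lambda p: np.array([d.label for d in p])
    tr_docs, tr_y = evaluation.oversample_minority(tr, y(tr), seed=seed)

    def enc(part):
        out = textprep.encode_documents(part, vocab)
        if transform is not None:
            out = [transform(ids) for ids in out]
        return out

    enc_cfg = EncoderConfig(layers=2, dim=32, window=window,
                            vocab_size=len(vocab) + 2)
    head_cfg = heads.HeadConfig(strategy=strategy, max_segments=max_segments,
                                hidden_size=hidden, freeze_encoder=freeze)
    model = heads.EncoderDocClassifier(enc_cfg, head_cfg, seed=seed, lr=lr)
    result = evaluation.train_model(model, (enc(tr_docs), tr_y),
                                    (enc(val), y(val)), (enc(te), y(te)),
                                    evaluation.TrainConfig(epochs=epochs, seed=seed))
    return result, model
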