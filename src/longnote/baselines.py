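"""Bag-of-words with logistic regression, and the neural sequence baselines.

The bag-of-words model counts unigram occurrences over the vocabulary
(word order discarded, no stemming, no stopword removal, no weighting)
and fits a logistic regression on the counts.  The neural baselines are
a multi-width convolutional classifier (embeddings, parallel
convolutions of widths 3/4/5, max-over-time pooling, dropout, linear
readout) and a GRU classifier (embeddings, recurrent pass, final-state
readout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .autograd import Tensor, relu
from .nn import (GRU, Adam, Embedding, Linear, cross_entropy, dropout,
                 pad_batch, positive_proba)
from .textprep import Document, Vocabulary

__all__ = [
    "BowVector",
    "LinearModel",
    "bow_featurize",
    "bow_matrix",
    "train_logistic",
    "ConvClassifierConfig",
    "RecurrentClassifierConfig",
    "ConvTextClassifier",
    "RecurrentTextClassifier",
    "conv_text_classifier",
    "recurrent_text_classifier",
]


# ----------------------------------------------------------------------
# bag of words + logistic regression
# ----------------------------------------------------------------------

@dataclass
class BowVector:
    counts: np.ndarray  # length = number of unigram vocabulary entries


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    l2: float
    loss: str = "logistic"

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.weights + self.bias)


def bow_featurize(doc: Document, vocab: Vocabulary) -> BowVector:
    """Unigram counts over the vocabulary; out-of-vocabulary tokens ignored."""
    counts = np.zeros(vocab.n_unigrams, dtype=np.float64)
    for tok in doc.ensure_tokens():
        j = vocab.entries.get(tok)
        if j is not None and j < vocab.n_unigrams:
            counts[j] += 1.0
    return BowVector(counts=counts)


def bow_matrix(docs: Sequence[Document], vocab: Vocabulary) -> np.ndarray:
    return np.stack([bow_featurize(d, vocab).counts for d in docs])


def train_logistic(X: np.ndarray, y: np.ndarray, l2: float = 1.0,
                   loss: str = "logistic", seed: int = 0,
                   max_iter: int = 5000) -> LinearModel:
    """Fit the linear classifier on count features.

    ``loss="logistic"`` is the reference path: cross-entropy with L2
    *regularization* of strength ``l2`` (objective
    ``sum CE + l2/2 * ||w||^2``, intercept unpenalized).
    ``loss="squared"`` minimizes squared error between the sigmoid output
    and the 0/1 label (same regularizer) by full-batch gradient descent;
    it exists for fidelity comparisons, not as the default.
    """
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    if loss == "logistic":
        clf = LogisticRegression(C=1.0 / l2, solver="lbfgs", tol=1e-10,
                                 max_iter=max_iter, random_state=seed)
        clf.fit(X, y)
        return LinearModel(weights=clf.coef_[0].copy(),
                           bias=float(clf.intercept_[0]), l2=l2, loss=loss)
    if loss != "squared":
        raise ValueError(f"unknown loss: {loss!r}")
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    lr = 1.0 / (np.linalg.norm(X, ord=2) ** 2 / n + l2 + 1.0)
    for _ in range(max_iter):
        p = expit(X @ w + b)
        err = (p - y) * p * (1.0 - p)
        gw = 2.0 * X.T @ err / n + l2 * w / n
        gb = 2.0 * err.sum() / n
        w -= lr * gw
        b -= lr * gb
        if max(np.abs(gw).max(), abs(gb)) < 1e-8:
            break
    return LinearModel(weights=w, bias=b, l2=l2, loss=loss)


# ----------------------------------------------------------------------
# neural baselines
# ----------------------------------------------------------------------

@dataclass
class ConvClassifierConfig:
    embedding_dim: int = 100
    filter_widths: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 100
    dropout: float = 0.3
    lr: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        if not 50 <= self.embedding_dim <= 1000:
            raise ValueError("embedding_dim outside the supported 50..1000 range")
        if not 0.1 <= self.dropout <= 0.5:
            raise ValueError("dropout outside the supported 0.1..0.5 range")


@dataclass
class RecurrentClassifierConfig:
    embedding_dim: int = 100
    hidden_size: int = 256
    dropout: float = 0.3
    lr: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        if not 50 <= self.embedding_dim <= 1000:
            raise ValueError("embedding_dim outside the supported 50..1000 range")
        if not 50 <= self.hidden_size <= 1000:
            raise ValueError("hidden_size outside the supported 50..1000 range")
        if not 0.1 <= self.dropout <= 0.5:
            raise ValueError("dropout outside the supported 0.1..0.5 range")


class ConvTextClassifier:
    """Embeddings -> parallel width-w convolutions -> masked max-over-time
    -> dropout -> linear.  Max pooling only looks at windows fully inside
    the real sequence, so trailing padding cannot change the score."""

    def __init__(self, vocab_size: int, config: ConvClassifierConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D = config.embedding_dim
        self.embedding = Embedding(vocab_size + 1, D, rng)  # +1 for pad id 0
        self.filters = [Linear(w * D, config.n_filters, rng)
                        for w in config.filter_widths]
        self.out = Linear(config.n_filters * len(config.filter_widths), 2, rng)
        params = self.embedding.parameters() + self.out.parameters()
        for f in self.filters:
            params += f.parameters()
        self.optimizer = Adam(params, lr=config.lr)
        self.batch_size = config.batch_size

    def _forward(self, X: Sequence[np.ndarray], train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        ids, lengths = pad_batch([np.asarray(x, dtype=np.intp) + 1 for x in X])
        B, T = ids.shape
        widest = max(self.config.filter_widths)
        if T < widest:  # ensure at least one window per width
            ids = np.concatenate([ids, np.zeros((B, widest - T), dtype=np.intp)], axis=1)
            T = widest
        emb = self.embedding(ids)  # (B, T, D)
        pooled = []
        from .autograd import concat
        for w, filt in zip(self.config.filter_widths, self.filters):
            windows = concat([emb[:, i:T - w + 1 + i, :] for i in range(w)], axis=2)
            fmap = relu(filt(windows))  # (B, T-w+1, F)
            # a window starting at i is valid iff i + w <= true length
            valid = (np.arange(T - w + 1)[None, :] + w) <= np.maximum(lengths, w)[:, None]
            bias = np.where(valid[:, :, None], 0.0, -1e30)
            pooled.append((fmap + Tensor(bias)).max(axis=1))
        rep = concat(pooled, axis=1)
        rep = dropout(rep, self.config.dropout, rng, train)
        return self.out(rep)

    def train_epoch(self, X, y, rng: np.random.Generator) -> float:
        return _epoch(self, X, y, rng)

    def predict_proba(self, X) -> np.ndarray:
        return _predict(self, X)

    def score(self, token_ids: np.ndarray) -> float:
        return float(self.predict_proba([np.asarray(token_ids, dtype=np.intp)])[0])

    def get_state(self) -> dict:
        return {i: p.data.copy() for i, p in enumerate(self.optimizer.params)}

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.optimizer.params):
            p.data[...] = state[i]


class RecurrentTextClassifier:
    """Embeddings -> GRU -> final hidden state -> dropout -> linear."""

    def __init__(self, vocab_size: int, config: RecurrentClassifierConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D = config.embedding_dim
        self.embedding = Embedding(vocab_size + 1, D, rng)
        self.gru = GRU(D, config.hidden_size, rng)
        self.out = Linear(config.hidden_size, 2, rng)
        params = (self.embedding.parameters() + self.gru.parameters()
                  + self.out.parameters())
        self.optimizer = Adam(params, lr=config.lr)
        self.batch_size = config.batch_size

    def _forward(self, X, train: bool, rng) -> Tensor:
        ids, lengths = pad_batch([np.asarray(x, dtype=np.intp) + 1 for x in X])
        emb = self.embedding(ids)
        h = self.gru(emb, lengths=np.maximum(lengths, 1))
        h = dropout(h, self.config.dropout, rng, train)
        return self.out(h)

    train_epoch = ConvTextClassifier.train_epoch
    predict_proba = ConvTextClassifier.predict_proba
    score = ConvTextClassifier.score
    get_state = ConvTextClassifier.get_state
    set_state = ConvTextClassifier.set_state


def _epoch(model, X, y, rng: np.random.Generator) -> float:
    order = rng.permutation(len(X))
    y = np.asarray(y)
    losses = []
    for start in range(0, len(order), model.batch_size):
        batch = order[start:start + model.batch_size]
        logits = model._forward([X[i] for i in batch], train=True, rng=rng)
        loss = cross_entropy(logits, y[batch])
        model.optimizer.zero_grad()
        loss.backward()
        model.optimizer.step()
        losses.append(float(loss.data))
    return float(np.mean(losses))


def _predict(model, X) -> np.ndarray:
    out = []
    for start in range(0, len(X), 4 * model.batch_size):
        chunk = X[start:start + 4 * model.batch_size]
        logits = model._forward(chunk, train=False, rng=None)
        out.append(positive_proba(logits))
    return np.concatenate(out) if out else np.zeros(0)


def conv_text_classifier(X: Sequence[np.ndarray], y: np.ndarray,
                         config: ConvClassifierConfig, seed: int = 0,
                         epochs: int = 5) -> ConvTextClassifier:
    """Train a convolutional scorer on token-id sequences for ``epochs`` passes."""
    if len(X) == 0:
        raise ValueError("empty training set")
    vocab_size = int(max((int(x.max()) for x in X if len(x)), default=0)) + 1
    model = ConvTextClassifier(vocab_size, config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        model.train_epoch(X, y, rng)
    return model


def recurrent_text_classifier(X: Sequence[np.ndarray], y: np.ndarray,
                              config: RecurrentClassifierConfig, seed: int = 0,
                              epochs: int = 5) -> RecurrentTextClassifier:
    if len(X) == 0:
        raise ValueError("empty training set")
    vocab_size = int(max((int(x.max()) for x in X if len(x)), default=0)) + 1
    model = RecurrentTextClassifier(vocab_size, config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        model.train_epoch(X, y, rng)
    return model
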