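"""Mean-pooling n-gram embedding classifier.

Every word and n-gram (up to order ``n_max``, typically 3) kept in the
vocabulary owns a trainable embedding vector.  A document is represented
by the arithmetic mean of the vectors of all its in-vocabulary units —
token *instances*, so duplicates count — and that single vector feeds a
fully connected 2-way softmax layer.  The whole model trains by
backpropagation.  No subword units and no external corpus are involved;
the embeddings exist only for this classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autograd import Tensor
from .nn import Adam, Linear, cross_entropy, dropout, positive_proba
from .textprep import Vocabulary, ngram_key

__all__ = [
    "EmbeddingTable",
    "MeanPoolModel",
    "extract_units",
    "mean_pool",
    "meanpool_score",
]


@dataclass
class EmbeddingTable:
    """One trainable vector per vocabulary entry (unigrams and n-grams)."""

    vectors: np.ndarray  # (|V|, D)


def extract_units(tokens: Sequence[str], vocab: Vocabulary, n_max: int) -> list[int]:
    """All in-vocabulary unigram and 2..n_max-gram ids, in document order.

    Unigrams come first (in token order), then each higher order in
    position order.
    """
    if n_max > vocab.n_max:
        raise ValueError("vocabulary was built with a smaller n_max")
    units: list[int] = []
    for n in range(1, n_max + 1):
        for i in range(len(tokens) - n + 1):
            key = ngram_key(tokens[i:i + n])
            j = vocab.entries.get(key)
            if j is not None:
                units.append(j)
    return units


def mean_pool(unit_ids: Sequence[int], table: EmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the unit vectors; zero vector for no units."""
    if len(unit_ids) == 0:
        return np.zeros(table.vectors.shape[1])
    return table.vectors[np.asarray(unit_ids, dtype=np.intp)].mean(axis=0)


class MeanPoolModel:
    """Trainable mean-then-linear classifier over unit-id sequences.

    ``train_epoch`` / ``predict_proba`` operate on lists of unit-id
    arrays (produced by :func:`extract_units`); scoring is exactly
    softmax(output_weights @ mean + bias).
    """

    def __init__(self, vocab_size: int, dim: int = 100, dropout_rate: float = 0.1,
                 n_max: int = 1, seed: int = 0, lr: float = 1e-2,
                 batch_size: int = 64):
        rng = np.random.default_rng(seed)
        self.table = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)),
                            requires_grad=True)
        self.out = Linear(dim, 2, rng)
        self.dropout_rate = dropout_rate
        self.n_max = n_max
        self.batch_size = batch_size
        self.optimizer = Adam([self.table] + self.out.parameters(), lr=lr)

    @property
    def embedding_table(self) -> EmbeddingTable:
        return EmbeddingTable(vectors=self.table.data)

    def _forward(self, X: Sequence[np.ndarray], train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        B = len(X)
        U = max(1, max(len(x) for x in X))
        dim = self.table.shape[1]
        idx = np.full((B, U), self.table.shape[0], dtype=np.intp)
        counts = np.zeros(B)
        for b, x in enumerate(X):
            idx[b, : len(x)] = np.asarray(x, dtype=np.intp)
            counts[b] = max(len(x), 1)
        from .nn import gather_rows
        g = gather_rows(self.table, idx)  # (B, U, D); pads hit the zero row
        rep = g.sum(axis=1) * Tensor(1.0 / counts[:, None])
        rep = dropout(rep, self.dropout_rate, rng, train)
        return self.out(rep)

    def train_epoch(self, X, y, rng: np.random.Generator) -> float:
        order = rng.permutation(len(X))
        y = np.asarray(y)
        losses = []
        for start in range(0, len(order), self.batch_size):
            batch = order[start:start + self.batch_size]
            logits = self._forward([X[i] for i in batch], train=True, rng=rng)
            loss = cross_entropy(logits, y[batch])
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def predict_proba(self, X) -> np.ndarray:
        out = []
        for start in range(0, len(X), 8 * self.batch_size):
            chunk = X[start:start + 8 * self.batch_size]
            out.append(positive_proba(self._forward(chunk, train=False, rng=None)))
        return np.concatenate(out) if out else np.zeros(0)

    def get_state(self) -> dict:
        return {i: p.data.copy() for i, p in enumerate(self.optimizer.params)}

    def set_state(self, state: dict) -> None:
        for i, p in enumerate(self.optimizer.params):
            p.data[...] = state[i]


def meanpool_score(unit_ids: Sequence[int], model: MeanPoolModel) -> float:
    """Positive-class probability of one document's unit-id sequence."""
    v = mean_pool(unit_ids, model.embedding_table)
    logits = v @ model.out.W.data + model.out.b.data
    z = logits - logits.max()
    e = np.exp(z)
    return float(e[1] / e.sum())
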