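"""Layers, initializers, the optimizer and loss shared by all trainable models.

Everything here is a thin composition of :mod:`longnote.autograd` ops.
Layers hold their parameters as ``Tensor`` objects with
``requires_grad=True``; an :class:`Adam` instance updates ``tensor.data``
in place, so parameter arrays can be shared with plain-NumPy inference
paths.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, exp, log, sigmoid, tanh

# Reserved token ids used by every embedding-based model: real vocabulary
# ids are shifted by ID_OFFSET so 0 can pad ragged batches and 1 can mark
# the classification position of the attention encoder.
PAD_ID = 0
CLS_ID = 1
ID_OFFSET = 2

NEG_INF = -1e30


# ----------------------------------------------------------------------
# initializers
# ----------------------------------------------------------------------

def normal_init(rng: np.random.Generator, shape, std: float = 0.1) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


def xavier_init(rng: np.random.Generator, shape) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def zeros_init(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

class Linear:
    """Affine map ``x @ W + b`` with W of shape (in_dim, out_dim)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = xavier_init(rng, (in_dim, out_dim))
        self.b = zeros_init((out_dim,))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    def __init__(self, num: int, dim: int, rng: np.random.Generator, std: float = 0.1):
        self.W = normal_init(rng, (num, dim), std=std)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.W[ids]

    def parameters(self) -> list[Tensor]:
        return [self.W]


class LSTM:
    """Single-layer LSTM returning the final hidden state.

    Steps past a sequence's true length leave the state untouched, so the
    returned state is the one after the last real element regardless of
    padding.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = xavier_init(rng, (in_dim, 4 * hidden))
        self.Wh = xavier_init(rng, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for t in range(T):
            xt = x[:, t, :]
            g = xt @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(g[:, 0:H])
            f = sigmoid(g[:, H:2 * H])
            o = sigmoid(g[:, 2 * H:3 * H])
            cand = tanh(g[:, 3 * H:4 * H])
            c_new = f * c + i * cand
            h_new = o * tanh(c_new)
            m = (t < lengths).astype(np.float64)[:, None]
            c = Tensor(m) * c_new + Tensor(1.0 - m) * c
            h = Tensor(m) * h_new + Tensor(1.0 - m) * h
        return h

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


class GRU:
    """Single-layer GRU returning the final hidden state (length-masked)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = xavier_init(rng, (in_dim, 3 * hidden))
        self.Wh = xavier_init(rng, (hidden, 3 * hidden))
        self.b = zeros_init((3 * hidden,))

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        for t in range(T):
            xt = x[:, t, :]
            gx = xt @ self.Wx + self.b
            gh = h @ self.Wh
            r = sigmoid(gx[:, 0:H] + gh[:, 0:H])
            z = sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
            cand = tanh(gx[:, 2 * H:3 * H] + r * gh[:, 2 * H:3 * H])
            h_new = z * h + (1.0 - z) * cand
            m = (t < lengths).astype(np.float64)[:, None]
            h = Tensor(m) * h_new + Tensor(1.0 - m) * h
        return h

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(mask)


# ----------------------------------------------------------------------
# loss / scoring
# ----------------------------------------------------------------------

def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # constant, detached
    z = logits - shift
    lse = log(exp(z).sum(axis=axis, keepdims=True))
    return z - lse


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under 2-way logits."""
    logp = log_softmax(logits)
    picked = logp[np.arange(len(labels)), np.asarray(labels, dtype=np.intp)]
    return -picked.mean()


def positive_proba(logits: Tensor | np.ndarray) -> np.ndarray:
    """P(label = 1) from a (B, 2) logit array."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=-1)


# ----------------------------------------------------------------------
# optimizer
# ----------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------
# ragged-batch helpers
# ----------------------------------------------------------------------

def pad_batch(seqs: list[np.ndarray], pad_id: int = PAD_ID) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad integer sequences into a (B, T) matrix plus lengths."""
    lengths = np.array([len(s) for s in seqs], dtype=np.intp)
    T = max(1, int(lengths.max()) if len(lengths) else 1)
    out = np.full((len(seqs), T), pad_id, dtype=np.intp)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out, lengths


def gather_rows(source: Tensor, index: np.ndarray) -> Tensor:
    """Differentiable row gather: ``source[index]`` with a zero row appended.

    ``index`` entries equal to ``source.shape[0]`` select the zero row,
    which is how ragged segment batches are padded without breaking the
    gradient flow to real rows.
    """
    zero = Tensor(np.zeros((1,) + source.shape[1:]))
    augmented = concat([source, zero], axis=0)
    return augmented[index]
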