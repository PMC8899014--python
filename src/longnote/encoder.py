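"""Simplified attention encoder with CLS-based classification.

The encoder maps a token window to one vector per position through L
identical layers.  A layer computes, for every output position i,

    v'_i = tanh( W @ sum_t alpha_t v_t ),
    alpha_t = softmax_t( (v_i . W' v_t) / sqrt(D) ),

with one W and one W' per layer shared across positions.  This is the
bare attention mechanism: a single head, no residual connections, no
layer normalization and no feed-forward sublayer, so every layer output
lies strictly inside (-1, 1).  A reserved classification token occupies
position 0 of every window; its top-layer vector represents the whole
segment and a 2-way linear readout ``argmax(W1 @ v0_top)`` makes the
segment-level decision.

A ``block="standard"`` mode (residual connection + layer normalization
around the attention update) exists for robustness comparisons; the
reference path is the literal form above.

Two equivalent forward implementations live here: per-segment NumPy
functions (:func:`encode_segment` and friends) used for inference and as
a cross-check, and a padded-batch autodiff forward
(:func:`encode_batch`) used for training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .autograd import Tensor, softmax as ag_softmax, tanh as ag_tanh
from .nn import CLS_ID, ID_OFFSET, NEG_INF, PAD_ID

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "SegmentEncoding",
    "embed_input",
    "attention_weights",
    "encoder_layer",
    "encode_segment",
    "classify_cls",
    "encode_batch",
    "prepare_segment_ids",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    ``window`` counts positions including the classification token, so a
    512-window encoder accepts at most 511 content tokens.  ``vocab_size``
    is the full embedding-table size including the reserved pad and CLS
    ids.  The test-scale preset (dim 32, 2 layers, window 64) exercises
    every mechanism at desk cost; window 512 is the clinical preset.
    """

    layers: int = 2
    dim: int = 32
    window: int = 64
    vocab_size: int = 1000
    scale: str = "rsqrt_d"   # "rsqrt_d" | "none"
    block: str = "literal"   # "literal" | "standard"

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2 (CLS plus at least one token)")
        if self.layers < 0:
            raise ValueError("layers must be >= 0")
        if self.scale not in ("rsqrt_d", "none"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.block not in ("literal", "standard"):
            raise ValueError(f"unknown block: {self.block!r}")

    @property
    def scale_factor(self) -> float:
        return 1.0 / np.sqrt(self.dim) if self.scale == "rsqrt_d" else 1.0

    @classmethod
    def clinical(cls, vocab_size: int, dim: int = 256, layers: int = 4) -> "EncoderConfig":
        return cls(layers=layers, dim=dim, window=512, vocab_size=vocab_size)

    @classmethod
    def test_scale(cls, vocab_size: int) -> "EncoderConfig":
        return cls(layers=2, dim=32, window=64, vocab_size=vocab_size)


@dataclass
class EncoderParams:
    """All trainable arrays: embeddings, per-layer (W, W'), readout W1."""

    token_embeddings: np.ndarray
    positional: np.ndarray
    W: list[np.ndarray] = field(default_factory=list)
    W_prime: list[np.ndarray] = field(default_factory=list)
    W1: np.ndarray = None

    @classmethod
    def init(cls, config: EncoderConfig, seed: int) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        D = config.dim
        bound = np.sqrt(3.0 / D)
        return cls(
            token_embeddings=rng.normal(0.0, 0.1, size=(config.vocab_size, D)),
            positional=rng.normal(0.0, 0.02, size=(config.window, D)),
            W=[rng.uniform(-bound, bound, size=(D, D)) for _ in range(config.layers)],
            W_prime=[rng.uniform(-bound, bound, size=(D, D)) for _ in range(config.layers)],
            W1=rng.normal(0.0, 0.1, size=(2, D)),
        )

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            token_embeddings=self.token_embeddings.copy(),
            positional=self.positional.copy(),
            W=[w.copy() for w in self.W],
            W_prime=[w.copy() for w in self.W_prime],
            W1=self.W1.copy(),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        out = {"token_embeddings": self.token_embeddings,
               "positional": self.positional, "W1": self.W1}
        for i, (w, wp) in enumerate(zip(self.W, self.W_prime)):
            out[f"W_{i}"] = w
            out[f"W_prime_{i}"] = wp
        return out


@dataclass
class SegmentEncoding:
    """Top-layer vectors of one encoded segment; ``cls`` is position 0."""

    top_vectors: np.ndarray  # (k+1, D) including the CLS position
    cls: np.ndarray          # alias of top_vectors[0]


# ----------------------------------------------------------------------
# per-segment NumPy forward (reference path)
# ----------------------------------------------------------------------

def embed_input(token_ids: Sequence[int], params: EncoderParams,
                config: EncoderConfig) -> np.ndarray:
    """Token + positional embeddings with the CLS id prepended at position 0.

    ``token_ids`` are raw embedding-table ids (already offset past the
    reserved pad/CLS ids).
    """
    ids = np.asarray(token_ids, dtype=np.intp)
    if len(ids) > config.window - 1:
        raise ValueError("segment exceeds window")
    full = np.concatenate([[CLS_ID], ids])
    return params.token_embeddings[full] + params.positional[: len(full)]


def attention_weights(i: int, vectors: np.ndarray, W_prime: np.ndarray,
                      scale: float) -> np.ndarray:
    """Softmax-normalized scaled bilinear scores of position ``i`` against all."""
    scores = scale * (vectors[i] @ W_prime @ vectors.T)
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def encoder_layer(vectors: np.ndarray, W: np.ndarray, W_prime: np.ndarray,
                  scale: float, block: str = "literal") -> np.ndarray:
    """One layer: attention-pool the lower vectors, transform, squash."""
    scores = scale * (vectors @ W_prime @ vectors.T)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    alpha = e / e.sum(axis=1, keepdims=True)
    update = np.tanh((alpha @ vectors) @ W.T)
    if block == "standard":
        out = vectors + update
        mu = out.mean(axis=1, keepdims=True)
        sd = out.std(axis=1, keepdims=True)
        return (out - mu) / (sd + 1e-6)
    return update


def encode_segment(token_ids: Sequence[int], params: EncoderParams,
                   config: EncoderConfig) -> SegmentEncoding:
    """Stack ``config.layers`` layers over the embedded input."""
    x = embed_input(token_ids, params, config)
    for W, Wp in zip(params.W, params.W_prime):
        x = encoder_layer(x, W, Wp, config.scale_factor, config.block)
    return SegmentEncoding(top_vectors=x, cls=x[0])


def classify_cls(cls_vector: np.ndarray, W1: np.ndarray) -> tuple[int, np.ndarray]:
    """2-way readout of the CLS vector: (argmax label, softmax scores).

    Ties break toward label 0.
    """
    logits = W1 @ cls_vector
    z = logits - logits.max()
    e = np.exp(z)
    probs = e / e.sum()
    return int(np.argmax(logits)), probs


# ----------------------------------------------------------------------
# batched autodiff forward (training path)
# ----------------------------------------------------------------------

def prepare_segment_ids(segment_tokens: list[np.ndarray],
                        config: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build a (B, T) embedding-id matrix with CLS at column 0 and pad tail.

    Input sequences hold raw vocabulary ids; they are shifted by the
    reserved-id offset here.  Returns the matrix and per-row lengths
    (including the CLS position).
    """
    limit = config.window - 1
    rows = []
    for seg in segment_tokens:
        if len(seg) > limit:
            raise ValueError("segment exceeds window")
        rows.append(np.concatenate([[CLS_ID], np.asarray(seg, dtype=np.intp) + ID_OFFSET]))
    return nn.pad_batch(rows, pad_id=PAD_ID)


def encode_batch(ids: np.ndarray, lengths: np.ndarray,
                 tensors: dict[str, Tensor], config: EncoderConfig) -> Tensor:
    """Differentiable forward over a padded batch; returns (B, T, D) tops.

    ``tensors`` maps the names of :meth:`EncoderParams.arrays` to
    autograd Tensors (sharing storage with the parameter arrays).  Padded
    positions are excluded from every attention softmax; their own
    outputs are garbage and must be masked downstream.
    """
    B, T = ids.shape
    x = tensors["token_embeddings"][ids] + tensors["positional"][np.arange(T)]
    key_mask = (np.arange(T)[None, :] < lengths[:, None])
    bias = np.where(key_mask, 0.0, NEG_INF)[:, None, :]  # (B, 1, T) additive
    scale = config.scale_factor
    for layer in range(config.layers):
        W = tensors[f"W_{layer}"]
        Wp = tensors[f"W_prime_{layer}"]
        scores = ((x @ Wp) @ x.transpose(0, 2, 1)) * scale + Tensor(bias)
        alpha = ag_softmax(scores, axis=-1)
        update = ag_tanh((alpha @ x) @ W.transpose(1, 0))
        if config.block == "standard":
            s = x + update
            mu = s.mean(axis=2, keepdims=True)
            var = ((s - mu) ** 2.0).mean(axis=2, keepdims=True)
            x = (s - mu) * (var + 1e-6) ** -0.5
        else:
            x = update
    return x


# ----------------------------------------------------------------------
# checkpoints: flat binary tensors + JSON shape manifest
# ----------------------------------------------------------------------

def save_checkpoint(path, params: EncoderParams, config: EncoderConfig) -> None:
    arrays = params.arrays()
    np.savez(path, **arrays)
    manifest = {"config": config.__dict__,
                "shapes": {k: list(v.shape) for k, v in arrays.items()}}
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path) -> tuple[EncoderParams, EncoderConfig]:
    with open(str(path) + ".json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    config = EncoderConfig(**manifest["config"])
    p = str(path)
    if not p.endswith(".npz"):
        p += ".npz"  # np.savez appends the suffix on write
    with np.load(p) as data:
        arrays = {k: data[k] for k in data.files}
    return EncoderParams(
        token_embeddings=arrays["token_embeddings"],
        positional=arrays["positional"],
        W=[arrays[f"W_{i}"] for i in range(config.layers)],
        W_prime=[arrays[f"W_prime_{i}"] for i in range(config.layers)],
        W1=arrays["W1"],
    ), config
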