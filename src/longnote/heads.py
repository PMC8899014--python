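"""Segment-combination heads: one document vector from many window encodings.

A bounded-window encoder sees at most ``window`` tokens at a time, but an
admission document is several windows long.  Seven strategies map the
per-segment encodings to a single document vector ``v_d``:

==============  ============================================================
``lstm_cls``    CLS vectors fed in segment order to an LSTM; final state.
``lstm_top``    ALL top-layer position vectors (flattened in order) to an
                LSTM; requires a frozen encoder.
``concat_top``  all top-layer vectors concatenated (fixed segment budget).
``concat_cls``  CLS vectors concatenated (fixed segment budget).
``mean_cls``    elementwise mean of the CLS vectors.
``min_cls``     elementwise minimum.
``max_cls``     elementwise maximum.
==============  ============================================================

``v_d`` feeds a fully connected 2-way classifier; the whole stack
(encoder + head) trains by backpropagation unless the encoder is frozen,
in which case gradients stop at the segment encodings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .autograd import Tensor
from .encoder import (EncoderConfig, EncoderParams, SegmentEncoding,
                      encode_batch, prepare_segment_ids)
from .nn import LSTM, Adam, Linear, cross_entropy, dropout, gather_rows, positive_proba

STRATEGIES = ("lstm_cls", "lstm_top", "concat_top", "concat_cls",
              "mean_cls", "min_cls", "max_cls")

__all__ = [
    "STRATEGIES",
    "HeadConfig",
    "DocumentRepresentation",
    "pad_or_truncate",
    "combine_segments",
    "EncoderDocClassifier",
    "predict_document",
]


@dataclass
class HeadConfig:
    strategy: str = "lstm_cls"
    max_segments: int = 6
    hidden_size: int = 256
    freeze_encoder: bool = False
    relax_freeze_requirement: bool = False

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")
        # Backpropagating through every position of every segment is the
        # expensive case; these heads run with the encoder frozen.
        if (self.strategy in ("lstm_top", "concat_top")
                and not self.freeze_encoder and not self.relax_freeze_requirement):
            raise ValueError(f"{self.strategy} requires freeze_encoder=True")


@dataclass
class DocumentRepresentation:
    v_d: np.ndarray
    strategy: str
    segments_consumed: int


def pad_or_truncate(encodings: Sequence[SegmentEncoding], S: int) -> list[SegmentEncoding]:
    """Right-pad with zero-vector encodings, or keep only the first S."""
    if S < 1:
        raise ValueError("S must be >= 1")
    enc = list(encodings[:S])
    if enc:
        top_shape = enc[0].top_vectors.shape
    else:
        top_shape = (1, 1)
    while len(enc) < S:
        z = np.zeros(top_shape)
        enc.append(SegmentEncoding(top_vectors=z, cls=z[0]))
    return enc


def _run_lstm(lstm: LSTM, seq: np.ndarray) -> np.ndarray:
    h = lstm(Tensor(seq[None, :, :]), lengths=np.array([seq.shape[0]]))
    return h.data[0]


def combine_segments(encodings: Sequence[SegmentEncoding], config: HeadConfig,
                     lstm: LSTM | None = None,
                     window: int | None = None) -> DocumentRepresentation:
    """Produce ``v_d`` from per-segment encodings under one strategy.

    ``lstm`` supplies the recurrent weights for the ``lstm_*`` strategies;
    ``window`` fixes the per-segment position count for ``concat_top``
    (defaults to the longest segment seen).
    """
    encodings = list(encodings)
    if not encodings:
        raise ValueError("empty encoding sequence")
    strat = config.strategy
    if strat in ("mean_cls", "min_cls", "max_cls"):
        cls = np.stack([e.cls for e in encodings])
        op = {"mean_cls": np.mean, "min_cls": np.min, "max_cls": np.max}[strat]
        return DocumentRepresentation(op(cls, axis=0), strat, len(encodings))
    if strat == "concat_cls":
        padded = pad_or_truncate(encodings, config.max_segments)
        v = np.concatenate([e.cls for e in padded])
        return DocumentRepresentation(v, strat, min(len(encodings), config.max_segments))
    if strat == "concat_top":
        S = config.max_segments
        W = window or max(e.top_vectors.shape[0] for e in encodings)
        D = encodings[0].top_vectors.shape[1]
        parts = []
        for e in pad_or_truncate(encodings, S):
            block = np.zeros((W, D))
            k = min(W, e.top_vectors.shape[0])
            block[:k] = e.top_vectors[:k]
            parts.append(block.ravel())
        return DocumentRepresentation(np.concatenate(parts), strat,
                                      min(len(encodings), S))
    if lstm is None:
        raise ValueError(f"{strat} needs the recurrent head weights")
    if strat == "lstm_cls":
        seq = np.stack([e.cls for e in encodings])
    else:  # lstm_top: every position of every segment, in order
        seq = np.concatenate([e.top_vectors for e in encodings], axis=0)
    return DocumentRepresentation(_run_lstm(lstm, seq), strat, len(encodings))


# ----------------------------------------------------------------------
# trainable document classifier: encoder + head + linear readout
# ----------------------------------------------------------------------

class EncoderDocClassifier:
    """Window encoder, segment-combination head and 2-way readout, trained
    end to end (or with the encoder frozen).

    Training and scoring take lists of token-id arrays (raw vocabulary
    ids); segmentation into windows happens internally.  All randomness
    flows from the constructor seed and the per-epoch generator, so runs
    are exactly reproducible.
    """

    def __init__(self, enc_config: EncoderConfig, head_config: HeadConfig,
                 seed: int = 0, lr: float = 3e-3, batch_size: int = 32,
                 dropout_rate: float = 0.1):
        self.enc_config = enc_config
        self.head_config = head_config
        self.lr = lr
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)
        self.encoder_params = EncoderParams.init(enc_config, seed)
        trainable = not head_config.freeze_encoder
        self.enc_tensors = {k: Tensor(v, requires_grad=trainable)
                            for k, v in self.encoder_params.arrays().items()
                            if k != "W1"}
        D = enc_config.dim
        S = head_config.max_segments
        self.lstm = None
        if head_config.strategy in ("lstm_cls", "lstm_top"):
            self.lstm = LSTM(D, head_config.hidden_size, rng)
            rep_dim = head_config.hidden_size
        elif head_config.strategy == "concat_cls":
            rep_dim = S * D
        elif head_config.strategy == "concat_top":
            rep_dim = S * enc_config.window * D
        else:
            rep_dim = D
        self.classifier = Linear(rep_dim, 2, rng)
        params = list(self.classifier.parameters())
        if self.lstm is not None:
            params += self.lstm.parameters()
        if trainable:
            params += list(self.enc_tensors.values())
        self.optimizer = Adam(params, lr=lr)

    # -- forward --------------------------------------------------------
    def _segments(self, ids: np.ndarray) -> list[np.ndarray]:
        content = self.enc_config.window - 1  # one position reserved for CLS
        ids = np.asarray(ids, dtype=np.intp)
        if len(ids) == 0:
            ids = np.zeros(0, dtype=np.intp)
            return [ids]
        segs = [ids[i:i + content] for i in range(0, len(ids), content)]
        return segs[: self.head_config.max_segments]

    def _forward(self, X: Sequence[np.ndarray], train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        doc_segs = [self._segments(ids) for ids in X]
        flat = [s for segs in doc_segs for s in segs]
        seg_ids, seg_lengths = prepare_segment_ids(flat, self.enc_config)
        top = encode_batch(seg_ids, seg_lengths, self.enc_tensors, self.enc_config)
        N, T, D = top.shape
        n_segs = np.array([len(s) for s in doc_segs], dtype=np.intp)
        offsets = np.concatenate([[0], np.cumsum(n_segs)[:-1]])
        strat = self.head_config.strategy
        B = len(X)
        if strat in ("mean_cls", "min_cls", "max_cls", "concat_cls", "lstm_cls"):
            S = (self.head_config.max_segments if strat == "concat_cls"
                 else int(n_segs.max()))
            idx = np.full((B, S), N, dtype=np.intp)  # N -> zero pad row
            for b in range(B):
                idx[b, : n_segs[b]] = offsets[b] + np.arange(n_segs[b])
            cls = top[:, 0, :]
            g = gather_rows(cls, idx)  # (B, S, D)
            if strat == "mean_cls":
                rep = g.sum(axis=1) * Tensor(1.0 / n_segs[:, None])
            elif strat in ("min_cls", "max_cls"):
                pad = (idx == N)[:, :, None]
                bias = np.where(pad, nn.NEG_INF, 0.0)
                if strat == "min_cls":
                    rep = (g - Tensor(bias)).min(axis=1)
                else:
                    rep = (g + Tensor(bias)).max(axis=1)
            elif strat == "concat_cls":
                rep = g.reshape(B, S * D)
            else:
                rep = self.lstm(g, lengths=n_segs)
        else:  # lstm_top / concat_top: every real position of every segment
            flat_top = top.reshape(N * T, D)
            pos_counts = seg_lengths  # includes the CLS position
            if strat == "concat_top":
                P = self.head_config.max_segments * self.enc_config.window
            else:
                P = int(max(int(pos_counts[offsets[b]:offsets[b] + n_segs[b]].sum())
                            for b in range(B)))
            pidx = np.full((B, P), N * T, dtype=np.intp)
            tot = np.zeros(B, dtype=np.intp)
            for b in range(B):
                cursor = 0
                for s in range(n_segs[b]):
                    seg_row = offsets[b] + s
                    k = int(pos_counts[seg_row])
                    if strat == "concat_top":
                        base = s * self.enc_config.window
                        pidx[b, base: base + k] = seg_row * T + np.arange(k)
                    else:
                        pidx[b, cursor: cursor + k] = seg_row * T + np.arange(k)
                    cursor += k
                tot[b] = cursor
            gp = gather_rows(flat_top, pidx)  # (B, P, D)
            if strat == "concat_top":
                rep = gp.reshape(B, P * D)
            else:
                rep = self.lstm(gp, lengths=tot)
        rep = dropout(rep, self.dropout_rate, rng, train)
        return self.classifier(rep)

    # -- training protocol ---------------------------------------------
    def train_epoch(self, X: Sequence[np.ndarray], y: np.ndarray,
                    rng: np.random.Generator) -> float:
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(order), self.batch_size):
            batch = order[start:start + self.batch_size]
            logits = self._forward([X[i] for i in batch], train=True, rng=rng)
            loss = cross_entropy(logits, np.asarray(y)[batch])
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def predict_proba(self, X: Sequence[np.ndarray]) -> np.ndarray:
        out = []
        for start in range(0, len(X), 4 * self.batch_size):
            chunk = X[start:start + 4 * self.batch_size]
            logits = self._forward(chunk, train=False, rng=None)
            out.append(positive_proba(logits))
        return np.concatenate(out) if out else np.zeros(0)

    # -- snapshots ------------------------------------------------------
    def get_state(self) -> dict:
        state = {f"enc:{k}": t.data.copy() for k, t in self.enc_tensors.items()}
        state["cls:W"] = self.classifier.W.data.copy()
        state["cls:b"] = self.classifier.b.data.copy()
        if self.lstm is not None:
            for name, t in zip(("Wx", "Wh", "b"), self.lstm.parameters()):
                state[f"lstm:{name}"] = t.data.copy()
        return state

    def set_state(self, state: dict) -> None:
        for k, t in self.enc_tensors.items():
            t.data[...] = state[f"enc:{k}"]
        self.classifier.W.data[...] = state["cls:W"]
        self.classifier.b.data[...] = state["cls:b"]
        if self.lstm is not None:
            for name, t in zip(("Wx", "Wh", "b"), self.lstm.parameters()):
                t.data[...] = state[f"lstm:{name}"]


def predict_document(token_ids: np.ndarray, model: EncoderDocClassifier) -> float:
    """Probability of the positive class for one document's token ids."""
    return float(model.predict_proba([np.asarray(token_ids, dtype=np.intp)])[0])
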