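"""Boolean attribute encoding and text + attribute fusion.

Non-text admission attributes (age, gender, demographics, religion,
admission type, discharge location, insurance — not medical treatments)
are flattened into a fixed-order boolean vector by an
:class:`AttributeSchema`.  An attribute-only classifier is a single
fully connected softmax layer over the bits.  The combined model simply
concatenates the boolean vector with the text model's document
representation (the encoder's CLS-derived vector) before the final
classifier, and trains end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .autograd import Tensor, concat
from .heads import EncoderDocClassifier, HeadConfig
from .encoder import EncoderConfig
from .nn import Adam, Linear, cross_entropy, dropout, positive_proba

__all__ = [
    "AttributeSpec",
    "AttributeSchema",
    "encode_attributes",
    "clinical_preset_schema",
    "AttributeOnlyClassifier",
    "attribute_only_classifier",
    "fuse_concat",
    "FusedDocClassifier",
]


@dataclass
class AttributeSpec:
    """One boolean attribute: a named rule over a raw record field.

    Rules: ``{"op": "ge"|"le", "value": x}`` threshold a numeric field;
    ``{"op": "eq", "value": v}`` / ``{"op": "in", "value": [...]}`` test
    category membership; ``{"op": "bool"}`` passes a truthy field
    through.
    """

    name: str
    source_field: str
    rule: dict

    def evaluate(self, record: dict) -> int:
        raw = record.get(self.source_field)
        if raw is None:
            return 0  # missing raw value encodes as 0
        op = self.rule.get("op", "bool")
        if op == "ge":
            return int(float(raw) >= self.rule["value"])
        if op == "le":
            return int(float(raw) <= self.rule["value"])
        if op == "eq":
            return int(raw == self.rule["value"])
        if op == "in":
            return int(raw in self.rule["value"])
        if op == "bool":
            return int(bool(raw))
        raise ValueError(f"unknown rule op: {op!r}")


@dataclass
class AttributeSchema:
    attributes: list[AttributeSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.attributes)

    def encode(self, record: dict) -> np.ndarray:
        return np.array([a.evaluate(record) for a in self.attributes],
                        dtype=np.float64)

    @classmethod
    def from_file(cls, path) -> "AttributeSchema":
        text = open(path, encoding="utf-8").read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls([AttributeSpec(**a) for a in data])

    def to_file(self, path) -> None:
        data = [{"name": a.name, "source_field": a.source_field, "rule": a.rule}
                for a in self.attributes]
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh)


def encode_attributes(record: dict, schema: AttributeSchema) -> np.ndarray:
    """Deterministic 0/1 vector; missing raw values encode as 0."""
    return schema.encode(record)


def read_attribute_records(path) -> dict[str, dict]:
    """Raw attribute records from a CSV keyed by its ``doc_id`` column."""
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        return {row["doc_id"]: {k: v for k, v in row.items() if v != ""}
                for row in csv.DictReader(fh)}


def clinical_preset_schema() -> AttributeSchema:
    """A synthetic stand-in admission-attribute schema of dimension 255.

    The attribute families (age bands, gender, ethnicity, religion,
    admission type, discharge location, insurance, language, marital
    status) and the total dimension match an admission-level clinical
    attribute inventory; the individual category values are synthetic
    placeholders, not a real hospital's coding tables.  Treatment
    descriptors are deliberately absent.
    """
    specs: list[AttributeSpec] = []
    for lo in range(15, 105, 5):  # 18 age bands
        specs.append(AttributeSpec(f"age_ge_{lo}", "age", {"op": "ge", "value": lo}))
    for g in ("female", "male"):
        specs.append(AttributeSpec(f"gender_{g}", "gender", {"op": "eq", "value": g}))
    families = {
        "ethnicity": 60, "religion": 40, "admission_type": 8,
        "admission_location": 20, "discharge_location": 30,
        "insurance": 12, "language": 50, "marital_status": 15,
    }
    for fam, k in families.items():
        for j in range(k):
            specs.append(AttributeSpec(f"{fam}_{j:02d}", fam,
                                       {"op": "eq", "value": f"{fam}_cat_{j:02d}"}))
    assert len(specs) == 255
    return AttributeSchema(specs)


def fuse_concat(text_vector: np.ndarray, attrs: np.ndarray) -> np.ndarray:
    """Concatenate text representation (first) with attribute bits (after)."""
    return np.concatenate([np.asarray(text_vector, dtype=np.float64),
                           np.asarray(attrs, dtype=np.float64)])


# ----------------------------------------------------------------------
# attribute-only classifier
# ----------------------------------------------------------------------

class AttributeOnlyClassifier:
    """Single fully connected softmax layer over the boolean vector."""

    def __init__(self, n_attributes: int, seed: int = 0, lr: float = 1e-2,
                 batch_size: int = 64):
        rng = np.random.default_rng(seed)
        self.out = Linear(n_attributes, 2, rng)
        self.optimizer = Adam(self.out.parameters(), lr=lr)
        self.batch_size = batch_size

    def train_epoch(self, X: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> float:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(order), self.batch_size):
            batch = order[start:start + self.batch_size]
            logits = self.out(Tensor(X[batch]))
            loss = cross_entropy(logits, y[batch])
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return positive_proba(self.out(Tensor(np.asarray(X, dtype=np.float64))))

    def get_state(self) -> dict:
        return {"W": self.out.W.data.copy(), "b": self.out.b.data.copy()}

    def set_state(self, state: dict) -> None:
        self.out.W.data[...] = state["W"]
        self.out.b.data[...] = state["b"]


def attribute_only_classifier(X: np.ndarray, y: np.ndarray, seed: int = 0,
                              epochs: int = 5) -> AttributeOnlyClassifier:
    """Train the single-layer attribute scorer with the shared protocol length."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    model = AttributeOnlyClassifier(np.asarray(X).shape[1], seed=seed)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        model.train_epoch(X, y, rng)
    return model


# ----------------------------------------------------------------------
# fused text + attribute classifier
# ----------------------------------------------------------------------

class FusedDocClassifier(EncoderDocClassifier):
    """Encoder document model whose final classifier also sees the bits.

    Inputs are ``(token_ids, attribute_bits)`` pairs.  The document
    representation from the segment-combination head is concatenated
    with the boolean attribute vector (text dimensions first) and the
    fused vector feeds the 2-way classifier.  With an all-zero attribute
    vector and zero attribute-side weights the score reduces exactly to
    the text-only model's.
    """

    def __init__(self, enc_config: EncoderConfig, head_config: HeadConfig,
                 n_attributes: int, seed: int = 0, lr: float = 3e-3,
                 batch_size: int = 32, dropout_rate: float = 0.1):
        super().__init__(enc_config, head_config, seed=seed, lr=lr,
                         batch_size=batch_size, dropout_rate=dropout_rate)
        self.n_attributes = n_attributes
        rng = np.random.default_rng(seed + 7)
        rep_dim = self.classifier.W.shape[0]
        self.classifier = Linear(rep_dim + n_attributes, 2, rng)
        params = list(self.classifier.parameters())
        if self.lstm is not None:
            params += self.lstm.parameters()
        if not head_config.freeze_encoder:
            params += list(self.enc_tensors.values())
        self.optimizer = Adam(params, lr=lr)

    def _forward(self, X, train: bool, rng) -> Tensor:
        ids = [x[0] for x in X]
        bits = np.stack([np.asarray(x[1], dtype=np.float64) for x in X])
        saved = self.classifier
        # reuse the parent forward up to the head representation by
        # swapping in an identity readout
        self.classifier = lambda rep: concat([rep, Tensor(bits)], axis=1)
        try:
            fused = super()._forward(ids, train=train, rng=rng)
        finally:
            self.classifier = saved
        return self.classifier(fused)

    def get_state(self) -> dict:
        state = {f"enc:{k}": t.data.copy() for k, t in self.enc_tensors.items()}
        state["cls:W"] = self.classifier.W.data.copy()
        state["cls:b"] = self.classifier.b.data.copy()
        if self.lstm is not None:
            for name, t in zip(("Wx", "Wh", "b"), self.lstm.parameters()):
                state[f"lstm:{name}"] = t.data.copy()
        return state
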