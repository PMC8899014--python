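"""Splitting, oversampling, ROC-AUC and the shared training protocol.

The evaluation pipeline is the same for every model: split admissions
75/10/15 into train/validation/test with whole admission groups kept in
one partition (leakage control), balance the training partition by
oversampling the minority class, train for a fixed number of epochs
selecting the epoch snapshot with the best validation AUC, and report
the test AUC of that snapshot.  AUC is computed by pair counting
(Mann-Whitney with half credit for ties).  Two models on the same test
split are compared with a paired stratified bootstrap of the AUC
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "RocResult",
    "TrainResult",
    "split",
    "oversample_minority",
    "auc",
    "train_model",
    "compare_models",
    "cross_validate",
]


@dataclass
class SplitSpec:
    train: float = 0.75
    validation: float = 0.10
    test: float = 0.15
    seed: int = 0
    group_by: str = "group_id"

    def __post_init__(self):
        if min(self.train, self.validation, self.test) <= 0:
            raise ValueError("fractions must be positive")
        if not math.isclose(self.train + self.validation + self.test, 1.0,
                            abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


@dataclass
class TrainResult:
    epoch_val_auc: list[float]
    best_epoch: int  # 0-based
    test_roc: RocResult | None


def _group_key(item, group_by: str):
    if isinstance(item, dict):
        return item[group_by]
    return getattr(item, group_by)


def split(dataset: Sequence, spec: SplitSpec) -> tuple[list, list, list]:
    """Group-atomic random partition into (train, validation, test).

    Target sizes are the largest-remainder apportionment of the
    fractions; shuffled groups fill the train partition first, then
    validation, then test, so sizes are exact whenever groups are
    singletons and within group granularity otherwise.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    n = len(dataset)
    raw = np.array([spec.train, spec.validation, spec.test]) * n
    targets = np.floor(raw).astype(int)
    for _ in range(n - targets.sum()):
        targets[np.argmax(raw - targets)] += 1
    groups: dict = {}
    for i, item in enumerate(dataset):
        groups.setdefault(_group_key(item, spec.group_by), []).append(i)
    keys = sorted(groups, key=str)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(keys)
    parts: list[list] = [[], [], []]
    which = 0
    for key in keys:
        while which < 2 and len(parts[which]) >= targets[which]:
            which += 1
        parts[which].extend(groups[key])
    return tuple([dataset[i] for i in sorted(p)] for p in parts)


def oversample_minority(items: Sequence, labels: Sequence[int],
                        seed: int = 0) -> tuple[list, np.ndarray]:
    """Balance classes by repeated full passes over the minority pool.

    The minority class is duplicated in whole without-replacement passes;
    the remainder is one final without-replacement draw.  Majority items
    are untouched, so the sets of distinct records never change.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for oversampling")
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) == len(majority):
        return list(items), labels.copy()
    rng = np.random.default_rng(seed)
    deficit = len(majority) - len(minority)
    extra: list[int] = []
    while deficit >= len(minority):
        extra.extend(minority)
        deficit -= len(minority)
    if deficit > 0:
        extra.extend(rng.choice(minority, size=deficit, replace=False))
    keep = np.concatenate([np.arange(len(labels)), np.array(extra, dtype=int)])
    rng.shuffle(keep)
    return [items[i] for i in keep], labels[keep]


def auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Mann-Whitney AUC: concordant pairs plus half credit for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = rankdata(scores)  # average ranks implement half-credit ties
    value = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(auc=float(value), n_pos=n_pos, n_neg=n_neg,
                     scores=scores, labels=labels)


def train_model(model, train: tuple, validation: tuple, test: tuple | None,
                config: TrainConfig) -> TrainResult:
    """Run the shared protocol: fixed epochs, validation-AUC model selection.

    ``model`` implements ``train_epoch(X, y, rng)``, ``predict_proba(X)``,
    ``get_state()`` and ``set_state(state)``.  Each ``(X, y)`` pair holds
    model-specific inputs and 0/1 labels.  After the final epoch the
    snapshot with the highest validation AUC is restored; if ``test`` is
    given its AUC is computed once on that snapshot.
    """
    X_tr, y_tr = train
    X_val, y_val = validation
    rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    best_state = None
    best_auc = -np.inf
    for _ in range(config.epochs):
        model.train_epoch(X_tr, y_tr, rng)
        val_auc = auc(model.predict_proba(X_val), y_val).auc
        trace.append(val_auc)
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.get_state()
    model.set_state(best_state)
    test_roc = None
    if test is not None:
        X_te, y_te = test
        test_roc = auc(model.predict_proba(X_te), y_te)
    return TrainResult(epoch_val_auc=trace, best_epoch=int(np.argmax(trace)),
                       test_roc=test_roc)


def compare_models(a: RocResult, b: RocResult, method: str = "bootstrap",
                   reps: int = 2000, seed: int = 0) -> float:
    """Two-sided p-value for the AUC difference of paired score sets.

    Stratified bootstrap: positives and negatives are resampled
    separately (preserving prevalence), the AUC difference recomputed per
    replicate, and the p-value is twice the smaller tail mass of the
    replicate distribution around zero (clipped at 1).
    """
    if method != "bootstrap":
        raise ValueError(f"unknown method: {method!r}")
    if len(a.labels) != len(b.labels) or not np.array_equal(a.labels, b.labels):
        raise ValueError("results come from different test sets")
    labels = a.labels
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    deltas = np.empty(reps)
    for r in range(reps):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        lab = labels[idx]
        deltas[r] = auc(a.scores[idx], lab).auc - auc(b.scores[idx], lab).auc
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return float(min(p, 1.0))


def cross_validate(run: Callable[[tuple, tuple, tuple], float], dataset: Sequence,
                   spec: SplitSpec, repeats: int = 5) -> list[float]:
    """Repeated random resplits; ``run(train, val, test)`` returns a metric."""
    out = []
    for r in range(repeats):
        s = SplitSpec(train=spec.train, validation=spec.validation,
                      test=spec.test, seed=spec.seed + r, group_by=spec.group_by)
        out.append(run(*split(dataset, s)))
    return out
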