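"""Tokenization, admission assembly, vocabulary construction and windowing.

The unit of analysis is the *admission*: a hospital stay may produce
several discharge summaries (later ones are often addenda), which are
concatenated in their original order into one :class:`Document`.
Documents are tokenized with a deterministic lowercase word tokenizer,
mapped onto a corpus :class:`Vocabulary`, and cut into non-overlapping
fixed-size windows (:class:`Segment`) for encoders whose input length is
bounded.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Document",
    "Vocabulary",
    "Segment",
    "tokenize",
    "assemble_admission",
    "build_vocabulary",
    "ngram_key",
    "encode_tokens",
    "encode_documents",
    "segment_document",
    "sample_subsequence",
    "take_head",
    "take_tail",
    "read_jsonl",
    "write_jsonl",
    "read_csv",
    "write_segments_jsonl",
]

# letters | digit runs | apostrophe-led suffixes ('s) | any single punctuation
_TOKEN_RE = re.compile(r"[a-z]+|[0-9]+|'[a-z]+|[^\sa-z0-9]")


@dataclass
class Document:
    """One admission: concatenated note text plus its prediction label."""

    doc_id: str
    group_id: str
    text: str
    tokens: Optional[list[str]] = None
    label: Optional[int] = None
    attributes: Optional[np.ndarray] = None

    def ensure_tokens(self) -> list[str]:
        if self.tokens is None:
            self.tokens = tokenize(self.text)
        return self.tokens


def tokenize(text: str, scheme: str = "default") -> list[str]:
    """Deterministic word tokenizer: lowercase, split punctuation and digits.

    Letter runs, digit runs, apostrophe suffixes (``'s``) and individual
    punctuation marks each become tokens; whitespace only separates.
    Idempotent on text re-joined with single spaces.
    """
    if scheme != "default":
        raise ValueError(f"unknown tokenizer scheme: {scheme!r}")
    return _TOKEN_RE.findall(text.lower())


def assemble_admission(records: Sequence[tuple[str, str]]) -> Document:
    """Concatenate one admission's summaries, in dataset order, into a Document.

    ``records`` is a sequence of ``(group_id, text)`` pairs sharing one
    group id; texts are joined by a single space.
    """
    records = list(records)
    if not records:
        raise ValueError("no summaries for admission")
    group_ids = {g for g, _ in records}
    if len(group_ids) != 1:
        raise ValueError(f"records span multiple admissions: {sorted(group_ids)}")
    gid = records[0][0]
    text = " ".join(t for _, t in records)
    return Document(doc_id=str(gid), group_id=str(gid), text=text)


# ----------------------------------------------------------------------
# vocabulary
# ----------------------------------------------------------------------

def ngram_key(words: Sequence[str]) -> str:
    """Vocabulary key for a token window; order-prefixed for n >= 2.

    The prefix keeps a literal token such as ``"a_b"`` distinct from the
    bigram (a, b).
    """
    if len(words) == 1:
        return words[0]
    return f"{len(words)}~" + "_".join(words)


@dataclass
class Vocabulary:
    """Token and n-gram inventory with dense integer ids.

    Unigrams enter if they occur in at least ``min_doc_freq`` documents;
    n-grams (2..n_max) if their corpus count reaches ``min_count``.
    Unigrams receive the low ids (sorted lexicographically), n-grams
    follow, so the unigram block doubles as the bag-of-words feature
    space.
    """

    entries: dict[str, int] = field(default_factory=dict)
    n_max: int = 1
    min_doc_freq: int = 10
    min_count: int = 5
    n_unigrams: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def id(self, key: str) -> int:
        return self.entries[key]


def build_vocabulary(corpus: Iterable[Document], min_doc_freq: int = 10,
                     min_count: int = 5, n_max: int = 1) -> Vocabulary:
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if min_doc_freq < 1 or min_count < 1:
        raise ValueError("frequency thresholds must be >= 1")
    doc_freq: Counter[str] = Counter()
    gram_count: Counter[str] = Counter()
    for doc in corpus:
        toks = doc.ensure_tokens()
        doc_freq.update(set(toks))
        for n in range(2, n_max + 1):
            for i in range(len(toks) - n + 1):
                gram_count[ngram_key(toks[i:i + n])] += 1
    unigrams = sorted(w for w, df in doc_freq.items() if df >= min_doc_freq)
    ngrams = sorted(g for g, c in gram_count.items() if c >= min_count)
    entries = {w: i for i, w in enumerate(unigrams)}
    for g in ngrams:
        entries[g] = len(entries)
    return Vocabulary(entries=entries, n_max=n_max, min_doc_freq=min_doc_freq,
                      min_count=min_count, n_unigrams=len(unigrams))


def encode_tokens(tokens: Sequence[str], vocab: Vocabulary) -> np.ndarray:
    """Map tokens to unigram vocabulary ids, dropping out-of-vocabulary tokens."""
    return np.array([vocab.entries[t] for t in tokens if t in vocab.entries],
                    dtype=np.intp)


def encode_documents(docs: Sequence[Document], vocab: Vocabulary) -> list[np.ndarray]:
    return [encode_tokens(d.ensure_tokens(), vocab) for d in docs]


# ----------------------------------------------------------------------
# windowing
# ----------------------------------------------------------------------

@dataclass
class Segment:
    source_doc_id: str
    index: int
    token_ids: np.ndarray


def _as_ids(tokens) -> np.ndarray:
    arr = np.asarray(tokens)
    if arr.size == 0:
        raise ValueError("empty token sequence")
    return arr


def segment_document(tokens, window: int, doc_id: str = "") -> list[Segment]:
    """Cut a token-id sequence into non-overlapping windows of ``window`` tokens.

    All segments are full length except possibly the last; concatenating
    them in index order reproduces the input exactly.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = _as_ids(tokens)
    return [Segment(source_doc_id=doc_id, index=s, token_ids=arr[start:start + window])
            for s, start in enumerate(range(0, len(arr), window))]


def sample_subsequence(tokens, window: int, rng: np.random.Generator,
                       doc_id: str = "") -> Segment:
    """A uniformly placed contiguous window of min(window, len) tokens."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = _as_ids(tokens)
    if len(arr) <= window:
        return Segment(source_doc_id=doc_id, index=0, token_ids=arr.copy())
    start = int(rng.integers(0, len(arr) - window + 1))
    return Segment(source_doc_id=doc_id, index=0, token_ids=arr[start:start + window])


def take_head(tokens, window: int, doc_id: str = "") -> Segment:
    """The first min(window, len) tokens; whole sequence if shorter."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = _as_ids(tokens)
    return Segment(source_doc_id=doc_id, index=0, token_ids=arr[:window].copy())


def take_tail(tokens, window: int, doc_id: str = "") -> Segment:
    """The last min(window, len) tokens; whole sequence if shorter."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = _as_ids(tokens)
    return Segment(source_doc_id=doc_id, index=0, token_ids=arr[-window:].copy())


# ----------------------------------------------------------------------
# IO: JSONL is the primary interchange format; CSV accepted with the
# same columns.
# ----------------------------------------------------------------------

def _record_to_document(rec: dict) -> Document:
    attrs = rec.get("attributes")
    return Document(
        doc_id=str(rec["doc_id"]),
        group_id=str(rec["group_id"]),
        text=rec.get("text", ""),
        label=None if rec.get("label") is None else int(rec["label"]),
        attributes=None if attrs is None else np.asarray(attrs, dtype=np.float64),
    )


def read_jsonl(path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(_record_to_document(json.loads(line)))
    return docs


def write_jsonl(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "group_id": d.group_id, "text": d.text,
                   "label": d.label}
            if d.attributes is not None:
                rec["attributes"] = [int(b) for b in d.attributes]
            fh.write(json.dumps(rec) + "\n")


def read_csv(path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            if rec.get("attributes"):
                rec = dict(rec)
                rec["attributes"] = json.loads(rec["attributes"])
            else:
                rec = {**rec, "attributes": None}
            docs.append(_record_to_document(rec))
    return docs


def write_segments_jsonl(docs: Sequence[Document], vocab: Vocabulary,
                         window: int, path) -> None:
    """Tokenize, encode and window documents; one JSONL row per segment."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            ids = encode_tokens(d.ensure_tokens(), vocab)
            if len(ids) == 0:
                continue
            for seg in segment_document(ids, window, doc_id=d.doc_id):
                fh.write(json.dumps({
                    "doc_id": d.doc_id, "group_id": d.group_id,
                    "segment_index": seg.index, "label": d.label,
                    "token_ids": [int(t) for t in seg.token_ids],
                }) + "\n")
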