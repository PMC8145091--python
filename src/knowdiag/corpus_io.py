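"""Reading, writing and tokenizing clinical records and knowledge documents.

Records travel as line-delimited JSON (one object per line with keys ``id``,
``text``, ``labels`` and optional ``numeric``); knowledge documents are one
UTF-8 ``.txt`` file per medical concept with the concept id as filename; the
label vocabulary is one label per line with the order defining score-matrix
columns.

Documents are hierarchical: a document is a list of sentences, a sentence a
list of tokens.  Sentence boundaries are the sentence-final punctuation marks
(both CJK and ASCII); word segmentation is a pluggable callable with a
whitespace default, so corpora in languages needing a real segmenter can
inject one.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Record",
    "KnowledgeDoc",
    "LabelVocabulary",
    "TokenVocabulary",
    "whitespace_tokenizer",
    "tokenize_hierarchical",
    "read_records",
    "write_records",
    "read_knowledge",
    "write_knowledge",
    "read_labels",
    "write_labels",
    "build_vocab",
    "pad_batch",
    "MAX_CHARS_DEFAULT",
]

#: Maximum document length in characters before any tokenization.
MAX_CHARS_DEFAULT = 1600

_SENTENCE_SPLIT = re.compile(r"[。！？.!?]")


class CorpusError(ValueError):
    """Malformed corpus input (parse or validation failure)."""


@dataclass
class Record:
    """One clinical document: hierarchical text + numeric fields + label set."""

    record_id: str
    text: str
    sentences: list[list[str]]
    numeric_raw: dict[str, str] = field(default_factory=dict)
    labels: set[str] = field(default_factory=set)


@dataclass
class KnowledgeDoc:
    """A plain-text description of one medical concept."""

    concept_id: str
    text: str
    sentences: list[list[str]]

    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]


class LabelVocabulary:
    """Ordered label set; the order defines score-matrix columns."""

    def __init__(self, labels: Sequence[str]):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise CorpusError("duplicate labels in vocabulary")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __iter__(self):
        return iter(self.labels)

    def binarize(self, label_sets: Iterable[set[str]]) -> np.ndarray:
        """Gold label sets -> binary matrix aligned with this vocabulary."""
        sets = list(label_sets)
        out = np.zeros((len(sets), len(self.labels)), dtype=np.int64)
        for i, labs in enumerate(sets):
            for lab in labs:
                out[i, self.index[lab]] = 1
        return out


class TokenVocabulary:
    """Token -> contiguous integer index map with reserved pad/unk slots."""

    PAD = 0
    UNK = 1

    def __init__(self, tokens: Sequence[str]):
        self.index = {"<pad>": self.PAD, "<unk>": self.UNK}
        for tok in tokens:
            if tok not in self.index:
                self.index[tok] = len(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, self.UNK)

    def encode(self, tokens: Iterable[str]) -> list[int]:
        return [self[t] for t in tokens]


def whitespace_tokenizer(sentence: str) -> list[str]:
    return sentence.split()


def tokenize_hierarchical(
    text: str,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    max_chars: int = MAX_CHARS_DEFAULT,
) -> list[list[str]]:
    """Split text into sentences of tokens, truncating to ``max_chars`` first.

    Truncation keeps the document prefix: clinical documents lead with the
    chief complaint, so the head carries the most diagnostic signal.  Empty
    sentences are dropped.
    """
    if max_chars <= 0:
        raise ValueError("max_chars must be positive")
    text = text[:max_chars]
    sentences = []
    for chunk in _SENTENCE_SPLIT.split(text):
        toks = tokenizer(chunk)
        if toks:
            sentences.append(toks)
    return sentences


def read_records(
    path: str | Path,
    label_vocab: LabelVocabulary,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    max_chars: int = MAX_CHARS_DEFAULT,
) -> list[Record]:
    """Read a JSONL record file, validating labels against the vocabulary."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rid = str(obj["id"])
                text = obj["text"]
                labels = set(obj["labels"])
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusError(f"malformed record at line {lineno}: {exc}") from exc
            for lab in labels:
                if lab not in label_vocab:
                    raise CorpusError(
                        f"record {rid!r} (line {lineno}) has unknown label {lab!r}"
                    )
            numeric = {str(k): str(v) for k, v in obj.get("numeric", {}).items()}
            records.append(
                Record(
                    record_id=rid,
                    text=text,
                    sentences=tokenize_hierarchical(text, tokenizer, max_chars),
                    numeric_raw=numeric,
                    labels=labels,
                )
            )
    return records


def write_records(records: Iterable[Record], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "id": rec.record_id,
                "text": rec.text,
                "labels": sorted(rec.labels),
                "numeric": rec.numeric_raw,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_knowledge(
    directory: str | Path,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenizer,
    max_chars: int = MAX_CHARS_DEFAULT,
) -> list[KnowledgeDoc]:
    """Read one ``.txt`` knowledge document per concept from a directory."""
    docs = []
    for path in sorted(Path(directory).glob("*.txt")):
        text = path.read_text(encoding="utf-8")
        docs.append(
            KnowledgeDoc(
                concept_id=path.stem,
                text=text,
                sentences=tokenize_hierarchical(text, tokenizer, max_chars),
            )
        )
    ids = [d.concept_id for d in docs]
    if len(set(ids)) != len(ids):
        raise CorpusError("duplicate concept ids in knowledge collection")
    return docs


def write_knowledge(docs: Iterable[KnowledgeDoc], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.concept_id}.txt").write_text(doc.text, encoding="utf-8")


def read_labels(path: str | Path) -> LabelVocabulary:
    lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    return LabelVocabulary([ln for ln in lines if ln])


def write_labels(vocab: LabelVocabulary, path: str | Path) -> None:
    Path(path).write_text("\n".join(vocab.labels) + "\n", encoding="utf-8")


def build_vocab(
    records: Sequence[Record],
    knowledge: Sequence[KnowledgeDoc] = (),
    min_count: int = 0,
) -> TokenVocabulary:
    """Token vocabulary over records and knowledge with a count cutoff.

    Index assignment is deterministic: descending count, ties broken
    lexicographically.
    """
    counts: dict[str, int] = {}
    for rec in records:
        for sent in rec.sentences:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
    for doc in knowledge:
        for sent in doc.sentences:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
    if not counts:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return TokenVocabulary(kept)


def pad_batch(
    docs: Sequence[list[list[str]]],
    vocab: TokenVocabulary,
    max_sents: int,
    max_words: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Index and pad a batch of hierarchical documents.

    Returns ``(indices, mask)`` of shape ``(batch, max_sents, max_words)``;
    the mask is 1 exactly on surviving (post-truncation) real tokens.
    """
    if max_sents <= 0 or max_words <= 0:
        raise ValueError("batch limits must be positive")
    batch = len(docs)
    idx = np.zeros((batch, max_sents, max_words), dtype=np.int64)
    mask = np.zeros((batch, max_sents, max_words), dtype=np.int64)
    for b, doc in enumerate(docs):
        for s, sent in enumerate(doc[:max_sents]):
            toks = sent[:max_words]
            idx[b, s, : len(toks)] = vocab.encode(toks)
            mask[b, s, : len(toks)] = 1
    return idx, mask
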