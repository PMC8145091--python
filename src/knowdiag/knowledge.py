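"""Knowledge attention: TF-IDF filtering and attention aggregation of
external medical knowledge documents.

Stage 1 (filter) is model-free text retrieval: records and knowledge
documents become TF-IDF vectors — TF(x) = N(x)/N within a document, IDF
smoothed as log((1+D)/(1+D(x))) + 1 so that domain words occurring in every
document still keep a usable weight — and any knowledge document whose
cosine similarity with the record falls below the threshold (default 0.5) is
dropped as irrelevant.

Stage 2 (aggregator) is learned: each surviving knowledge embedding k_t is
scored against the record embedding e' (bilinear by default), the scores are
softmaxed into attention weights, the top-k documents by weight are retained
(k defaulting to the ceiling of the mean label count per record), missing
slots are zero-padded, and the aggregated embedding k' is the weight-renormalized
sum of the retained embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor, masked_softmax
from .corpus_io import KnowledgeDoc, Record

__all__ = [
    "TfidfModel",
    "KnowledgeEmbeddings",
    "AggregatedKnowledge",
    "tfidf_fit",
    "tfidf_vector",
    "cosine",
    "filter_knowledge",
    "aggregate_knowledge",
    "choose_k_budget",
]


@dataclass
class TfidfModel:
    """Document frequencies and corpus size backing the smoothed IDF."""

    doc_freq: dict[str, int]
    n_docs: int

    def idf(self, token: str) -> float:
        df = self.doc_freq.get(token, 0)
        return math.log((1 + self.n_docs) / (1 + df)) + 1.0


@dataclass
class KnowledgeEmbeddings:
    """Encoded knowledge vectors k_1..k_j aligned with their concept ids."""

    vectors: np.ndarray          # (j, 2H)
    concept_ids: list[str]


@dataclass
class AggregatedKnowledge:
    """Aggregated knowledge embedding k' with its attention trail."""

    k_prime: np.ndarray
    selected: list[str]                       # <= k_budget concept ids
    attention: dict[str, float] = field(default_factory=dict)


def tfidf_fit(documents: Sequence[Sequence[str]]) -> TfidfModel:
    """Fit document frequencies on flat token sequences."""
    documents = list(documents)
    if not documents:
        raise ValueError("tfidf_fit needs at least one document")
    if all(len(d) == 0 for d in documents):
        raise ValueError("all documents are empty")
    df: dict[str, int] = {}
    for doc in documents:
        for tok in set(doc):
            df[tok] = df.get(tok, 0) + 1
    return TfidfModel(doc_freq=df, n_docs=len(documents))


def tfidf_vector(document: Sequence[str], model: TfidfModel) -> dict[str, float]:
    """TF-IDF weights for one document; out-of-vocabulary tokens are ignored."""
    n = len(document)
    if n == 0:
        return {}
    counts: dict[str, int] = {}
    for tok in document:
        counts[tok] = counts.get(tok, 0) + 1
    return {
        tok: (c / n) * model.idf(tok)
        for tok, c in counts.items()
        if tok in model.doc_freq
    }


def cosine(u, v) -> float:
    """Cosine similarity; dict (sparse) or array inputs; 0 for a zero vector."""
    if isinstance(u, dict) and isinstance(v, dict):
        dot = sum(w * v[t] for t, w in u.items() if t in v)
        nu = math.sqrt(sum(w * w for w in u.values()))
        nv = math.sqrt(sum(w * w for w in v.values()))
    else:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        dot = float(u @ v)
        nu = float(np.linalg.norm(u))
        nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return dot / (nu * nv)


def filter_knowledge(
    record_tokens: Sequence[str],
    knowledge: Sequence[KnowledgeDoc],
    model: TfidfModel,
    threshold: float = 0.5,
) -> list[tuple[KnowledgeDoc, float]]:
    """Keep knowledge documents with cosine(record, doc) >= threshold."""
    rec_vec = tfidf_vector(record_tokens, model)
    kept = []
    for doc in knowledge:
        score = cosine(rec_vec, tfidf_vector(doc.tokens(), model))
        if score >= threshold:
            kept.append((doc, score))
    return kept


def knowledge_similarity_matrix(
    records: Sequence[Record],
    knowledge: Sequence[KnowledgeDoc],
    model: TfidfModel,
) -> np.ndarray:
    """Cosine similarity of every record against every knowledge doc (n x j)."""
    kvecs = [tfidf_vector(doc.tokens(), model) for doc in knowledge]
    out = np.zeros((len(records), len(knowledge)))
    for i, rec in enumerate(records):
        rvec = tfidf_vector([t for s in rec.sentences for t in s], model)
        for j, kv in enumerate(kvecs):
            out[i, j] = cosine(rvec, kv)
    return out


# ---- aggregator ----------------------------------------------------------------

def aggregator_scores(
    e_prime: Tensor,
    K: Tensor,
    W: Tensor | None,
    mode: str = "bilinear",
) -> Tensor:
    """Attention scores of each knowledge embedding against each record.

    e_prime is (B, D), K is (j, 2H), W is (2H, D).  ``bilinear`` scores
    k_t^T W e'; ``dot`` requires D == 2H and uses a plain inner product.
    """
    if mode == "bilinear":
        if W is None:
            raise ValueError("bilinear aggregator needs a weight matrix")
        return ((K @ W) @ e_prime.transpose()).transpose()   # (B, j)
    if mode == "dot":
        return e_prime @ K.transpose()
    raise ValueError(f"unknown aggregator score mode {mode!r}")


def aggregate_batch(
    e_prime: Tensor,
    K: Tensor,
    survive: np.ndarray,
    k_budget: int,
    W: Tensor | None,
    mode: str = "bilinear",
    concept_ids: Sequence[str] | None = None,
) -> tuple[Tensor, Tensor, np.ndarray]:
    """Batched attention aggregation.

    ``survive`` is the (B, j) 0/1 filter-survival mask.  Returns
    ``(k_prime, alpha, selected_mask)`` where ``k_prime`` is (B, 2H), ``alpha``
    the (B, j) softmax over surviving docs, and ``selected_mask`` the 0/1
    top-k selection.  Records with no surviving knowledge get a zero k'.
    """
    if k_budget < 1:
        raise ValueError("k_budget must be >= 1")
    B, j = survive.shape
    scores = aggregator_scores(e_prime, K, W, mode)
    alpha = masked_softmax(scores, survive, axis=-1)   # zero rows when none survive
    ids = list(concept_ids) if concept_ids is not None else [str(t) for t in range(j)]
    sel = np.zeros((B, j))
    a = alpha.data
    for b in range(B):
        alive = np.flatnonzero(survive[b])
        # stable deterministic top-k: descending weight, ties by concept id
        order = sorted(alive, key=lambda t: (-a[b, t], ids[t]))
        sel[b, order[: k_budget]] = 1.0
    kept = alpha * sel
    denom = kept.sum(axis=-1, keepdims=True) + 1e-30
    renorm = kept / denom
    k_prime = renorm @ K                                # (B, 2H)
    return k_prime, alpha, sel


def aggregate_knowledge(
    e_prime: np.ndarray,
    K: KnowledgeEmbeddings,
    k_budget: int,
    W: np.ndarray | None = None,
    mode: str = "bilinear",
) -> AggregatedKnowledge:
    """Aggregate one record's surviving knowledge into k'.

    An empty knowledge collection legally yields a zero vector: some records
    simply have no relevant knowledge.
    """
    j = K.vectors.shape[0] if K.vectors.size else 0
    if j == 0:
        dim = K.vectors.shape[1] if K.vectors.ndim == 2 and K.vectors.shape[1] else (
            np.asarray(e_prime).shape[-1]
        )
        return AggregatedKnowledge(k_prime=np.zeros(dim), selected=[], attention={})
    e = Tensor(np.asarray(e_prime, dtype=float)[None, :])
    Kt = Tensor(np.asarray(K.vectors, dtype=float))
    Wt = Tensor(np.asarray(W, dtype=float)) if W is not None else None
    survive = np.ones((1, j), dtype=int)
    k_prime, alpha, sel = aggregate_batch(
        e, Kt, survive, k_budget, Wt, mode, concept_ids=K.concept_ids
    )
    a = alpha.data[0]
    selected = [K.concept_ids[t] for t in np.flatnonzero(sel[0])]
    selected.sort(key=lambda cid: (-a[K.concept_ids.index(cid)], cid))
    return AggregatedKnowledge(
        k_prime=k_prime.data[0],
        selected=selected,
        attention={cid: float(a[t]) for t, cid in enumerate(K.concept_ids)},
    )


def write_filter_report(
    records: Sequence[Record],
    knowledge: Sequence[KnowledgeDoc],
    model: TfidfModel,
    path,
    threshold: float = 0.5,
) -> None:
    """TSV log of every record/knowledge cosine and the keep decision."""
    sims = knowledge_similarity_matrix(records, knowledge, model)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tconcept_id\tcosine\tkept\n")
        for i, rec in enumerate(records):
            for j, doc in enumerate(knowledge):
                kept = int(sims[i, j] >= threshold)
                fh.write(f"{rec.record_id}\t{doc.concept_id}\t"
                         f"{sims[i, j]:.6f}\t{kept}\n")


def write_aggregation_report(
    record_id: str,
    aggregated: AggregatedKnowledge,
    path,
) -> None:
    """TSV log of one record's knowledge-attention weights and selection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tconcept_id\talpha\tselected\n")
        for cid, alpha in sorted(aggregated.attention.items(),
                                 key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{record_id}\t{cid}\t{alpha:.6f}\t"
                     f"{int(cid in aggregated.selected)}\n")


def choose_k_budget(records: Iterable[Record]) -> int:
    """Per-record knowledge budget: ceiling of the mean label-set size."""
    sizes = [len(r.labels) for r in records]
    if not sizes or sum(sizes) == 0:
        raise ValueError("cannot choose a knowledge budget: no labels in corpus")
    return math.ceil(sum(sizes) / len(sizes))
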