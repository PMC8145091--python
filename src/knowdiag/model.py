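"""End-to-end knowledge-aware diagnosis model.

The model reads a clinical record three ways and fuses them for multilabel
diagnosis:

* the hierarchical encoder turns the document into a vector ``e`` (dim 2H);
* the numeric extractor appends the z-scored physiological vector ``n``,
  giving the record embedding ``e' = [e; n]``;
* the knowledge module retrieves (TF-IDF filter) and attends over
  (aggregator) external knowledge documents, yielding ``k'``.

``[e'; k']`` passes through two fully connected layers (tanh between) and a
per-label sigmoid; labels with probability strictly greater than the
threshold tau are the predicted diagnosis set.  Training is Adam on summed
per-label binary cross-entropy.

The public surface follows the statsmodels convention: ``DiagnosisModel`` is
built from data and configuration, ``fit()`` returns a ``DiagnosisResults``
carrying the fitted parameters, the training log, prediction/evaluation and
a ``summary()`` table.

Two ablations are first-class: ``no_knowledge`` feeds only ``e'`` (the
output is then bitwise independent of the knowledge collection), and
``no_attention`` replaces the aggregator with direct concatenation of all
(filter-masked, zero-padded) knowledge embeddings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat
from .corpus_io import KnowledgeDoc, LabelVocabulary, Record, build_vocab, pad_batch
from .encoder import (EncoderParams, _flatten_params, _load_params, encode_batch,
                      encode_document)
from .knowledge import (KnowledgeEmbeddings, TfidfModel, aggregate_batch,
                        aggregate_knowledge, choose_k_budget,
                        knowledge_similarity_matrix, tfidf_fit)
from .metrics import evaluate_all
from .numeric_features import FeatureSchema, NumericExtractor
from .synthetic import default_feature_schema  # noqa: F401  (re-export convenience)

__all__ = ["ModelConfig", "ModelParams", "Prediction", "DiagnosisModel",
           "DiagnosisResults"]

_ABLATIONS = ("full", "no_knowledge", "no_attention")


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the reference setting (H=100,
    lr=0.001, batch 32, tau=0.5, max 1600 characters per document)."""

    hidden_size: int = 100
    embedding_dim: int = 100
    tau: float = 0.5
    k_budget: int | None = None      # None -> ceil(mean labels/record)
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    ablation: str = "full"
    fc_hidden: int = 200
    max_sents: int = 30
    max_words: int = 50
    min_count: int = 1
    filter_threshold: float = 0.5
    aggregator_score: str = "bilinear"
    project_record: bool = False     # project [e; n] back to 2H before the head

    def __post_init__(self):
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly between 0 and 1")
        if self.ablation not in _ABLATIONS:
            raise ValueError(f"ablation must be one of {_ABLATIONS}")
        for name in ("hidden_size", "embedding_dim", "batch_size", "epochs",
                     "fc_hidden", "max_sents", "max_words"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelParams:
    encoder: EncoderParams
    W_proj: Tensor | None
    W_agg: Tensor | None
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def tensors(self) -> list[Tensor]:
        out = self.encoder.tensors()
        if self.W_proj is not None:
            out.append(self.W_proj)
        if self.W_agg is not None:
            out.append(self.W_agg)
        out.extend([self.W1, self.b1, self.W2, self.b2])
        return out


@dataclass
class Prediction:
    probabilities: np.ndarray
    labels: set[str]


def loss_fn(probabilities: Tensor, gold: np.ndarray) -> Tensor:
    """Per-label binary cross-entropy, summed over labels, averaged over the
    batch; probabilities are epsilon-clamped for stability."""
    p = probabilities.clip(1e-7, 1.0 - 1e-7)
    g = np.asarray(gold, dtype=float)
    ll = g * p.log() + (1.0 - g) * (1.0 - p).log()
    return -(ll.sum(axis=-1).mean())


class DiagnosisModel:
    """Knowledge-aware hierarchical diagnosis model bound to a corpus."""

    def __init__(
        self,
        records: Sequence[Record],
        knowledge: Sequence[KnowledgeDoc],
        label_vocab: LabelVocabulary,
        schema: FeatureSchema | None = None,
        config: ModelConfig | None = None,
    ):
        if not records:
            raise ValueError("training corpus is empty")
        self.records = list(records)
        self.knowledge = sorted(knowledge, key=lambda d: d.concept_id)
        self.label_vocab = label_vocab
        self.schema = schema
        self.config = config or ModelConfig()

        # the no_knowledge ablation must be bitwise independent of the
        # knowledge collection, so knowledge joins preprocessing only when
        # the knowledge path is actually used
        self._use_knowledge = self.config.ablation != "no_knowledge"
        vocab_knowledge = self.knowledge if self._use_knowledge else []
        self.token_vocab = build_vocab(self.records, vocab_knowledge,
                                       min_count=self.config.min_count)
        self.k_budget = (self.config.k_budget if self.config.k_budget is not None
                         else choose_k_budget(self.records))

        # numeric pipeline (fitted on the training corpus only)
        if schema is not None and len(schema) > 0:
            self.numeric = NumericExtractor(schema).fit(self.records)
            self.n_numeric = len(schema)
        else:
            self.numeric = None
            self.n_numeric = 0

        # TF-IDF retrieval model over records + knowledge
        docs = [[t for s in r.sentences for t in s] for r in self.records]
        docs += [d.tokens() for d in vocab_knowledge]
        self.tfidf: TfidfModel = tfidf_fit(docs)

        # training-side arrays (documents are padded per batch, to the batch's
        # own sentence/word maxima capped by the config limits)
        self._train_docs = [r.sentences for r in self.records]
        self._train_numeric = self._numeric_matrix(self.records)
        self._train_survive = self._survival(self.records)
        self._train_gold = label_vocab.binarize([r.labels for r in self.records])

        self._know_idx, self._know_mask = self._pad(
            [d.sentences for d in self.knowledge])

    @classmethod
    def _restore(cls, meta: dict, knowledge: Sequence[KnowledgeDoc]) -> "DiagnosisModel":
        """Rebuild the preprocessing state of a trained model from metadata."""
        from .corpus_io import TokenVocabulary
        from .numeric_features import FeatureSpec

        self = cls.__new__(cls)
        self.records = []
        self.knowledge = sorted(knowledge, key=lambda d: d.concept_id)
        self.label_vocab = LabelVocabulary(meta["labels"])
        self.config = ModelConfig(**meta["config"])
        self.token_vocab = TokenVocabulary(meta["tokens"])
        self._use_knowledge = self.config.ablation != "no_knowledge"
        self.k_budget = meta["k_budget"]
        self.tfidf = TfidfModel(doc_freq=dict(meta["tfidf"]["doc_freq"]),
                                n_docs=meta["tfidf"]["n_docs"])
        if meta.get("schema"):
            self.schema = FeatureSchema([FeatureSpec(**f) for f in meta["schema"]])
            self.numeric = NumericExtractor(self.schema)
            self.numeric.means_ = np.asarray(meta["numeric"]["means"])
            self.numeric.mu_ = np.asarray(meta["numeric"]["mu"])
            self.numeric.sigma_ = np.asarray(meta["numeric"]["sigma"])
            self.n_numeric = len(self.schema)
        else:
            self.schema = None
            self.numeric = None
            self.n_numeric = 0
        self._know_idx, self._know_mask = self._pad(
            [d.sentences for d in self.knowledge])
        return self

    # ---- data preparation ----------------------------------------------------
    def _pad(self, docs: Sequence[list[list[str]]]) -> tuple[np.ndarray, np.ndarray]:
        """Pad a batch to its own maxima, capped by the config limits.

        Attention masking makes the outputs invariant to the padded size, so
        trimming to the batch maxima changes nothing but memory and time.
        """
        ms = max(1, min(self.config.max_sents,
                        max((len(d) for d in docs), default=1)))
        mw = max(1, min(self.config.max_words,
                        max((len(s) for d in docs for s in d), default=1)))
        return pad_batch(docs, self.token_vocab, ms, mw)

    def _numeric_matrix(self, records: Sequence[Record]) -> np.ndarray:
        if self.numeric is None:
            return np.zeros((len(records), 0))
        return self.numeric.transform(records)[0]

    def _survival(self, records: Sequence[Record]) -> np.ndarray:
        if not self.knowledge or not self._use_knowledge:
            return np.zeros((len(records), len(self.knowledge)), dtype=int)
        sims = knowledge_similarity_matrix(records, self.knowledge, self.tfidf)
        return (sims >= self.config.filter_threshold).astype(int)

    # ---- parameters ----------------------------------------------------------
    def _head_input_dim(self) -> int:
        H2 = 2 * self.config.hidden_size
        d_record = H2 if self.config.project_record else H2 + self.n_numeric
        if self.config.ablation == "no_knowledge":
            return d_record
        if self.config.ablation == "no_attention":
            return d_record + len(self.knowledge) * H2
        return d_record + H2

    def init_params(self, rng: np.random.Generator) -> ModelParams:
        cfg = self.config
        H2 = 2 * cfg.hidden_size
        enc = EncoderParams.init(len(self.token_vocab), cfg.embedding_dim,
                                 cfg.hidden_size, rng)

        def glorot(m, n):
            lim = np.sqrt(6.0 / (m + n))
            return Tensor(rng.uniform(-lim, lim, size=(m, n)), requires_grad=True)

        d_eprime = H2 + self.n_numeric
        W_proj = glorot(d_eprime, H2) if cfg.project_record else None
        d_rec = H2 if cfg.project_record else d_eprime
        W_agg = None
        if cfg.ablation == "full" and cfg.aggregator_score == "bilinear":
            W_agg = glorot(H2, d_rec)
        return ModelParams(
            encoder=enc, W_proj=W_proj, W_agg=W_agg,
            W1=glorot(self._head_input_dim(), cfg.fc_hidden),
            b1=Tensor(np.zeros(cfg.fc_hidden), requires_grad=True),
            W2=glorot(cfg.fc_hidden, len(self.label_vocab)),
            b2=Tensor(np.zeros(len(self.label_vocab)), requires_grad=True),
        )

    # ---- forward -------------------------------------------------------------
    def _forward(
        self,
        params: ModelParams,
        idx: np.ndarray,
        mask: np.ndarray,
        numeric: np.ndarray,
        survive: np.ndarray,
    ) -> tuple[Tensor, dict]:
        cfg = self.config
        e, _, _, _ = encode_batch(idx, mask, params.encoder)
        parts = [e]
        if self.n_numeric:
            parts.append(Tensor(numeric))
        e_prime = concat(parts, axis=-1) if len(parts) > 1 else e
        if params.W_proj is not None:
            e_prime = (e_prime @ params.W_proj).tanh()
        aux: dict = {}

        if cfg.ablation == "no_knowledge":
            head_in = e_prime
        else:
            Kenc, _, _, _ = encode_batch(self._know_idx, self._know_mask,
                                         params.encoder)  # (j, 2H)
            if cfg.ablation == "no_attention":
                B, j = survive.shape
                masked = Kenc.reshape(1, j, Kenc.shape[1]) * \
                    survive[:, :, None].astype(float)
                head_in = concat([e_prime, masked.reshape(B, -1)], axis=-1)
            else:
                k_prime, alpha, sel = aggregate_batch(
                    e_prime, Kenc, survive, self.k_budget, params.W_agg,
                    cfg.aggregator_score,
                    concept_ids=[d.concept_id for d in self.knowledge])
                head_in = concat([e_prime, k_prime], axis=-1)
                aux = {"alpha": alpha.data, "selected": sel}
        hidden = (head_in @ params.W1 + params.b1).tanh()
        logits = hidden @ params.W2 + params.b2
        return logits.sigmoid(), aux

    def forward(self, record: Record, params: ModelParams) -> Prediction:
        """Probabilities and thresholded label set for one record."""
        idx, mask = self._pad([record.sentences])
        numeric = self._numeric_matrix([record])
        survive = self._survival([record])
        probs, _ = self._forward(params, idx, mask, numeric, survive)
        p = probs.data[0]
        labels = {lab for lab, pi in zip(self.label_vocab.labels, p)
                  if pi > self.config.tau}
        return Prediction(probabilities=p, labels=labels)

    # ---- training ------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "DiagnosisResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = self.init_params(rng)
        opt = Adam(params.tensors(), lr=cfg.learning_rate)
        n = len(self.records)
        log: list[float] = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                sel = perm[start:start + cfg.batch_size]
                idx, mask = self._pad([self._train_docs[i] for i in sel])
                probs, _ = self._forward(
                    params, idx, mask,
                    self._train_numeric[sel], self._train_survive[sel])
                loss = loss_fn(probs, self._train_gold[sel])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            log.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1:3d}/{cfg.epochs}  loss {log[-1]:.4f}")
        return DiagnosisResults(self, params, log)


class DiagnosisResults:
    """Fitted diagnosis model: parameters, training log, prediction."""

    def __init__(self, model: DiagnosisModel, params: ModelParams,
                 training_log: list[float]):
        self.model = model
        self.params = params
        self.training_log = training_log

    # ---- prediction ----------------------------------------------------------
    def predict(
        self, records: Sequence[Record] | None = None
    ) -> tuple[np.ndarray, list[set[str]]]:
        """Score matrix (rows follow input order) and thresholded label sets."""
        m = self.model
        records = list(records) if records is not None else m.records
        numeric = m._numeric_matrix(records)
        survive = m._survival(records)
        rows = []
        bs = m.config.batch_size
        for start in range(0, len(records), bs):
            sl = slice(start, start + bs)
            idx, mask = m._pad([r.sentences for r in records[sl]])
            probs, _ = m._forward(self.params, idx, mask,
                                  numeric[sl], survive[sl])
            rows.append(probs.data)
        scores = np.concatenate(rows, axis=0) if rows else np.zeros((0, len(m.label_vocab)))
        sets = [
            {lab for lab, p in zip(m.label_vocab.labels, row) if p > m.config.tau}
            for row in scores
        ]
        return scores, sets

    def evaluate(self, records: Sequence[Record]) -> dict[str, float]:
        """The five example-based ranking metrics on the given records."""
        records = list(records)
        scores, _ = self.predict(records)
        gold = self.model.label_vocab.binarize([r.labels for r in records])
        return evaluate_all(scores, gold, tau=self.model.config.tau)

    # ---- interpretability ----------------------------------------------------
    def explain(self, record: Record):
        """Encoder and knowledge attention for one record (for heatmaps)."""
        m = self.model
        idx, mask = m._pad([record.sentences])
        encoded = encode_document(idx[0], mask[0], self.params.encoder)
        aggregated = None
        if m.config.ablation == "full" and m.knowledge:
            numeric = m._numeric_matrix([record])
            e_prime = encoded.e
            if m.n_numeric:
                e_prime = np.concatenate([encoded.e, numeric[0]])
            if self.params.W_proj is not None:
                e_prime = np.tanh(e_prime @ self.params.W_proj.data)
            survive = m._survival([record])[0].astype(bool)
            kept = [d for d, s in zip(m.knowledge, survive) if s]
            if kept:
                kidx, kmask = m._pad([d.sentences for d in kept])
                Kenc, _, _, _ = encode_batch(kidx, kmask, self.params.encoder)
                K = KnowledgeEmbeddings(vectors=Kenc.data,
                                        concept_ids=[d.concept_id for d in kept])
                W = self.params.W_agg.data if self.params.W_agg is not None else None
                aggregated = aggregate_knowledge(e_prime, K, m.k_budget, W,
                                                 m.config.aggregator_score)
        return encoded, aggregated

    # ---- reporting -----------------------------------------------------------
    def summary(self, test_records: Sequence[Record] | None = None) -> str:
        m = self.model
        lines = [
            "Knowledge-aware hierarchical diagnosis model",
            "=" * 58,
            f"records: {len(m.records)}    labels: {len(m.label_vocab)}    "
            f"knowledge docs: {len(m.knowledge)}",
            f"token vocabulary: {len(m.token_vocab)}    "
            f"numeric features: {m.n_numeric}",
            f"ablation: {m.config.ablation}    k budget: {m.k_budget}    "
            f"tau: {m.config.tau}",
            f"hidden: {m.config.hidden_size} (doc dim {2 * m.config.hidden_size})"
            f"    epochs: {len(self.training_log)}",
            f"final training loss: {self.training_log[-1]:.4f}"
            if self.training_log else "not trained",
        ]
        if test_records is not None:
            metrics = self.evaluate(test_records)
            lines.append("-" * 58)
            lines.append(f"evaluation on {len(list(test_records))} records:")
            for name, value in metrics.items():
                lines.append(f"  {name:<20s} {value:.4f}")
        return "\n".join(lines)

    # ---- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + config + vocabularies."""
        arrays = _flatten_params(self.params.encoder)
        for name in ("W_proj", "W_agg", "W1", "b1", "W2", "b2"):
            t = getattr(self.params, name)
            if t is not None:
                arrays[f"head.{name}"] = t.data
        m = self.model
        meta = {
            "config": asdict(m.config),
            "labels": m.label_vocab.labels,
            "tokens": list(m.token_vocab.index.keys())[2:],  # after pad/unk
            "training_log": self.training_log,
            "k_budget": m.k_budget,
            "tfidf": {"doc_freq": m.tfidf.doc_freq, "n_docs": m.tfidf.n_docs},
            "numeric": None if m.numeric is None else {
                "means": m.numeric.means_.tolist(),
                "mu": m.numeric.mu_.tolist(),
                "sigma": m.numeric.sigma_.tolist(),
            },
            "schema": None if m.schema is None else [
                {"name": f.name, "unit": f.unit, "min": f.min, "max": f.max,
                 "conversions": f.conversions} for f in m.schema
            ],
        }
        arrays["meta.json"] = np.array(json.dumps(meta))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path,
             knowledge: Sequence[KnowledgeDoc]) -> "DiagnosisResults":
        """Rebind a saved checkpoint to its knowledge collection.

        The checkpoint carries everything prediction needs (parameters,
        config, vocabularies, TF-IDF statistics, numeric scaling); only the
        knowledge documents themselves are re-read from disk.
        """
        params, meta = cls.load_params(path)
        model = DiagnosisModel._restore(meta, knowledge)
        return cls(model, params, list(meta.get("training_log", [])))

    @staticmethod
    def load_params(path: str | Path) -> tuple[ModelParams, dict]:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(str(arrays.pop("meta.json")))
        enc = _load_params(arrays)

        def head(name):
            key = f"head.{name}"
            return (Tensor(arrays[key], requires_grad=True)
                    if key in arrays else None)

        params = ModelParams(encoder=enc, W_proj=head("W_proj"),
                             W_agg=head("W_agg"), W1=head("W1"), b1=head("b1"),
                             W2=head("W2"), b2=head("b2"))
        return params, meta
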