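"""Synthetic multilabel clinical corpora with planted topic signatures.

The generator emulates the statistical structure the diagnosis model
assumes, at desk scale: multi-sentence documents whose tokens mix per-label
"signature" vocabulary with shared noise vocabulary; label sets drawn from a
zero-truncated Poisson with a target mean around 2.7 labels per record; one
knowledge document per label written predominantly in that label's signature
vocabulary (so TF-IDF retrieval and knowledge attention have real signal);
and bounded numeric features with label-conditional shifts plus a small
corrupted fraction pushed outside the plausibility thresholds to exercise
validation.

Tokens are synthetic ASCII symbols (``L3_sig_07``, ``noise_012``),
whitespace-delimited; sentences end with a period so the hierarchical
tokenizer reconstructs the sentence/word structure from raw text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .corpus_io import KnowledgeDoc, LabelVocabulary, Record, tokenize_hierarchical
from .numeric_features import FeatureSchema, FeatureSpec

__all__ = ["SyntheticSpec", "default_feature_schema", "generate_corpus",
           "generate_score_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters controlling synthetic corpus generation.

    Defaults mirror the structure of a real obstetric record corpus at desk
    scale: 600 records over 8 diagnoses averaging ~2.7 labels each, one
    knowledge document per diagnosis, three bounded physiological features.
    """

    seed: int
    n_records: int = 600
    n_labels: int = 8
    mean_labels: float = 2.7
    sig_tokens_per_label: int = 8
    sig_overlap: float = 0.0   # fraction of signature shared with the sibling label
    label_skew: float = 0.0    # Zipf exponent of label frequencies (0 = uniform)
    noise_tokens: int = 40
    sentences_range: tuple[int, int] = (4, 8)
    words_range: tuple[int, int] = (8, 12)
    sig_prob: float = 0.85
    knowledge_sentences: int = 6
    knowledge_words: int = 10
    knowledge_noise_prob: float = 0.0
    numeric_corruption: float = 0.02
    weeks_fraction: float = 0.3  # menopause values reported in weeks
    # additive shift applied to a feature's mean when the label is present
    numeric_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mean_labels < 1:
            raise ValueError("mean_labels must be >= 1")
        if self.mean_labels > self.n_labels:
            raise ValueError("mean_labels cannot exceed the number of labels")
        if not 0 <= self.sig_prob <= 1:
            raise ValueError("sig_prob must be a probability")
        if not 0 <= self.sig_overlap <= 1:
            raise ValueError("sig_overlap must be a probability")
        if not self.numeric_effects:
            # each of the first labels nudges one feature, alternating sign
            self.numeric_effects = {
                f"DX{j}": {["age", "menopause", "uterine_height"][j % 3]:
                           (6.0 if j % 2 == 0 else -6.0) * (0.5 if j % 3 == 1 else 1.0)}
                for j in range(self.n_labels)
            }


def default_feature_schema() -> FeatureSchema:
    """Example obstetric feature schema used by the generator and the docs."""
    return FeatureSchema([
        FeatureSpec(name="age", unit="years", min=10.0, max=60.0),
        FeatureSpec(name="menopause", unit="months", min=0.0, max=11.0,
                    conversions={"weeks": 0.25}),
        FeatureSpec(name="uterine_height", unit="cm", min=10.0, max=45.0),
    ])


def _truncated_poisson_rate(mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0 + 1e-9:
        return 1e-9

    def f(lam):
        return lam / (1.0 - np.exp(-lam)) - mean

    return brentq(f, 1e-9, 10.0 * mean)


def _label_set_sizes(rng: np.random.Generator, n: int, mean: float, cap: int) -> np.ndarray:
    if mean <= 1.0 + 1e-9:  # degenerate: every record has exactly one label
        return np.ones(n, dtype=int)
    lam = _truncated_poisson_rate(mean)
    sizes = np.zeros(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draw = rng.poisson(lam, size=todo.size)
        ok = (draw >= 1) & (draw <= cap)
        sizes[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return sizes


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[Record], list[KnowledgeDoc], LabelVocabulary, FeatureSchema]:
    """Generate a fully reproducible synthetic corpus from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"DX{j}" for j in range(spec.n_labels)]
    vocab = LabelVocabulary(labels)
    schema = default_feature_schema()

    # labels form sibling pairs (2m, 2m+1) sharing a fraction of their
    # signature vocabulary — confusable related diagnoses whose knowledge
    # documents legitimately overlap
    n_shared = int(round(spec.sig_overlap * spec.sig_tokens_per_label))
    sig = {}
    for j, lab in enumerate(labels):
        pair = j // 2
        shared = [f"P{pair}_shr_{t:02d}" for t in range(n_shared)]
        own = [f"L{j}_sig_{t:02d}" for t in range(spec.sig_tokens_per_label - n_shared)]
        sig[lab] = shared + own
    noise = [f"noise_{t:03d}" for t in range(spec.noise_tokens)]
    # Zipf-weighted noise: a few ubiquitous function-word-like tokens, so
    # noise carries the low-IDF profile of real clinical boilerplate
    noise_w = 1.0 / np.arange(1, spec.noise_tokens + 1)
    noise_w /= noise_w.sum()

    sizes = _label_set_sizes(rng, spec.n_records, spec.mean_labels, spec.n_labels)
    # Zipf-skewed diagnosis frequencies: real corpora mix common and rare
    # diseases; skew 0 recovers the uniform draw
    label_w = 1.0 / np.arange(1, spec.n_labels + 1) ** spec.label_skew
    label_w /= label_w.sum()
    base_means = {"age": 29.0, "menopause": 5.0, "uterine_height": 28.0}
    base_sds = {"age": 5.0, "menopause": 1.8, "uterine_height": 4.0}

    records = []
    for i in range(spec.n_records):
        labs = sorted(rng.choice(labels, size=sizes[i], replace=False,
                                 p=label_w).tolist())
        pool = [tok for lab in labs for tok in sig[lab]]
        n_sents = rng.integers(spec.sentences_range[0], spec.sentences_range[1] + 1)
        sentence_strs = []
        for _ in range(n_sents):
            n_words = rng.integers(spec.words_range[0], spec.words_range[1] + 1)
            toks = [
                pool[rng.integers(len(pool))]
                if rng.random() < spec.sig_prob
                else noise[rng.choice(spec.noise_tokens, p=noise_w)]
                for _ in range(n_words)
            ]
            sentence_strs.append(" ".join(toks))
        text = " . ".join(sentence_strs) + " ."

        numeric = {}
        for feat in schema:
            mean = base_means[feat.name]
            for lab in labs:
                mean += spec.numeric_effects.get(lab, {}).get(feat.name, 0.0)
            value = rng.normal(mean, base_sds[feat.name])
            value = float(np.clip(value, feat.min, feat.max))
            if rng.random() < spec.numeric_corruption:
                # transcription error: push the value far outside the range
                value = feat.max * 100.0
                numeric[feat.name] = f"{value:.1f}"
            elif feat.name == "menopause" and rng.random() < spec.weeks_fraction:
                numeric[feat.name] = f"{value * 4.0:.1f} weeks"
            else:
                numeric[feat.name] = f"{value:.1f}"

        records.append(Record(
            record_id=f"R{i:05d}",
            text=text,
            sentences=tokenize_hierarchical(text),
            numeric_raw=numeric,
            labels=set(labs),
        ))

    knowledge = []
    for lab in labels:
        sentence_strs = []
        for _ in range(spec.knowledge_sentences):
            toks = [
                noise[rng.choice(spec.noise_tokens, p=noise_w)]
                if rng.random() < spec.knowledge_noise_prob
                else sig[lab][rng.integers(len(sig[lab]))]
                for _ in range(spec.knowledge_words)
            ]
            sentence_strs.append(" ".join(toks))
        text = " . ".join(sentence_strs) + " ."
        knowledge.append(KnowledgeDoc(
            concept_id=lab, text=text, sentences=tokenize_hierarchical(text)
        ))

    return records, knowledge, vocab, schema


def generate_score_fixture(
    n: int, c: int, structure: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Score/gold fixtures for metric tests.

    ``perfect`` ranks every relevant label above every irrelevant one,
    ``inverted`` the reverse, ``random`` draws i.i.d. uniform scores.
    """
    rng = np.random.default_rng(seed)
    gold = np.zeros((n, c), dtype=int)
    for i in range(n):
        k = rng.integers(1, c)  # at least one relevant, at least one irrelevant
        gold[i, rng.choice(c, size=k, replace=False)] = 1
    if structure == "random":
        scores = rng.uniform(size=(n, c))
    elif structure in ("perfect", "inverted"):
        jitter = rng.uniform(0.0, 0.4, size=(n, c))
        scores = np.where(gold == 1, 0.6 + jitter, jitter - 0.1)
        if structure == "inverted":
            scores = 1.0 - scores
    else:
        raise ValueError(f"unknown fixture structure {structure!r}")
    return scores, gold
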