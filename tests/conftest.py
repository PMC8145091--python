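import numpy as np
import pytest

from knowdiag.corpus_io import KnowledgeDoc, LabelVocabulary, Record, tokenize_hierarchical
from knowdiag.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(rid, text, labels=(), numeric=None):
    return Record(
        record_id=rid,
        text=text,
        sentences=tokenize_hierarchical(text),
        numeric_raw=dict(numeric or {}),
        labels=set(labels),
    )


def make_knowledge(cid, text):
    return KnowledgeDoc(concept_id=cid, text=text,
                        sentences=tokenize_hierarchical(text))


@pytest.fixture(scope="session")
def small_corpus():
    """Desk-scale synthetic corpus shared by model-level tests."""
    spec = SyntheticSpec(seed=7, n_records=120)
    records, knowledge, vocab, schema = generate_corpus(spec)
    return {
        "train": records[:100],
        "test": records[100:],
        "knowledge": knowledge,
        "vocab": vocab,
        "schema": schema,
    }


@pytest.fixture
def label_vocab():
    return LabelVocabulary(["A", "B", "C"])
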