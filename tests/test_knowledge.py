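"""TF-IDF retrieval, cosine filtering and attention aggregation."""

import math

import numpy as np
import pytest

from knowdiag.autodiff import Tensor
from knowdiag.knowledge import (KnowledgeEmbeddings, aggregate_batch,
                                aggregate_knowledge, choose_k_budget, cosine,
                                filter_knowledge, tfidf_fit, tfidf_vector)
from conftest import make_knowledge, make_record


def tfidf_oracle(documents):
    """Independent two-pass counting implementation of TF-IDF."""
    D = len(documents)
    df = {}
    for doc in documents:
        for tok in set(doc):
            df[tok] = df.get(tok, 0) + 1

    def vector(doc):
        out = {}
        for tok in set(doc):
            if tok not in df:
                continue
            tf = doc.count(tok) / len(doc)
            idf = math.log((1 + D) / (1 + df[tok])) + 1.0
            out[tok] = tf * idf
        return out

    return vector


class TestTfidf:
    CORPUS = [["a", "b"], ["a"], ["c"]]

    def test_derived_three_doc_values(self):
        model = tfidf_fit(self.CORPUS)
        vec = tfidf_vector(self.CORPUS[0], model)
        # TF("a") in doc1 = 1/2; smoothed IDF("a") = log(4/3) + 1
        assert vec["a"] == pytest.approx(0.5 * (math.log(4 / 3) + 1.0))
        assert vec["b"] == pytest.approx(0.5 * (math.log(4 / 2) + 1.0))

    def test_ubiquitous_word_keeps_nonzero_idf(self):
        model = tfidf_fit([["x", "a"], ["x", "b"], ["x", "c"]])
        # raw log(D/D(x)) would be 0; smoothing leaves IDF = 1
        assert model.idf("x") == pytest.approx(1.0)
        assert tfidf_vector(["x"], model)["x"] == pytest.approx(1.0)

    def test_absent_word_has_no_component(self):
        model = tfidf_fit(self.CORPUS)
        assert "c" not in tfidf_vector(self.CORPUS[0], model)

    def test_empty_document_is_zero_vector(self):
        model = tfidf_fit(self.CORPUS)
        assert tfidf_vector([], model) == {}

    def test_out_of_vocabulary_ignored(self):
        model = tfidf_fit(self.CORPUS)
        assert "zzz" not in tfidf_vector(["a", "zzz"], model)

    def test_matches_counting_oracle_on_random_corpora(self, rng):
        alphabet = list("abcdefgh")
        for _ in range(25):
            docs = [
                [alphabet[j] for j in rng.integers(0, len(alphabet),
                                                   size=rng.integers(1, 12))]
                for _ in range(rng.integers(2, 8))
            ]
            model = tfidf_fit(docs)
            oracle = tfidf_oracle(docs)
            for doc in docs:
                mine, ref = tfidf_vector(doc, model), oracle(doc)
                assert set(mine) == set(ref)
                for tok in mine:
                    assert mine[tok] == pytest.approx(ref[tok], abs=1e-9)

    def test_idf_agrees_with_sklearn_smoothing(self):
        sklearn = pytest.importorskip("sklearn.feature_extraction.text")
        docs = [["a", "b"], ["a"], ["c", "b"], ["d"]]
        vec = sklearn.TfidfVectorizer(smooth_idf=True, norm=None,
                                      analyzer=lambda d: d)
        vec.fit(docs)
        model = tfidf_fit(docs)
        for tok, col in vec.vocabulary_.items():
            assert model.idf(tok) == pytest.approx(vec.idf_[col])

    def test_all_empty_errors(self):
        with pytest.raises(ValueError):
            tfidf_fit([[], []])


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_direct_formula(self):
        assert cosine(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == pytest.approx(0.8)

    def test_zero_vector_defined_as_zero(self):
        assert cosine(np.zeros(2), np.array([1.0, 1.0])) == 0.0
        assert cosine({}, {"a": 1.0}) == 0.0

    def test_sparse_matches_dense(self, rng):
        u = {"a": 0.3, "b": -1.2, "c": 0.5}
        v = {"b": 2.0, "c": 0.1, "d": 4.0}
        keys = sorted(set(u) | set(v))
        ud = np.array([u.get(k, 0.0) for k in keys])
        vd = np.array([v.get(k, 0.0) for k in keys])
        assert cosine(u, v) == pytest.approx(cosine(ud, vd))


class TestFilter:
    def test_disjoint_vocabulary_filtered_out(self):
        know = [make_knowledge("k", "x y.")]
        model = tfidf_fit([["a", "b"], ["x", "y"]])
        assert filter_knowledge(["a", "b"], know, model) == []

    def test_identical_text_kept_with_cosine_one(self):
        know = [make_knowledge("k", "a b.")]
        model = tfidf_fit([["a", "b"], ["a", "b"]])
        kept = filter_knowledge(["a", "b"], know, model)
        assert len(kept) == 1
        assert kept[0][1] == pytest.approx(1.0)

    def test_straddling_pair_around_half(self):
        """Two constructed documents whose cosines bracket the 0.5 cutoff."""
        record = ["c"]
        near = make_knowledge("near", "a b b c c .")
        far = make_knowledge("far", "b b b c c .")
        corpus = [record, near.tokens(), far.tokens()]
        model = tfidf_fit(corpus)
        # independent arithmetic: D=3; df(a)=1, df(b)=2, df(c)=3; the record
        # has a single axis, so cos(record, v) = v_c / ||v||
        idf = {"a": math.log(2) + 1, "b": math.log(4 / 3) + 1, "c": 1.0}
        v_near = {"a": idf["a"] / 5, "b": 2 * idf["b"] / 5, "c": 2 * idf["c"] / 5}
        v_far = {"b": 3 * idf["b"] / 5, "c": 2 * idf["c"] / 5}
        def cos_c(v):
            return v["c"] / math.sqrt(sum(x * x for x in v.values()))
        assert cos_c(v_near) == pytest.approx(0.5443, abs=1e-4)
        assert cos_c(v_far) == pytest.approx(0.4598, abs=1e-4)
        kept = filter_knowledge(record, [near, far], model)
        assert [d.concept_id for d, _ in kept] == ["near"]
        assert kept[0][1] == pytest.approx(cos_c(v_near), abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        alphabet = list("abcdef")
        know = [
            make_knowledge(f"k{i}", " ".join(
                alphabet[j] for j in rng.integers(0, 6, size=6)) + " .")
            for i in range(6)
        ]
        record = [alphabet[j] for j in rng.integers(0, 6, size=8)]
        model = tfidf_fit([record] + [k.tokens() for k in know])
        prev = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            kept = {d.concept_id for d, _ in
                    filter_knowledge(record, know, model, threshold=thr)}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestAggregate:
    def make_K(self, rng, j, dim=4):
        return KnowledgeEmbeddings(vectors=rng.normal(size=(j, dim)),
                                   concept_ids=[f"c{t}" for t in range(j)])

    def test_single_survivor_padded_with_zero_slots(self, rng):
        K = self.make_K(rng, 1)
        out = aggregate_knowledge(rng.normal(size=4), K, k_budget=3,
                                  W=np.eye(4))
        assert out.selected == ["c0"]
        assert out.attention["c0"] == pytest.approx(1.0)
        np.testing.assert_allclose(out.k_prime, K.vectors[0], atol=1e-12)

    def test_identical_embeddings_get_uniform_attention(self, rng):
        v = rng.normal(size=4)
        K = KnowledgeEmbeddings(vectors=np.tile(v, (5, 1)),
                                concept_ids=[f"c{t}" for t in range(5)])
        out = aggregate_knowledge(rng.normal(size=4), K, k_budget=5, W=np.eye(4))
        for cid in K.concept_ids:
            assert out.attention[cid] == pytest.approx(0.2, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        """Brute-force score/softmax/sort/renormalize/weighted-sum oracle."""
        for j in (2, 4, 6):
            K = self.make_K(rng, j)
            e = rng.normal(size=4)
            W = rng.normal(size=(4, 4))
            k_budget = 2
            out = aggregate_knowledge(e, K, k_budget=k_budget, W=W)
            scores = np.array([K.vectors[t] @ W @ e for t in range(j)])
            alpha = np.exp(scores - scores.max())
            alpha /= alpha.sum()
            top = sorted(range(j), key=lambda t: (-alpha[t], K.concept_ids[t]))[:k_budget]
            renorm = np.zeros(j)
            renorm[top] = alpha[top] / alpha[top].sum()
            np.testing.assert_allclose(out.k_prime, renorm @ K.vectors, atol=1e-10)
            assert set(out.selected) == {K.concept_ids[t] for t in top}
            for t in range(j):
                assert out.attention[K.concept_ids[t]] == pytest.approx(alpha[t])

    def test_empty_collection_yields_zero_vector(self):
        K = KnowledgeEmbeddings(vectors=np.zeros((0, 4)), concept_ids=[])
        out = aggregate_knowledge(np.ones(4), K, k_budget=3, W=np.eye(4))
        np.testing.assert_array_equal(out.k_prime, np.zeros(4))
        assert out.selected == []

    def test_batched_survival_mask_and_renormalization(self, rng):
        j, B = 5, 3
        K = Tensor(rng.normal(size=(j, 4)))
        e = Tensor(rng.normal(size=(B, 4)))
        W = Tensor(rng.normal(size=(4, 4)))
        survive = np.array([[1, 1, 1, 1, 1],
                            [1, 0, 0, 0, 0],
                            [0, 0, 0, 0, 0]])
        k_prime, alpha, sel = aggregate_batch(e, K, survive, 2, W)
        # row 0: alpha over all docs sums to 1, top-2 renormalized
        assert alpha.data[0].sum() == pytest.approx(1.0)
        assert sel[0].sum() == 2
        # row 1: only doc 0 survives
        np.testing.assert_allclose(alpha.data[1], [1, 0, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(k_prime.data[1], K.data[0], atol=1e-10)
        # row 2: nothing survives -> zero aggregate
        np.testing.assert_allclose(k_prime.data[2], 0.0, atol=1e-12)

    def test_k_budget_must_be_positive(self, rng):
        K = self.make_K(rng, 2)
        with pytest.raises(ValueError):
            aggregate_knowledge(np.ones(4), K, k_budget=0, W=np.eye(4))


class TestChooseKBudget:
    def test_reported_mean_rounds_up_to_three(self):
        # 312 records with 2 labels + 688 with 3 labels -> mean 2.688
        records = [make_record(f"r{i}", "t.", labels={"a", "b"})
                   for i in range(312)]
        records += [make_record(f"s{i}", "t.", labels={"a", "b", "c"})
                    for i in range(688)]
        sizes = [len(r.labels) for r in records]
        assert np.mean(sizes) == pytest.approx(2.688)
        assert choose_k_budget(records) == 3

    def test_single_label_corpus(self):
        records = [make_record(f"r{i}", "t.", labels={"a"}) for i in range(5)]
        assert choose_k_budget(records) == 1

    def test_integer_mean_not_rounded_up(self):
        records = [make_record("r1", "t.", labels={"a"}),
                   make_record("r2", "t.", labels={"a", "b"}),
                   make_record("r3", "t.", labels={"a", "b", "c"})]
        assert choose_k_budget(records) == 2

    def test_no_labels_errors(self):
        with pytest.raises(ValueError):
            choose_k_budget([make_record("r", "t.")])


class TestReports:
    def test_filter_report_lists_every_pair(self, tmp_path, rng):
        recs = [make_record("r1", "a b c ."), make_record("r2", "a d .")]
        know = [make_knowledge("k1", "a b ."), make_knowledge("k2", "x y .")]
        model = tfidf_fit([[t for s in r.sentences for t in s] for r in recs]
                          + [k.tokens() for k in know])
        from knowdiag.knowledge import write_filter_report
        path = tmp_path / "filter.tsv"
        write_filter_report(recs, know, model, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "record_id\tconcept_id\tcosine\tkept"
        assert len(lines) == 1 + len(recs) * len(know)
        for line in lines[1:]:
            rid, cid, cos, kept = line.split("\t")
            assert (float(cos) >= 0.5) == bool(int(kept))

    def test_aggregation_report_marks_selected(self, tmp_path):
        from knowdiag.knowledge import (AggregatedKnowledge,
                                        write_aggregation_report)
        agg = AggregatedKnowledge(k_prime=np.zeros(2), selected=["b"],
                                  attention={"a": 0.3, "b": 0.7})
        path = tmp_path / "agg.tsv"
        write_aggregation_report("r9", agg, path)
        lines = path.read_text().strip().splitlines()
        assert lines[1] == "r9\tb\t0.700000\t1"
        assert lines[2] == "r9\ta\t0.300000\t0"
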