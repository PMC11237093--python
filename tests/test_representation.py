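import math

import numpy as np
import pytest

from drugtopics.corpus import Corpus
from drugtopics.embedding import ReducedEmbedding, ReducerParams
from drugtopics.representation import (
    build_vocab,
    ctfidf,
    doc_term_counts,
    select_exemplars,
    top_keywords,
)
from drugtopics.topics import TopicModel

from conftest import make_corpus, make_discussion
from oracles import brute_ctfidf, tokenize


def model_from_assignment(assignment, k=2):
    assignment = np.asarray(assignment)
    T = assignment.max() + 1
    return TopicModel(assignment=assignment, centroids=np.zeros((T, k)))


class TestBuildVocab:
    def test_stopwords_and_lowercase(self):
        c = make_corpus("the Dog", "the Cat")
        v = build_vocab(c, {"stopwords": ["the"], "min_df": 1})
        assert v.terms == ["cat", "dog"]

    def test_min_df_filter_can_empty_vocab(self):
        c = make_corpus("the dog", "the cat")
        with pytest.raises(ValueError, match="min_df"):
            build_vocab(c, {"stopwords": ["the"], "min_df": 2})

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_vocab(Corpus([]))

    def test_vocabulary_matches_independent_enumeration(self):
        rng = np.random.default_rng(0)
        words = [f"word{i}" for i in range(12)]
        texts = [" ".join(rng.choice(words, size=8)) for _ in range(20)]
        c = make_corpus(*texts)
        v = build_vocab(c, {"stopwords": None, "min_df": 3})
        # independent enumeration: document frequency by brute force
        df = {}
        for t in texts:
            for tok in set(tokenize(t)):
                df[tok] = df.get(tok, 0) + 1
        expected = sorted(tok for tok, n in df.items() if n >= 3)
        assert v.terms == expected


class TestCTFIDF:
    def test_single_class_single_term_closed_form(self):
        # one class, doc "xx xx xx": tf=3, f=3, A=3 -> W = 3*log(2)
        c = make_corpus("xx xx xx")
        v = build_vocab(c, {"stopwords": None})
        W = ctfidf(c, model_from_assignment([0]), v).W
        assert W.shape == (1, 1)
        assert W[0, 0] == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_disjoint_classes_block_diagonal(self):
        c = make_corpus("aa aa bb", "cc dd dd")
        v = build_vocab(c, {"stopwords": None})
        W = ctfidf(c, model_from_assignment([0, 1]), v).W
        idx = v.index()
        for term in ["aa", "bb"]:
            assert W[1, idx[term]] == 0.0
            assert W[0, idx[term]] > 0.0
        for term in ["cc", "dd"]:
            assert W[0, idx[term]] == 0.0
            assert W[1, idx[term]] > 0.0

    def test_empty_topic_rejected(self):
        c = make_corpus("aa bb", "cc dd")
        v = build_vocab(c, {"stopwords": None})
        model = TopicModel(assignment=np.array([0, 0]), centroids=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty topic"):
            ctfidf(c, model, v)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.integers(2, 5)
        vocab_words = [f"wd{i}" for i in range(rng.integers(8, 30))]
        docs_by_class = [
            [" ".join(rng.choice(vocab_words, size=rng.integers(3, 15)))
             for _ in range(rng.integers(1, 5))]
            for _ in range(T)
        ]
        texts = [d for docs in docs_by_class for d in docs]
        assignment = [t for t, docs in enumerate(docs_by_class) for _ in docs]
        c = make_corpus(*texts)
        v = build_vocab(c, {"stopwords": None})
        W = ctfidf(c, model_from_assignment(assignment), v).W
        expected = np.array(brute_ctfidf(docs_by_class, v.terms))
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_no_hidden_state_under_count_scaling(self):
        # repeating every class's documents m times scales tf, f and A by m;
        # recomputing on the scaled corpus must equal direct evaluation
        m = 3
        docs_by_class = [["aa bb aa", "bb cc"], ["cc cc dd"]]
        scaled = [docs * m for docs in docs_by_class]
        texts = [d for docs in scaled for d in docs]
        assignment = [t for t, docs in enumerate(scaled) for _ in docs]
        c = make_corpus(*texts)
        v = build_vocab(c, {"stopwords": None})
        W = ctfidf(c, model_from_assignment(assignment), v).W
        np.testing.assert_allclose(W, np.array(brute_ctfidf(scaled, v.terms)), atol=1e-12)


class TestKeywordsAndExemplars:
    def test_keywords_descending_with_lexicographic_ties(self):
        c = make_corpus("bb bb aa aa zz")
        v = build_vocab(c, {"stopwords": None})
        weights = ctfidf(c, model_from_assignment([0]), v)
        kws = top_keywords(weights, 0, k=3)
        assert kws == ["aa", "bb", "zz"]  # aa/bb tie at tf=2 -> lexicographic

    def test_singleton_topic_is_its_own_representative(self):
        c = make_corpus("aa aa", "bb bb", "bb cc")
        v = build_vocab(c, {"stopwords": None})
        model = model_from_assignment([0, 1, 1])
        R = ReducedEmbedding(np.array([[0.0, 0], [5, 5], [6, 6]]),
                             ReducerParams(k=2, method="identity"))
        model.centroids = np.array([[0.0, 0], [5.5, 5.5]])
        cards = select_exemplars(model, R, c, ctfidf(c, model, v), n_representatives=1)
        assert cards[0].representative_ids == ["d0"]

    def test_nearest_representatives_match_exhaustive_sort(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        c = make_corpus(*[f"w{i} w{i}" for i in range(12)])
        model = model_from_assignment([0] * 12)
        model.centroids = X.mean(0, keepdims=True)
        v = build_vocab(c, {"stopwords": None})
        R = ReducedEmbedding(X, ReducerParams(k=2, method="identity"))
        cards = select_exemplars(model, R, c, ctfidf(c, model, v), n_representatives=4)
        d = np.linalg.norm(X - X.mean(0), axis=1)
        expected = [f"d{i}" for i in sorted(range(12), key=lambda i: (d[i], f"d{i}"))[:4]]
        assert cards[0].representative_ids == expected

    def test_sample_ids_deterministic_and_disjoint_from_representatives(self):
        c = make_corpus(*["xx yy"] * 10)
        model = model_from_assignment([0] * 10)
        model.centroids = np.zeros((1, 2))
        v = build_vocab(c, {"stopwords": None})
        R = ReducedEmbedding(np.random.default_rng(0).normal(size=(10, 2)),
                             ReducerParams(k=2, method="identity"))
        w = ctfidf(c, model, v)
        c1 = select_exemplars(model, R, c, w, n_representatives=3, n_samples=3, seed=5)
        c2 = select_exemplars(model, R, c, w, n_representatives=3, n_samples=3, seed=5)
        assert c1[0].sample_ids == c2[0].sample_ids
        assert not set(c1[0].sample_ids) & set(c1[0].representative_ids)


def test_doc_term_counts_align_with_vocab():
    c = make_corpus("aa bb aa", "bb cc")
    v = build_vocab(c, {"stopwords": None})
    M = doc_term_counts(c, v).toarray()
    idx = v.index()
    assert M[0, idx["aa"]] == 2 and M[1, idx["cc"]] == 1
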