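import numpy as np
import pytest

from drugtopics.embedding import (
    EmbeddingMatrix,
    HashingEmbedder,
    ReducerParams,
    embed,
    hash_embed,
    reduce,
)

from conftest import make_corpus


class TestHashEmbed:
    def test_pure_function_of_inputs(self):
        a = hash_embed("ozempic started last week", 64, seed=1)
        b = hash_embed("ozempic started last week", 64, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_bag_of_words_order_invariance(self):
        np.testing.assert_array_equal(hash_embed("aa bb", 64, 0), hash_embed("bb aa", 64, 0))

    def test_seed_changes_vector(self):
        assert not np.allclose(hash_embed("fixed text", 64, 0), hash_embed("fixed text", 64, 1))

    def test_rows_unit_norm(self):
        assert np.linalg.norm(hash_embed("some tokens here", 32, 0)) == pytest.approx(1.0)

    def test_empty_text_fallback_vector(self):
        v = hash_embed("   !!! ", 32, 0)
        assert v[0] == 1.0 and np.linalg.norm(v) == 1.0

    def test_minimum_dimension_enforced(self):
        with pytest.raises(ValueError, match="d must be >= 8"):
            hash_embed("x", 4, 0)

    def test_low_collision_rate_for_small_vocab(self):
        # with a vocab of d/4 random tokens, nearly every pair of distinct
        # tokens maps to distinct buckets
        d = 256
        rng = np.random.default_rng(0)
        tokens = [f"w{rng.integers(1e9)}" for _ in range(d // 4)]
        from drugtopics.embedding import _bucket_and_sign

        buckets = [_bucket_and_sign(t, d, 0)[0] for t in tokens]
        pairs = [(i, j) for i in range(len(tokens)) for j in range(i + 1, len(tokens))]
        distinct = sum(buckets[i] != buckets[j] for i, j in pairs)
        assert distinct / len(pairs) > 0.9


class TestEmbed:
    def test_identical_texts_identical_rows(self):
        c = make_corpus("same text", "same text", "other words entirely")
        E = embed(c, HashingEmbedder(d=64))
        np.testing.assert_array_equal(E.vectors[0], E.vectors[1])
        assert E.embedder_id.startswith("hashing-bow")

    def test_disjoint_vocabulary_near_zero_cosine(self):
        c = make_corpus("alpha beta gamma delta", "epsilon zeta eta theta")
        E = embed(c, HashingEmbedder(d=512))
        cos = float(E.vectors[0] @ E.vectors[1])
        assert abs(cos) < 0.2

    def test_single_document_shape(self):
        E = embed(make_corpus("only one"), HashingEmbedder(d=64))
        assert E.vectors.shape == (1, 64)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            embed(make_corpus(), HashingEmbedder())

    def test_flaky_embedder_retried_once_then_fatal(self):
        class Flaky:
            name = "flaky"

            def __init__(self, fail_times):
                self.fails = fail_times

            def encode(self, texts):
                if self.fails > 0:
                    self.fails -= 1
                    raise RuntimeError("transient")
                return np.ones((len(texts), 8))

        c = make_corpus("a b", "c d")
        E = embed(c, Flaky(1))  # one failure -> retry succeeds
        assert E.vectors.shape == (2, 8)
        with pytest.raises(RuntimeError, match="failed twice"):
            embed(c, Flaky(2))


class TestReduce:
    def test_identity_passthrough(self):
        X = np.random.default_rng(0).normal(size=(10, 6))
        E = EmbeddingMatrix(X, "test")
        R = reduce(E, ReducerParams(k=6, method="identity"))
        np.testing.assert_array_equal(R.vectors, X)

    def test_identity_requires_matching_dimension(self):
        E = EmbeddingMatrix(np.ones((5, 6)), "test")
        with pytest.raises(ValueError, match="k == d"):
            reduce(E, ReducerParams(k=3, method="identity"))

    def test_too_few_points_names_constraint(self):
        E = EmbeddingMatrix(np.ones((10, 6)), "test")
        with pytest.raises(ValueError, match="n_neighbors"):
            reduce(E, ReducerParams(k=2, n_neighbors=15))

    def test_umap_preserves_blob_separation_and_is_deterministic(self):
        # 3 well-separated centers in 64-dim survive reduction to 2-dim
        rng = np.random.default_rng(0)
        centers = rng.normal(size=(3, 64)) * 10
        X = np.vstack([c + rng.normal(scale=0.1, size=(20, 64)) for c in centers])
        E = EmbeddingMatrix(X, "blobs")
        params = ReducerParams(k=2, n_neighbors=10, metric="euclidean", seed=42)
        R1 = reduce(E, params)
        R2 = reduce(E, params)
        np.testing.assert_array_equal(R1.vectors, R2.vectors)
        Y = R1.vectors
        within = max(
            np.linalg.norm(Y[i * 20 : (i + 1) * 20] - Y[i * 20 : (i + 1) * 20].mean(0), axis=1).mean()
            for i in range(3)
        )
        cmeans = np.array([Y[i * 20 : (i + 1) * 20].mean(0) for i in range(3)])
        between = min(
            np.linalg.norm(cmeans[i] - cmeans[j]) for i in range(3) for j in range(i + 1, 3)
        )
        assert between > 3 * within
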