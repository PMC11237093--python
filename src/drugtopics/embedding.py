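"""Document embeddings and dimensionality reduction.

Embedders follow a small contract: ``encode(texts) -> (n, d) array`` plus a
``name`` for the run manifest. The default is a deterministic signed-hashing
bag-of-words embedder, so no model download is needed; a transformer
sentence embedder can be plugged in by name where the optional dependency
is available. Reduction is UMAP (cosine metric by default) with an identity
passthrough mode for testing.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "Embedder",
    "HashingEmbedder",
    "hash_embed",
    "EmbeddingMatrix",
    "ReducerParams",
    "ReducedEmbedding",
    "embed",
    "reduce",
    "load_plugin_embedder",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class Embedder(Protocol):
    name: str

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


def _bucket_and_sign(token: str, d: int, seed: int) -> tuple[int, float]:
    h = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    v = int.from_bytes(h, "big")
    return (v >> 1) % d, 1.0 if v & 1 else -1.0


def hash_embed(text: str, d: int = 384, seed: int = 0) -> np.ndarray:
    """Signed-hashing bag-of-words vector, L2-normalized.

    Pure function of (text, d, seed): tokens are lowercased ``[a-z0-9]+``
    runs, each hashed to one of ``d`` buckets with a +/-1 sign. An empty
    token list falls back to a reserved unit vector (bucket 0) so downstream
    norms are never zero.
    """
    if d < 8:
        raise ValueError(f"d must be >= 8, got {d}")
    v = np.zeros(d)
    tokens = _TOKEN_RE.findall(text.lower())
    if not tokens:
        v[0] = 1.0
        return v
    for tok in tokens:
        b, s = _bucket_and_sign(tok, d, seed)
        v[b] += s
    norm = np.linalg.norm(v)
    if norm == 0.0:  # pathological total sign cancellation
        v[0] = 1.0
        norm = 1.0
    return v / norm


class HashingEmbedder:
    """Deterministic bag-of-words embedder used for tests and desk runs."""

    def __init__(self, d: int = 384, seed: int = 0):
        self.d = d
        self.seed = seed
        self.name = f"hashing-bow-d{d}-s{seed}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([hash_embed(t, self.d, self.seed) for t in texts])


def load_plugin_embedder(model_name: str, batch_size: int = 64, max_tokens: int = 256):
    """Load a sentence-transformers model by name (optional dependency)."""
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:  # pragma: no cover - optional plugin
        raise ImportError(
            "the transformer embedder plugin requires the optional "
            "'sentence-transformers' dependency"
        ) from exc

    class _Plugin:  # pragma: no cover - optional plugin
        name = f"sentence-transformers:{model_name}"

        def __init__(self):
            self._m = SentenceTransformer(model_name)
            self._m.max_seq_length = max_tokens

        def encode(self, texts):
            return np.asarray(self._m.encode(list(texts), batch_size=batch_size))

    return _Plugin()


@dataclass
class EmbeddingMatrix:
    vectors: np.ndarray  # (n, d), row i embeds discussion i
    embedder_id: str

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def embed(corpus, embedder: Embedder, batch_size: int = 64) -> EmbeddingMatrix:
    """Embed every discussion text, batched, with one retry per batch."""
    texts = corpus.texts() if hasattr(corpus, "texts") else list(corpus)
    if not texts:
        raise ValueError("corpus is empty")
    chunks = []
    for i in range(0, len(texts), batch_size):
        batch = texts[i : i + batch_size]
        try:
            chunks.append(np.asarray(embedder.encode(batch)))
        except Exception:
            try:
                chunks.append(np.asarray(embedder.encode(batch)))
            except Exception as exc:
                raise RuntimeError(
                    f"embedder {embedder.name!r} failed twice on batch starting at {i}"
                ) from exc
    vectors = np.vstack(chunks).astype(float)
    if not np.all(np.isfinite(vectors)):
        raise ValueError("embedder produced non-finite values")
    return EmbeddingMatrix(vectors=vectors, embedder_id=embedder.name)


@dataclass
class ReducerParams:
    """UMAP settings; the reduced dimension feeds density clustering."""

    k: int = 5
    n_neighbors: int = 15
    min_dist: float = 0.0
    metric: str = "cosine"
    seed: int = 42
    method: str = "umap"  # "umap" | "identity"


@dataclass
class ReducedEmbedding:
    vectors: np.ndarray  # (n, k)
    params: ReducerParams = field(default_factory=ReducerParams)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def reduce(embeddings: EmbeddingMatrix, params: ReducerParams | None = None) -> ReducedEmbedding:
    """Reduce (n, d) embeddings to (n, k). Deterministic under a fixed seed."""
    params = params or ReducerParams()
    X = embeddings.vectors
    if params.method == "identity":
        if params.k != X.shape[1]:
            raise ValueError("identity reducer requires k == d")
        return ReducedEmbedding(X.copy(), params)
    if params.method != "umap":
        raise ValueError(f"unknown reducer method {params.method!r}")
    if X.shape[0] <= params.n_neighbors:
        raise ValueError(
            f"n={X.shape[0]} must exceed n_neighbors={params.n_neighbors}; "
            "lower n_neighbors or supply more documents"
        )
    import umap  # deferred: numba jit makes this import heavy

    reducer = umap.UMAP(
        n_components=params.k,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=params.seed,
    )
    Y = np.asarray(reducer.fit_transform(X), dtype=float)
    return ReducedEmbedding(Y, params)
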