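"""Topic representation: vocabulary, class-based TF-IDF, exemplar selection.

c-TF-IDF treats the concatenated text of each topic as one "class
document" and weights term t in class c as

    W[c, t] = tf(t, c) * log(1 + A / f(t))

with tf(t, c) the count of t in class c, f(t) its total count over all
classes, and A the mean token count per class. High-weight terms are
frequent inside a topic and rare across the rest of the corpus; they form
the topic's keyword list. Representative documents are the topic members
nearest their centroid in the reduced space (Euclidean distance), and a
further random sample is drawn for prompt diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer, ENGLISH_STOP_WORDS

from .corpus import Corpus
from .embedding import ReducedEmbedding
from .topics import TopicModel

__all__ = [
    "Vocabulary",
    "CTFIDFMatrix",
    "TopicCard",
    "build_vocab",
    "doc_term_counts",
    "ctfidf",
    "top_keywords",
    "select_exemplars",
]

# tokens start alphabetic, length >= 2; digits allowed after the first char
DEFAULT_TOKEN_PATTERN = r"(?u)\b[a-z][a-z0-9]+\b"


@dataclass
class Vocabulary:
    terms: list[str]
    preprocess: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


def _vectorizer(preprocess: dict) -> CountVectorizer:
    stop = preprocess.get("stopwords", "english")
    if stop == "english":
        stop = list(ENGLISH_STOP_WORDS)
    return CountVectorizer(
        lowercase=preprocess.get("lowercase", True),
        stop_words=stop,
        min_df=preprocess.get("min_df", 1),
        token_pattern=preprocess.get("token_pattern", DEFAULT_TOKEN_PATTERN),
        ngram_range=tuple(preprocess.get("ngram_range", (1, 1))),
    )


def build_vocab(corpus: Corpus, preprocess: dict | None = None) -> Vocabulary:
    """Tokenize, lowercase, drop stopwords and low-document-frequency terms."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    preprocess = dict(preprocess or {})
    vec = _vectorizer(preprocess)
    try:
        vec.fit(corpus.texts())
    except ValueError as exc:
        raise ValueError(
            "vocabulary is empty after preprocessing filters "
            f"(min_df={preprocess.get('min_df', 1)}, stopwords="
            f"{preprocess.get('stopwords', 'english')!r}): {exc}"
        ) from exc
    terms = vec.get_feature_names_out().tolist()
    if not terms:
        raise ValueError("vocabulary is empty after preprocessing filters")
    return Vocabulary(terms=terms, preprocess=preprocess)


def doc_term_counts(corpus: Corpus, vocab: Vocabulary) -> sp.csr_matrix:
    """(n_docs, |V|) raw term counts restricted to the vocabulary."""
    vec = _vectorizer(vocab.preprocess)
    vec.set_params(vocabulary=vocab.terms, min_df=1)
    return vec.transform(corpus.texts()).tocsr()


@dataclass
class CTFIDFMatrix:
    W: np.ndarray  # (T, |V|)
    vocab: Vocabulary

    @property
    def T(self) -> int:
        return self.W.shape[0]


def ctfidf(corpus: Corpus, model: TopicModel, vocab: Vocabulary) -> CTFIDFMatrix:
    """Class-based TF-IDF over the concatenated text of each topic."""
    sizes = model.sizes()
    if np.any(sizes == 0):
        raise ValueError(f"empty topic(s): {np.flatnonzero(sizes == 0).tolist()}")
    counts = doc_term_counts(corpus, vocab)
    T = model.T
    # tf[c, t]: term counts summed over the topic's documents
    group = sp.csr_matrix(
        (np.ones(len(corpus)), (model.assignment, np.arange(len(corpus)))),
        shape=(T, len(corpus)),
    )
    tf = np.asarray((group @ counts).todense(), dtype=float)
    f = tf.sum(axis=0)  # total count per term, all classes
    A = tf.sum() / T  # mean token count per class
    with np.errstate(divide="ignore", invalid="ignore"):
        idf = np.log1p(np.where(f > 0, A / np.maximum(f, 1e-300), 0.0))
    W = tf * idf
    return CTFIDFMatrix(W=W, vocab=vocab)


def top_keywords(weights: CTFIDFMatrix, topic: int, k: int = 10) -> list[str]:
    """Top-k terms by descending weight; ties broken lexicographically."""
    row = weights.W[topic]
    terms = weights.vocab.terms
    order = sorted(range(len(terms)), key=lambda i: (-row[i], terms[i]))
    return [terms[i] for i in order[:k] if row[i] > 0]


@dataclass
class TopicCard:
    topic_id: int
    keywords: list[str]
    representative_ids: list[str]
    sample_ids: list[str]
    size: int


def select_exemplars(
    model: TopicModel,
    reduced: ReducedEmbedding,
    corpus: Corpus,
    weights: CTFIDFMatrix,
    n_keywords: int = 10,
    n_representatives: int = 3,
    n_samples: int = 3,
    seed: int = 0,
) -> list[TopicCard]:
    """One card per topic: keywords, nearest-to-centroid representatives
    (ties by discussion id), and a seeded random sample of the rest."""
    ids = corpus.ids()
    rng = np.random.default_rng(seed)
    cards = []
    for t in range(model.T):
        members = model.members(t)
        dists = np.linalg.norm(reduced.vectors[members] - model.centroids[t], axis=1)
        order = sorted(range(len(members)), key=lambda i: (dists[i], ids[members[i]]))
        reps = [ids[members[i]] for i in order[: n_representatives]]
        rest = sorted(set(ids[m] for m in members) - set(reps))
        n_s = min(n_samples, len(rest))
        sample = sorted(rng.choice(rest, size=n_s, replace=False).tolist()) if n_s else []
        cards.append(
            TopicCard(
                topic_id=t,
                keywords=top_keywords(weights, t, n_keywords),
                representative_ids=reps,
                sample_ids=sample,
                size=int(len(members)),
            )
        )
    return cards
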