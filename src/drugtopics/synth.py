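"""Synthetic discussion corpora with known topic, theme and sentiment structure.

The generator emulates the structure the pipeline assumes of a real
social-media dump: short documents drawn from K latent topics (sharp
per-topic multinomials over a shared synthetic vocabulary), topics nested
in a small number of super-themes that share theme-level vocabulary, drug
names injected from the search lexicon at per-category rates, timestamps
concentrated in recent years, repeated authors, and a class-tilted
sentiment lexicon appended per document. Every choice is a deterministic
function of the seed, and the ground truth (topic, theme, sentiment,
injected terms) is returned alongside the corpus so recovery can be scored.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corpus import Corpus, Discussion, DrugLexicon, default_lexicon
from .sentiment import NEGATIVE_WORDS, NEUTRAL_WORDS, POSITIVE_WORDS

__all__ = ["SyntheticSpec", "GroundTruth", "generate_corpus", "adjusted_rand", "write_jsonl"]

_SUBREDDITS = ("r/meds", "r/weightloss", "r/diabetes", "r/health", "r/askdocs")
_SENT_LEX = {"negative": NEGATIVE_WORDS, "neutral": NEUTRAL_WORDS, "positive": POSITIVE_WORDS}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    Defaults mirror the scale and shares of the public GLP-1 RA discussion
    corpus the pipeline targets: a small number of latent topics nested in
    3 super-themes, short documents (negative-binomial length, mean 40),
    weight-loss-active drug mentions dominating the diabetes-only ones
    (~97/3 category split), ~96% of traffic in or after 2022, authors at
    ~0.3 per discussion, and a negative/neutral/positive sentiment mix of
    31.8/50.8/17.4 percent.
    """

    K: int = 8
    n_docs: int = 2000
    vocab_size: int = 500
    doc_length_mean: float = 40.0
    doc_length_dispersion: float = 5.0
    topic_concentration: float = 0.60  # token mass on the topic's own core
    theme_concentration: float = 0.25  # token mass on the theme's shared core
    background_mixture: float = 0.15  # token mass on shared background words
    n_themes: int = 3
    topic_core_size: int = 25
    theme_core_size: int = 20
    drug_mention_rate: dict[str, float] = field(
        default_factory=lambda: {
            "weight_loss_active": 0.90,
            "diabetes_only": 0.27,
            "investigational": 0.04,
        }
    )
    # within-category term weight overrides; remaining mass spread uniformly
    term_weights: dict[str, float] = field(default_factory=lambda: {"ozempic": 0.43})
    year_range: tuple[int, int] = (2019, 2023)
    year_weights: tuple[float, ...] | None = (0.01, 0.01, 0.02, 0.46, 0.50)
    n_authors: int | None = None  # default: 0.3 * n_docs
    post_fraction: float = 0.184
    sentiment_mix: tuple[float, float, float] = (0.318, 0.508, 0.174)
    n_sentiment_words: int = 4
    seed: int = 7

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_docs < self.K:
            raise ValueError("need K >= 1 and n_docs >= K")
        mix = np.asarray(self.sentiment_mix, float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-6:
            raise ValueError("sentiment_mix must be a probability triple summing to 1")
        w = self.topic_concentration + self.theme_concentration + self.background_mixture
        if abs(w - 1.0) > 1e-6:
            raise ValueError("topic + theme + background mixture weights must sum to 1")
        core_need = self.K * self.topic_core_size + self.n_themes * self.theme_core_size
        if self.vocab_size < core_need + 10:
            raise ValueError(
                f"vocab_size={self.vocab_size} too small for {self.K} disjoint topic "
                f"cores and {self.n_themes} theme cores (need > {core_need + 10})"
            )
        if self.year_weights is not None:
            ny = self.year_range[1] - self.year_range[0] + 1
            if len(self.year_weights) != ny:
                raise ValueError(f"year_weights must have {ny} entries")


@dataclass
class GroundTruth:
    true_topic: np.ndarray  # (n,)
    true_theme: np.ndarray  # (n,)
    true_sentiment: list[str]  # (n,)
    true_terms: list[frozenset[str]]  # injected lexicon terms per doc
    theme_of_topic: np.ndarray  # (K,)
    injected_counts: dict[tuple[str, int], int]  # (term, year) bookkeeping

    def to_csv(self, path: str | Path, ids: list[str]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["discussion_id", "true_topic", "true_theme", "true_sentiment", "true_terms"])
            for i, did in enumerate(ids):
                w.writerow(
                    [did, int(self.true_topic[i]), int(self.true_theme[i]),
                     self.true_sentiment[i], "|".join(sorted(self.true_terms[i]))]
                )


def _topic_distributions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """(K, V) token distributions and the theme index of each topic."""
    V, K, B = spec.vocab_size, spec.K, spec.n_themes
    theme_of_topic = np.array([t * B // K for t in range(K)])
    theme_lo = np.arange(B) * spec.theme_core_size
    topic_lo = B * spec.theme_core_size + np.arange(K) * spec.topic_core_size
    bg_lo = B * spec.theme_core_size + K * spec.topic_core_size

    P = np.zeros((K, V))
    for t in range(K):
        P[t, topic_lo[t] : topic_lo[t] + spec.topic_core_size] = (
            spec.topic_concentration / spec.topic_core_size
        )
        th = theme_of_topic[t]
        P[t, theme_lo[th] : theme_lo[th] + spec.theme_core_size] = (
            spec.theme_concentration / spec.theme_core_size
        )
        P[t, bg_lo:] = spec.background_mixture / (V - bg_lo)
    return P, theme_of_topic


def generate_corpus(
    spec: SyntheticSpec, lexicon: DrugLexicon | None = None
) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus and its ground truth from the spec. Deterministic in seed."""
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(spec.seed)
    V, K, n = spec.vocab_size, spec.K, spec.n_docs
    vocab = np.array([f"tok{i:04d}" for i in range(V)])
    P, theme_of_topic = _topic_distributions(spec)

    terms_by_cat: dict[str, list[str]] = {}
    for e in lexicon.entries:
        terms_by_cat.setdefault(e.category, []).append(e.term)
    probs_by_cat: dict[str, np.ndarray] = {}
    for cat, terms in terms_by_cat.items():
        explicit = {t: spec.term_weights[t] for t in terms if t in spec.term_weights}
        rest = [t for t in terms if t not in explicit]
        leftover = 1.0 - sum(explicit.values())
        if leftover < 0 or (not rest and abs(leftover) > 1e-9):
            raise ValueError(f"term_weights for category {cat!r} exceed 1")
        p = np.array([explicit.get(t, leftover / len(rest) if rest else 0.0) for t in terms])
        probs_by_cat[cat] = p / p.sum()

    n_authors = spec.n_authors if spec.n_authors is not None else max(1, round(0.3 * n))
    years = np.arange(spec.year_range[0], spec.year_range[1] + 1)
    yw = None if spec.year_weights is None else np.asarray(spec.year_weights, float)
    if yw is not None:
        yw = yw / yw.sum()

    # negative binomial: mean m, dispersion r -> p = r/(r+m)
    r_disp = spec.doc_length_dispersion
    p_nb = r_disp / (r_disp + spec.doc_length_mean)

    topic_draw = rng.integers(0, K, size=n)
    sent_draw = rng.choice(3, size=n, p=np.asarray(spec.sentiment_mix))
    sent_names = np.array(["negative", "neutral", "positive"])[sent_draw]
    year_draw = rng.choice(years, size=n, p=yw)
    author_draw = rng.integers(0, n_authors, size=n)
    kind_draw = rng.random(n) < spec.post_fraction
    lengths = np.maximum(rng.negative_binomial(r_disp, p_nb, size=n), 5)

    discussions: list[Discussion] = []
    true_terms: list[frozenset[str]] = []
    injected: dict[tuple[str, int], int] = {}
    for i in range(n):
        t = int(topic_draw[i])
        toks = list(vocab[rng.choice(V, size=int(lengths[i]), p=P[t])])
        doc_terms = set()
        for cat in sorted(spec.drug_mention_rate):
            if cat in terms_by_cat and rng.random() < spec.drug_mention_rate[cat]:
                term = str(rng.choice(terms_by_cat[cat], p=probs_by_cat[cat]))
                toks.insert(int(rng.integers(len(toks) + 1)), term)
                doc_terms.add(term)
        sent_words = rng.choice(
            _SENT_LEX[sent_names[i]], size=spec.n_sentiment_words, replace=True
        )
        toks.extend(sent_words)

        year = int(year_draw[i])
        start = int(_dt.datetime(year, 1, 1, tzinfo=_dt.timezone.utc).timestamp())
        end = int(_dt.datetime(year + 1, 1, 1, tzinfo=_dt.timezone.utc).timestamp())
        ts = int(rng.integers(start, end))
        for term in doc_terms:
            injected[(term, year)] = injected.get((term, year), 0) + 1

        discussions.append(
            Discussion(
                id=f"d{i:06d}",
                kind="post" if kind_draw[i] else "comment",
                author_id=f"author{int(author_draw[i]):05d}",
                created_at=ts,
                subreddit=_SUBREDDITS[int(rng.integers(len(_SUBREDDITS)))],
                text=" ".join(toks),
            )
        )
        true_terms.append(frozenset(doc_terms))

    corpus = Corpus(discussions, provenance={"generator": "synthetic", "seed": spec.seed})
    truth = GroundTruth(
        true_topic=topic_draw,
        true_theme=theme_of_topic[topic_draw],
        true_sentiment=list(sent_names),
        true_terms=true_terms,
        theme_of_topic=theme_of_topic,
        injected_counts=injected,
    )
    return corpus, truth


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (range [-0.5, 1])."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Emit the JSONL schema the ingestion loader reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus:
            fh.write(
                json.dumps(
                    {
                        "id": d.id,
                        "kind": d.kind,
                        "author_id": d.author_id,
                        "created_at": d.created_at,
                        "subreddit": d.subreddit,
                        "text": d.text,
                    }
                )
                + "\n"
            )
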