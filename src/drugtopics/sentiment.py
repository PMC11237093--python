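"""Three-class sentiment classification and corpus-level aggregation.

A classifier produces (negative, neutral, positive) probability triples;
the discussion's label is the argmax, with exact ties resolved to neutral.
The shipped classifier is a deterministic lexicon stub (counts of tilted
sentiment words, softmax over counts); a transformer sentiment model can
be plugged in through the same contract where available.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "SentimentResult",
    "SentimentSummary",
    "SentimentClassifier",
    "LexiconSentimentClassifier",
    "POSITIVE_WORDS",
    "NEGATIVE_WORDS",
    "NEUTRAL_WORDS",
    "classify_sentiment",
    "assign_label",
    "aggregate_sentiment",
    "load_plugin_classifier",
]

LABELS = ("negative", "neutral", "positive")

# tilted word lists used by both the lexicon stub and the synthetic generator
NEGATIVE_WORDS = ("awful", "terrible", "hate", "worse", "miserable", "nausea")
NEUTRAL_WORDS = ("update", "question", "info", "dose", "schedule", "refill")
POSITIVE_WORDS = ("great", "love", "amazing", "happy", "better", "thrilled")


@dataclass
class SentimentResult:
    discussion_id: str
    p_negative: float
    p_neutral: float
    p_positive: float
    label: str

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return (self.p_negative, self.p_neutral, self.p_positive)


class SentimentClassifier(Protocol):
    name: str

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray: ...


class LexiconSentimentClassifier:
    """Word-count stub: softmax over tilted-lexicon hit counts per class."""

    name = "lexicon-stub"

    def __init__(self, temperature: float = 1.0):
        self.temperature = temperature
        self._lex = (set(NEGATIVE_WORDS), set(NEUTRAL_WORDS), set(POSITIVE_WORDS))

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), 3))
        for i, text in enumerate(texts):
            toks = text.lower().split()
            counts = np.array([sum(t in lex for t in toks) for lex in self._lex], float)
            z = counts / self.temperature
            z -= z.max()
            e = np.exp(z)
            out[i] = e / e.sum()
        return out


def load_plugin_classifier(model_name: str, max_tokens: int = 512):
    """Load a transformers sequence classifier by name (optional dependency)."""
    try:  # pragma: no cover - optional plugin
        from transformers import pipeline
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the transformer sentiment plugin requires the optional "
            "'transformers' dependency"
        ) from exc

    class _Plugin:  # pragma: no cover - optional plugin
        name = f"transformers:{model_name}"

        def __init__(self):
            self._p = pipeline("text-classification", model=model_name, top_k=None)
            self.max_tokens = max_tokens

        def predict_proba(self, texts):
            order = {"negative": 0, "neutral": 1, "positive": 2}
            res = self._p(list(texts), truncation=True, max_length=self.max_tokens)
            out = np.zeros((len(texts), 3))
            for i, scores in enumerate(res):
                for s in scores:
                    out[i, order[s["label"].lower()]] = s["score"]
            return out

    return _Plugin()


def assign_label(p_negative: float, p_neutral: float, p_positive: float) -> str:
    """Argmax label; exact ties resolve to neutral (conservative)."""
    p = (p_negative, p_neutral, p_positive)
    best = max(p)
    if p[1] == best:
        return "neutral"
    return "negative" if p[0] == best else "positive"


def classify_sentiment(corpus, classifier: SentimentClassifier) -> list[SentimentResult]:
    """Classify every discussion; renormalize near-unit triples (|sum-1| <= 1e-3)."""
    texts = corpus.texts()
    ids = corpus.ids()
    probs = np.asarray(classifier.predict_proba(texts), dtype=float)
    if probs.shape != (len(texts), 3):
        raise ValueError(f"classifier returned shape {probs.shape}, expected ({len(texts)}, 3)")
    results = []
    for i, did in enumerate(ids):
        p = probs[i]
        if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"invalid probabilities for discussion {did!r}: {p.tolist()}")
        s = p.sum()
        if abs(s - 1.0) > 1e-3:
            raise ValueError(f"probabilities for discussion {did!r} sum to {s:.6f}")
        p = p / s
        results.append(
            SentimentResult(
                discussion_id=did,
                p_negative=float(p[0]),
                p_neutral=float(p[1]),
                p_positive=float(p[2]),
                label=assign_label(*p),
            )
        )
    return results


@dataclass
class SentimentSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    n_total: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _round1(x: float) -> float:
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    )


def aggregate_sentiment(results: Sequence[SentimentResult]) -> SentimentSummary:
    """Counts per label and percentages rounded half-up to one decimal."""
    if not results:
        raise ValueError("no sentiment results to aggregate")
    counts = {lab: 0 for lab in LABELS}
    for r in results:
        counts[r.label] += 1
    n = len(results)
    pct = {lab: _round1(100.0 * c / n) for lab, c in counts.items()}
    return SentimentSummary(counts=counts, percentages=pct, n_total=n)


def results_to_csv(results: Sequence[SentimentResult], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["discussion_id", "p_negative", "p_neutral", "p_positive", "label"])
        for r in results:
            w.writerow([r.discussion_id, r.p_negative, r.p_neutral, r.p_positive, r.label])
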