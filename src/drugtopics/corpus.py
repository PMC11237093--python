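"""Corpus ingestion, deduplication and drug-lexicon annotation.

The unit of analysis is a *discussion*: a single social-media post (thread
starter) or comment. Discussions are screened against a lexicon of drug
brand and generic names (here GLP-1 receptor agonists), tabulated by search
term and calendar year, and summarized at the corpus level.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Discussion",
    "LexiconEntry",
    "DrugLexicon",
    "Corpus",
    "HeatmapTable",
    "CorpusSummary",
    "default_lexicon",
    "load_discussions",
    "dedupe",
    "match_terms",
    "tabulate_term_year",
    "summarize",
]

REQUIRED_FIELDS = ("id", "kind", "author_id", "created_at", "subreddit", "text")

#: categories ordered by priority for resolving multi-category discussions
CATEGORY_PRIORITY = ("weight_loss_active", "diabetes_only", "investigational")


class RecordError(ValueError):
    """A malformed input record (carries the 1-based line number)."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Discussion:
    """One post or comment.

    ``created_at`` is stored as UTC epoch seconds. ``matched_terms`` is
    empty until :func:`match_terms` runs.
    """

    id: str
    kind: str  # "post" | "comment"
    author_id: str
    created_at: int
    subreddit: str
    text: str
    matched_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("post", "comment"):
            raise ValueError(f"kind must be 'post' or 'comment', got {self.kind!r}")

    @property
    def year(self) -> int:
        return _dt.datetime.fromtimestamp(self.created_at, tz=_dt.timezone.utc).year


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    generic_name: str
    category: str
    approval_year: int | None = None


@dataclass
class DrugLexicon:
    """Search-term lexicon of drug brand and generic names."""

    entries: list[LexiconEntry]

    def __post_init__(self) -> None:
        terms = [e.term for e in self.entries]
        if len(set(terms)) != len(terms):
            raise ValueError("lexicon terms must be unique")
        for t in terms:
            if t != t.lower():
                raise ValueError(f"lexicon term not lowercase: {t!r}")

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.entries]

    def category_of(self, term: str) -> str:
        for e in self.entries:
            if e.term == term:
                return e.category
        raise KeyError(term)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugLexicon":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                year = row.get("approval_year") or None
                entries.append(
                    LexiconEntry(
                        term=row["term"].strip().lower(),
                        generic_name=row["generic_name"].strip(),
                        category=row["category"].strip(),
                        approval_year=int(year) if year else None,
                    )
                )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "generic_name", "category", "approval_year"])
            for e in self.entries:
                w.writerow([e.term, e.generic_name, e.category, e.approval_year or ""])


def default_lexicon() -> DrugLexicon:
    """The 16-term GLP-1 receptor agonist lexicon shipped with the package."""
    with resources.as_file(resources.files("drugtopics.data") / "lexicon.csv") as p:
        lex = DrugLexicon.from_csv(p)
    assert len(lex.entries) == 16
    return lex


@dataclass
class Corpus:
    discussions: list[Discussion]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.discussions)

    def __iter__(self):
        return iter(self.discussions)

    def texts(self) -> list[str]:
        return [d.text for d in self.discussions]

    def ids(self) -> list[str]:
        return [d.id for d in self.discussions]


def _parse_timestamp(raw, line: int) -> int:
    """Accept epoch seconds (int/float/str) or ISO-8601; return UTC epoch seconds."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return int(raw)
    s = str(raw).strip()
    try:
        return int(float(s))
    except ValueError:
        pass
    try:
        dt = _dt.datetime.fromisoformat(s.replace("Z", "+00:00"))
    except ValueError as exc:
        raise RecordError(line, f"unparseable timestamp {raw!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=_dt.timezone.utc)
    return int(dt.timestamp())


def _record_to_discussion(rec: Mapping, line: int) -> Discussion | None:
    """None means the record was dropped (blank text)."""
    missing = [f for f in REQUIRED_FIELDS if f not in rec or rec[f] is None]
    if missing:
        raise RecordError(line, f"missing required field(s): {', '.join(missing)}")
    text = str(rec["text"])
    if not text.strip():
        return None
    kind = str(rec["kind"]).strip().lower()
    if kind not in ("post", "comment"):
        raise RecordError(line, f"kind must be 'post' or 'comment', got {rec['kind']!r}")
    return Discussion(
        id=str(rec["id"]),
        kind=kind,
        author_id=str(rec["author_id"]),
        created_at=_parse_timestamp(rec["created_at"], line),
        subreddit=str(rec["subreddit"]),
        text=text,
    )


def load_discussions(path: str | Path, format: str | None = None) -> Corpus:
    """Load a discussion corpus from JSONL or CSV.

    Records with empty or whitespace-only text are dropped and counted in
    ``corpus.provenance["load_report"]["dropped"]``. Malformed records raise
    :class:`RecordError` with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")

    discussions: list[Discussion] = []
    dropped = 0
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise RecordError(line_no, f"invalid JSON: {exc}") from exc
                d = _record_to_discussion(rec, line_no)
                if d is None:
                    dropped += 1
                else:
                    discussions.append(d)
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for line_no, rec in enumerate(reader, start=2):  # header is line 1
                d = _record_to_discussion(rec, line_no)
                if d is None:
                    dropped += 1
                else:
                    discussions.append(d)

    return Corpus(
        discussions,
        provenance={
            "source": str(path),
            "format": format,
            "load_report": {"loaded": len(discussions), "dropped": dropped},
        },
    )


def dedupe(corpus: Corpus) -> Corpus:
    """Keep the first occurrence of each discussion id. Idempotent."""
    seen: set[str] = set()
    kept: list[Discussion] = []
    dup_ids: list[str] = []
    for d in corpus:
        if d.id in seen:
            dup_ids.append(d.id)
        else:
            seen.add(d.id)
            kept.append(d)
    prov = dict(corpus.provenance)
    prov["dedupe_report"] = {"removed": len(dup_ids), "duplicate_ids": dup_ids}
    return Corpus(kept, prov)


def _term_pattern(terms: Sequence[str]) -> re.Pattern:
    # word boundaries over alphanumeric-delimited tokens: "ozempic-face"
    # matches, "bozempicx" does not
    alts = "|".join(re.escape(t) for t in sorted(terms, key=len, reverse=True))
    return re.compile(rf"(?<![a-z0-9])({alts})(?![a-z0-9])")


def match_terms(corpus: Corpus, lexicon: DrugLexicon) -> Corpus:
    """Annotate every discussion with the lexicon terms its text contains.

    Matching is case-insensitive and anchored at word boundaries; a single
    discussion may match several terms.
    """
    if not lexicon.entries:
        raise ValueError("lexicon is empty")
    pat = _term_pattern(lexicon.terms)
    out = []
    for d in corpus:
        hits = frozenset(pat.findall(d.text.lower()))
        out.append(
            Discussion(d.id, d.kind, d.author_id, d.created_at, d.subreddit, d.text, hits)
        )
    return Corpus(out, dict(corpus.provenance))


@dataclass
class HeatmapTable:
    """Counts of matching discussions per (search term, calendar year)."""

    cells: dict[tuple[str, int], int]

    def count(self, term: str, year: int) -> int:
        return self.cells.get((term, year), 0)

    def term_total(self, term: str) -> int:
        return sum(v for (t, _), v in self.cells.items() if t == term)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "year", "count"])
            for (term, year), n in sorted(self.cells.items()):
                w.writerow([term, year, n])


def tabulate_term_year(corpus: Corpus, lexicon: DrugLexicon) -> HeatmapTable:
    """Cell (t, y): discussions whose matched terms include t, posted in UTC
    year y. A discussion matching several terms increments every cell."""
    cells: dict[tuple[str, int], int] = {}
    for d in corpus:
        for t in d.matched_terms:
            key = (t, d.year)
            cells[key] = cells.get(key, 0) + 1
    return HeatmapTable(cells)


@dataclass
class CorpusSummary:
    n_total: int
    n_posts: int
    n_comments: int
    n_authors: int
    category_share: dict[str, float]  # percent of matched discussions
    share_after: dict[str, float]  # cutoff ISO date -> percent of discussions

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _round1(x: float) -> float:
    """Round half-up to one decimal (percent reporting convention)."""
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    )


def primary_category(matched: Iterable[str], lexicon: DrugLexicon) -> str | None:
    """Resolve a discussion's category by fixed priority (weight-loss-active
    first) when its matched terms span several lexicon categories."""
    cats = {lexicon.category_of(t) for t in matched}
    for c in CATEGORY_PRIORITY:
        if c in cats:
            return c
    return None


def summarize(
    corpus: Corpus,
    lexicon: DrugLexicon,
    cutoffs: Sequence[_dt.date] = (),
) -> CorpusSummary:
    """Corpus-level counts: posts/comments/authors, category shares over
    matched discussions, and the share of discussions after each cutoff."""
    n_posts = sum(1 for d in corpus if d.kind == "post")
    n_comments = len(corpus) - n_posts
    n_authors = len({d.author_id for d in corpus})

    matched = [d for d in corpus if d.matched_terms]
    cat_counts = {c: 0 for c in CATEGORY_PRIORITY}
    for d in matched:
        c = primary_category(d.matched_terms, lexicon)
        if c is not None:
            cat_counts[c] += 1
    share = {
        c: _round1(100.0 * n / len(matched)) if matched else 0.0
        for c, n in cat_counts.items()
    }

    share_after = {}
    for cut in cutoffs:
        ts = int(
            _dt.datetime(cut.year, cut.month, cut.day, tzinfo=_dt.timezone.utc).timestamp()
        )
        k = sum(1 for d in corpus if d.created_at >= ts)
        share_after[cut.isoformat()] = _round1(100.0 * k / len(corpus)) if len(corpus) else 0.0

    return CorpusSummary(
        n_total=len(corpus),
        n_posts=n_posts,
        n_comments=n_comments,
        n_authors=n_authors,
        category_share=share,
        share_after=share_after,
    )
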