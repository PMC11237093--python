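"""Prompt assembly and LLM labeling of topics and groups.

Topic prompts bundle the topic's keywords with excerpts of representative
discussions (nearest the topic centroid) and randomly sampled ones; group
prompts bundle the labels of the member topics. The generation client is a
one-method contract (text in, text out, plus a name for the manifest), so
a deterministic stub, a file-replay adapter, or a local model can stand
behind it interchangeably. Responses matching configurable refusal
patterns — models decline to label clusters of illicit-drug-sourcing
content, for example — are recorded as refusals, not labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from string import Formatter
from typing import Protocol, Sequence

__all__ = [
    "PromptText",
    "LabelResult",
    "GenerationClient",
    "StubClient",
    "ReplayClient",
    "DEFAULT_TOPIC_TEMPLATE",
    "DEFAULT_GROUP_TEMPLATE",
    "DEFAULT_REFUSAL_PATTERNS",
    "build_topic_prompt",
    "build_group_prompt",
    "label_with_client",
]

DEFAULT_TOPIC_TEMPLATE = """\
You are labeling a topic discovered in social-media discussions about medications.

Topic keywords: {keywords}

Representative discussions (closest to the topic centroid):
{representatives}

Randomly sampled discussions from the topic:
{samples}

Reply with a short, specific topic label (at most eight words) on a single line.
"""

DEFAULT_GROUP_TEMPLATE = """\
You are labeling an overarching theme that spans several discussion topics.

Topic labels in this theme:
{topic_labels}

Reply with a short, specific theme label (at most eight words) on a single line.
"""

DEFAULT_REFUSAL_PATTERNS = (
    "cannot",
    "can't",
    "illegal",
    "i'm not able",
    "i am not able",
    "unable to",
)


@dataclass
class PromptText:
    rendered: str
    template_id: str
    inputs_digest: str


@dataclass
class LabelResult:
    target: str  # e.g. "topic:3" or "group:1"
    status: str  # "labeled" | "refused" | "failed"
    label: str = ""
    raw_response: str = ""


class GenerationClient(Protocol):
    name: str

    def generate(self, prompt: str) -> str: ...


class StubClient:
    """Deterministic stand-in client: maps prompt digest to canned text.

    ``responses`` may be a plain string (returned for everything), a dict
    keyed by inputs digest, or a callable prompt -> text.
    """

    name = "stub-client"

    def __init__(self, responses="Synthetic topic label"):
        self._responses = responses

    def generate(self, prompt: str) -> str:
        r = self._responses
        if callable(r):
            return r(prompt)
        if isinstance(r, dict):
            return r[_digest(prompt)]
        return str(r)


class ReplayClient:
    """Records responses of an inner client to JSONL, or replays a recording."""

    def __init__(self, path: str | Path, inner: GenerationClient | None = None):
        self.path = Path(path)
        self.inner = inner
        self.name = f"replay:{inner.name}" if inner else "replay:file"
        self._cache: dict[str, str] = {}
        if self.path.exists():
            for line in self.path.read_text().splitlines():
                rec = json.loads(line)
                self._cache[rec["digest"]] = rec["response"]

    def generate(self, prompt: str) -> str:
        key = _digest(prompt)
        if key in self._cache:
            return self._cache[key]
        if self.inner is None:
            raise KeyError(f"no recorded response for prompt digest {key}")
        resp = self.inner.generate(prompt)
        self._cache[key] = resp
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps({"digest": key, "response": resp}) + "\n")
        return resp


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _truncate(text: str, limit: int) -> str:
    text = " ".join(text.split())
    return text if len(text) <= limit else text[: limit - 1] + "…"


def _check_placeholders(template: str, required: Sequence[str]) -> None:
    present = {f[1] for f in Formatter().parse(template) if f[1]}
    missing = [p for p in required if p not in present]
    if missing:
        raise ValueError(f"template missing placeholder(s): {', '.join(missing)}")


def build_topic_prompt(
    card,
    texts_by_id: dict[str, str],
    template: str = DEFAULT_TOPIC_TEMPLATE,
    excerpt_chars: int = 500,
) -> PromptText:
    """Render the labeling prompt for one topic card.

    Every keyword and an excerpt (truncated to ``excerpt_chars``) of every
    included discussion appears in the rendered text; rendering is a pure
    function of its inputs.
    """
    if not card.keywords and not card.representative_ids:
        raise ValueError(f"topic {card.topic_id} card is empty")
    _check_placeholders(template, ["keywords", "representatives", "samples"])

    def block(ids):
        if not ids:
            return "(none)"
        return "\n".join(f"- {_truncate(texts_by_id[i], excerpt_chars)}" for i in ids)

    rendered = template.format(
        keywords=", ".join(card.keywords),
        representatives=block(card.representative_ids),
        samples=block(card.sample_ids),
    )
    digest = _digest(json.dumps(
        [card.keywords, card.representative_ids, card.sample_ids], sort_keys=True
    ))
    return PromptText(rendered=rendered, template_id="topic-v1", inputs_digest=digest)


def build_group_prompt(
    topic_results: Sequence[LabelResult],
    template: str = DEFAULT_GROUP_TEMPLATE,
) -> PromptText:
    """Render the labeling prompt for one group from its topics' labels.

    Refused/failed topics are excluded, with a note line; a group whose
    topics were all refused cannot be labeled and raises.
    """
    _check_placeholders(template, ["topic_labels"])
    labeled = [r for r in topic_results if r.status == "labeled"]
    excluded = [r for r in topic_results if r.status != "labeled"]
    if not labeled:
        raise ValueError("every topic in this group was refused or failed; cannot label")
    lines = [f"- {r.label}" for r in labeled]
    if excluded:
        lines.append(f"(note: {len(excluded)} topic(s) excluded: no label available)")
    rendered = template.format(topic_labels="\n".join(lines))
    digest = _digest(json.dumps(sorted(r.label for r in labeled)))
    return PromptText(rendered=rendered, template_id="group-v1", inputs_digest=digest)


def label_with_client(
    prompt: PromptText,
    client: GenerationClient,
    target: str,
    refusal_patterns: Sequence[str] = DEFAULT_REFUSAL_PATTERNS,
    retries: int = 2,
) -> LabelResult:
    """Call the client; parse the first non-empty line as the label.

    Responses matching a refusal pattern (case-insensitive substring) are
    marked ``refused`` with the refusal text preserved. Client exceptions
    are retried; persistent failure yields status ``failed``.
    """
    response = None
    last_exc: Exception | None = None
    for _ in range(retries + 1):
        try:
            response = client.generate(prompt.rendered)
            break
        except Exception as exc:  # client contract: may raise anything
            last_exc = exc
    if response is None:
        return LabelResult(target=target, status="failed", raw_response=repr(last_exc))

    low = response.lower()
    if any(p in low for p in refusal_patterns):
        return LabelResult(target=target, status="refused", raw_response=response)

    label = ""
    for line in response.splitlines():
        line = line.strip().strip('"“”\'').strip()
        if line:
            label = line
            break
    if not label:
        return LabelResult(target=target, status="failed", raw_response=response)
    return LabelResult(target=target, status="labeled", label=label, raw_response=response)
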