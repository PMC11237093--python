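import datetime as dt

import pytest

from drugtopics.corpus import Corpus, Discussion


def ts(year: int, month: int = 6, day: int = 15) -> int:
    return int(dt.datetime(year, month, day, tzinfo=dt.timezone.utc).timestamp())


def make_discussion(
    id="d1", kind="comment", author="a1", year=2022, text="hello world", subreddit="r/meds"
) -> Discussion:
    return Discussion(
        id=id, kind=kind, author_id=author, created_at=ts(year), subreddit=subreddit, text=text
    )


def make_corpus(*texts, **kwargs) -> Corpus:
    return Corpus(
        [make_discussion(id=f"d{i}", text=t, **kwargs) for i, t in enumerate(texts)]
    )


@pytest.fixture
def lexicon():
    from drugtopics.corpus import default_lexicon

    return default_lexicon()
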