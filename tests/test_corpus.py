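import datetime as dt
import json

import pytest

from drugtopics.corpus import (
    Corpus,
    Discussion,
    RecordError,
    dedupe,
    load_discussions,
    match_terms,
    summarize,
    tabulate_term_year,
)

from conftest import make_corpus, make_discussion, ts

RECORDS = [
    {"id": "a", "kind": "post", "author_id": "u1", "created_at": ts(2021),
     "subreddit": "r/meds", "text": "Started Ozempic last week"},
    {"id": "b", "kind": "comment", "author_id": "u2", "created_at": ts(2022),
     "subreddit": "r/meds", "text": "switched from Wegovy to Mounjaro"},
    {"id": "c", "kind": "comment", "author_id": "u1", "created_at": ts(2022),
     "subreddit": "r/health", "text": "no drug mentioned"},
    {"id": "d", "kind": "post", "author_id": "u3", "created_at": ts(2023),
     "subreddit": "r/meds", "text": "trulicity vs ozempic"},
    {"id": "e", "kind": "comment", "author_id": "u3", "created_at": ts(2023),
     "subreddit": "r/meds", "text": "retatrutide trial results"},
]


def write_jsonl(path, records):
    path.write_text("".join(json.dumps(r) + "\n" for r in records))


def write_csv(path, records):
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(records[0]))
        w.writeheader()
        w.writerows(records)


class TestLoad:
    def test_blank_text_records_dropped_and_reported(self, tmp_path):
        recs = RECORDS[:2] + [dict(RECORDS[2], text="   ")]
        p = tmp_path / "c.jsonl"
        write_jsonl(p, recs)
        c = load_discussions(p, "jsonl")
        assert len(c) == 2
        assert c.provenance["load_report"]["dropped"] == 1

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text("")
        assert len(load_discussions(p, "jsonl")) == 0

    def test_csv_and_jsonl_encodings_agree(self, tmp_path):
        pj, pc = tmp_path / "c.jsonl", tmp_path / "c.csv"
        write_jsonl(pj, RECORDS)
        write_csv(pc, RECORDS)
        cj = load_discussions(pj).discussions
        cc = load_discussions(pc).discussions
        assert cj == cc

    def test_missing_field_reports_line_number(self, tmp_path):
        bad = dict(RECORDS[0])
        del bad["author_id"]
        p = tmp_path / "c.jsonl"
        write_jsonl(p, [RECORDS[1], bad])
        with pytest.raises(RecordError, match="line 2.*author_id"):
            load_discussions(p)

    def test_iso_timestamps_accepted(self, tmp_path):
        rec = dict(RECORDS[0], created_at="2022-03-01T12:00:00Z")
        p = tmp_path / "c.jsonl"
        write_jsonl(p, [rec])
        d = load_discussions(p).discussions[0]
        assert d.year == 2022

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_discussions(tmp_path / "absent.jsonl")


class TestDedupe:
    def test_first_occurrence_wins(self):
        c = Corpus([make_discussion(id=i) for i in ["a", "b", "a"]])
        assert dedupe(c).ids() == ["a", "b"]

    def test_all_unique_unchanged(self):
        c = make_corpus("one", "two", "three")
        assert dedupe(c).ids() == c.ids()

    def test_duplicates_reported(self):
        ids = ["a", "b", "c", "a", "d", "b", "e", "f", "g", "a"]
        c = Corpus([make_discussion(id=i) for i in ids])
        out = dedupe(c)
        assert len(out) == 7
        assert out.provenance["dedupe_report"]["duplicate_ids"] == ["a", "b", "a"]

    def test_idempotent(self):
        c = Corpus([make_discussion(id=i) for i in ["a", "b", "a", "c", "b"]])
        once = dedupe(c)
        twice = dedupe(once)
        assert once.ids() == twice.ids()


class TestMatchTerms:
    def test_single_brand_name(self, lexicon):
        c = match_terms(make_corpus("Started Ozempic last week"), lexicon)
        assert c.discussions[0].matched_terms == {"ozempic"}

    def test_no_drug_mentioned(self, lexicon):
        c = match_terms(make_corpus("no drug mentioned"), lexicon)
        assert c.discussions[0].matched_terms == frozenset()

    def test_multiple_terms_in_one_text(self, lexicon):
        c = match_terms(make_corpus("switched from Wegovy to Mounjaro"), lexicon)
        assert c.discussions[0].matched_terms == {"wegovy", "mounjaro"}

    def test_case_insensitive(self, lexicon):
        lo = match_terms(make_corpus("ozempic and wegovy"), lexicon)
        up = match_terms(make_corpus("OZEMPIC AND WEGOVY"), lexicon)
        assert lo.discussions[0].matched_terms == up.discussions[0].matched_terms

    @pytest.mark.parametrize(
        "text,expected",
        [("ozempic-face is a thing", {"ozempic"}), ("bozempicx", set()), ("ozempic2024", set())],
    )
    def test_word_boundaries(self, lexicon, text, expected):
        c = match_terms(make_corpus(text), lexicon)
        assert c.discussions[0].matched_terms == expected


class TestTabulate:
    def test_multi_term_discussion_increments_each_cell(self, lexicon):
        c = match_terms(make_corpus("ozempic wegovy", year=2022), lexicon)
        t = tabulate_term_year(c, lexicon)
        assert t.count("ozempic", 2022) == 1
        assert t.count("wegovy", 2022) == 1

    def test_empty_corpus_gives_empty_table(self, lexicon):
        t = tabulate_term_year(Corpus([]), lexicon)
        assert t.cells == {}

    def test_counts_match_brute_force(self, lexicon):
        texts_years = [
            ("ozempic rocks", 2021), ("ozempic again", 2021), ("wegovy and ozempic", 2022),
            ("saxenda", 2022), ("nothing", 2022), ("ozempic", 2022),
        ]
        c = Corpus([
            make_discussion(id=f"d{i}", text=t, year=y)
            for i, (t, y) in enumerate(texts_years)
        ])
        c = match_terms(c, lexicon)
        table = tabulate_term_year(c, lexicon)
        # brute force over all records
        expect = {}
        for d in c:
            for term in d.matched_terms:
                expect[(term, d.year)] = expect.get((term, d.year), 0) + 1
        assert table.cells == expect
        # row-sum identity
        for term in lexicon.terms:
            assert table.term_total(term) == sum(1 for d in c if term in d.matched_terms)


class TestSummarize:
    def test_total_is_posts_plus_comments(self, lexicon):
        c = Corpus(
            [make_discussion(id=f"p{i}", kind="post") for i in range(3)]
            + [make_discussion(id=f"c{i}", kind="comment") for i in range(5)]
        )
        s = summarize(match_terms(c, lexicon), lexicon)
        assert s.n_total == s.n_posts + s.n_comments == 8

    def test_single_author(self, lexicon):
        c = match_terms(make_corpus("a b", "c d", author="solo"), lexicon)
        assert summarize(c, lexicon).n_authors == 1

    def test_category_shares_hand_computed(self, lexicon):
        # 5 weight-loss-active, 2 diabetes-only, 1 both (-> weight_loss_active)
        texts = ["ozempic", "wegovy", "mounjaro", "saxenda", "semaglutide",
                 "trulicity", "byetta", "ozempic and trulicity"]
        c = match_terms(make_corpus(*texts), lexicon)
        s = summarize(c, lexicon)
        assert s.category_share["weight_loss_active"] == 75.0  # 6/8
        assert s.category_share["diabetes_only"] == 25.0  # 2/8
        assert s.category_share["investigational"] == 0.0

    def test_share_after_cutoff(self, lexicon):
        c = Corpus([
            make_discussion(id=f"d{i}", year=y) for i, y in enumerate([2020, 2022, 2023, 2023])
        ])
        s = summarize(match_terms(c, lexicon), lexicon, cutoffs=[dt.date(2022, 1, 1)])
        assert s.share_after["2022-01-01"] == 75.0
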