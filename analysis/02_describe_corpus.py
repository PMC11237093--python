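#!/usr/bin/env python
"""Tabulate the corpus: drug-term x year heatmap and summary shares.

Writes results/heatmap.csv (long format: term, year, count) and
results/corpus_summary.json, and prints the category and recency shares
that mirror the descriptive claims made about the real corpus.
"""

import datetime as dt
import json

from drugtopics.corpus import summarize, tabulate_term_year
from drugtopics.pipeline import PipelineRun

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()
lex = run.lexicon()

heat = tabulate_term_year(corpus, lex)
heat.to_csv("results/heatmap.csv")

summary = summarize(corpus, lex, cutoffs=[dt.date(2022, 1, 1)])
summary.to_json("results/corpus_summary.json")

print(json.dumps(summary.__dict__, indent=2))
print(f"\nbusiest term-years:")
for (term, year), n in sorted(heat.cells.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {term} {year}: {n}")
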