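#!/usr/bin/env python
"""Represent topics with c-TF-IDF and group them into themes.

Builds the vocabulary, computes class-based TF-IDF per topic, extracts
keyword cards, then clusters the topic vectors with spectral clustering,
choosing the group count by silhouette. Checks the recovered groups
against the 3 planted super-themes.
"""

import csv

import numpy as np

from drugtopics.pipeline import PipelineRun
from drugtopics.synth import adjusted_rand

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()
E = run.stage_embed(corpus)
R = run.stage_reduce(E)
model = run.stage_topics(R, corpus)
weights, cards = run.stage_represent(corpus, model, R)
gm = run.stage_group(weights)

print(f"G={gm.G} groups chosen, silhouette={gm.silhouette:.3f}")
print("scan:", ", ".join(f"G={g}: {s:.3f}" for g, s in gm.scan))
for card in cards[:4]:
    print(f"topic {card.topic_id} (n={card.size}): {', '.join(card.keywords[:6])}")

with open(run.out_dir / "ground_truth.csv") as fh:
    rows = list(csv.DictReader(fh))
true_theme = np.array([int(r["true_theme"]) for r in rows])
theme_of_topic = [
    int(np.bincount(true_theme[model.assignment == t]).argmax()) for t in range(model.T)
]
print(f"adjusted Rand vs planted themes: {adjusted_rand(gm.group_of, theme_of_topic):.3f}")
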