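#!/usr/bin/env python
"""Classify three-class sentiment and aggregate corpus shares.

Runs the lexicon stub classifier over every discussion, assigns the
argmax label, aggregates counts and percentages, and scores accuracy
against the generator's planted sentiment classes.
"""

import csv
import json

import numpy as np

from drugtopics.pipeline import PipelineRun
from drugtopics.sentiment import LexiconSentimentClassifier, classify_sentiment

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()
summary = run.stage_sentiment(corpus)

print(json.dumps(summary.__dict__, indent=2))

with open(run.out_dir / "ground_truth.csv") as fh:
    truth = [r["true_sentiment"] for r in csv.DictReader(fh)]
res = classify_sentiment(corpus, LexiconSentimentClassifier())
acc = float(np.mean([r.label == t for r, t in zip(res, truth)]))
print(f"stub accuracy vs planted sentiment: {acc:.3f}")
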