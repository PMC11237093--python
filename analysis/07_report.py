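#!/usr/bin/env python
"""Render the final report tables for the run.

Writes the heatmap CSV, the 2-D projection scatter (reduced coordinates
with topic and group ids), topic/group tables and corpus summary into
results/run/, and prints where each landed.
"""

from drugtopics.pipeline import PipelineRun

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()
E = run.stage_embed(corpus)
R = run.stage_reduce(E)
model = run.stage_topics(R, corpus)
weights, cards = run.stage_represent(corpus, model, R)
gm = run.stage_group(weights)
run.stage_sentiment(corpus)
files = run.stage_report(corpus, R, model, gm)

for kind, path in files.items():
    print(f"{kind}: {path}")
print(f"manifest: {run.manifest_path}")
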