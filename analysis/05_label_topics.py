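#!/usr/bin/env python
"""Label topics and groups through the pluggable generation client.

Assembles keyword + exemplar prompts per topic and topic-label prompts per
group, sends them to the deterministic stub client, and reports label and
refusal counts. Swap the client in the config to use a local LLM or a
recorded replay file.
"""

from drugtopics.pipeline import PipelineRun

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()
E = run.stage_embed(corpus)
R = run.stage_reduce(E)
model = run.stage_topics(R, corpus)
weights, cards = run.stage_represent(corpus, model, R)
gm = run.stage_group(weights)
results = run.stage_label(corpus, cards, gm)

by_status = {}
for r in results:
    by_status.setdefault(r.status, []).append(r)
print(f"labeled {len(by_status.get('labeled', []))} targets, "
      f"refused {len(by_status.get('refused', []))}, "
      f"failed {len(by_status.get('failed', []))}")
for r in results[: model.T][:5]:
    print(f"  {r.target}: {r.label}")
print(f"labels written to {run.out_dir}/labels.csv")
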