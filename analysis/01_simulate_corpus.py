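#!/usr/bin/env python
"""Generate the synthetic study corpus.

Draws 2,000 discussions from 8 latent topics nested in 3 super-themes,
with drug-name mentions, authors, timestamps and sentiment tilt emulating
the public GLP-1 RA Reddit corpus, and writes the JSONL corpus plus its
ground truth into results/run/.
"""

from drugtopics.pipeline import PipelineRun

run = PipelineRun({"out_dir": "results/run", "corpus": {"synthetic": {"seed": 7}}})
corpus = run.stage_corpus()

n_posts = sum(1 for d in corpus if d.kind == "post")
n_matched = sum(1 for d in corpus if d.matched_terms)
print(f"generated {len(corpus)} discussions "
      f"({n_posts} posts, {len(corpus) - n_posts} comments)")
print(f"{n_matched} mention at least one lexicon drug term")
print(f"artifacts: {run.out_dir}/corpus.jsonl, {run.out_dir}/ground_truth.csv")
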