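# drugtopics

Topic modeling and sentiment analysis of drug-related social-media
discussions, built for pharmacovigilance-style monitoring of public
discourse around medication classes such as GLP-1 receptor agonists
(semaglutide/Ozempic/Wegovy, tirzepatide/Mounjaro, ...). It is aimed at
researchers who want to turn a large dump of posts and comments into a
small set of labeled discussion topics, overarching themes, and a
corpus-level sentiment breakdown — with every stage testable against a
synthetic corpus whose ground truth is known.

## What the pipeline computes

Given a corpus of discussions (posts and comments), the pipeline:

1. **Ingests and deduplicates** records and matches each text against a
   drug-name lexicon (the 16-term GLP-1 RA search lexicon ships as the
   default), tabulating discussion counts per search term and year.
2. **Embeds** each discussion (deterministic signed-hashing bag-of-words
   by default; a transformer sentence embedder can be plugged in) and
   **reduces** the embedding to *k* = 5 dimensions with UMAP.
3. **Discovers topics**: HDBSCAN fixes the number of clusters *T* and
   their centroids; KMeans, initialized at exactly those centroids,
   refines the assignment so every discussion (including density noise)
   lands in a topic.
4. **Represents topics** by class-based TF-IDF. Treating each topic's
   concatenated text as one class document,

   $$W_{c,t} = \mathrm{tf}(t, c)\,\log\!\left(1 + \frac{A}{f(t)}\right),$$

   where tf(*t*,*c*) is the count of term *t* in class *c*, *f*(*t*) its
   total count over all classes, and *A* the mean token count per class.
   Top-weighted terms become the topic's keywords; members nearest the
   centroid (Euclidean distance) become its representative documents.
5. **Groups topics into themes** by spectral clustering of the
   L2-normalized c-TF-IDF rows (cosine affinity), choosing the group
   count *G* that maximizes the mean silhouette coefficient
   $s_i = (b_i - a_i)/\max(a_i, b_i)$.
6. **Labels** topics (keywords + representative and sampled excerpts) and
   groups (member topic labels) through a pluggable text-generation
   client, detecting and recording refusals.
7. **Classifies sentiment** into (negative, neutral, positive)
   probability triples, labels each discussion by argmax (ties → neutral),
   and aggregates counts and percentage shares.

A synthetic-corpus generator (`drugtopics.synth`) plants known topics,
super-themes, drug mentions, timestamps, authors and sentiment tilt, so
recovery of every stage can be scored with the adjusted Rand index.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic conditions (8 topics in 3 themes, 2,000 discussions, seed 7):

```bash
python analysis/01_simulate_corpus.py
python analysis/03_discover_topics.py
python analysis/04_group_themes.py
python analysis/06_sentiment.py
```

prints, in order:

```
generated 2000 discussions (348 posts, 1652 comments)
1869 mention at least one lexicon drug term

discovered T=8 topics (noise at init: 0.0%)
adjusted Rand vs planted topics: 0.997

G=3 groups chosen, silhouette=0.152
scan: G=2: 0.093, G=3: 0.152, G=4: 0.098, G=5: 0.044, G=6: 0.043, G=7: 0.042
adjusted Rand vs planted themes: 1.000

"percentages": {"negative": 31.0, "neutral": 50.8, "positive": 18.3}
stub accuracy vs planted sentiment: 1.000
```

Read: the pipeline recovered all 8 planted topics almost perfectly
(ARI 0.997), the silhouette scan peaked at exactly the 3 planted
super-themes (perfect group recovery), and the sentiment stage reproduced
the planted ~32/51/17 negative/neutral/positive mix. The same stages are
scriptable through the `drugtopics` CLI (`simulate`, `ingest`, `topics`,
`group`, `sentiment`, `report`, `run`, ...), driven by one YAML config,
with every seed and parameter recorded in a run manifest.

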