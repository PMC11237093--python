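# Methods

## Model and procedure

The pipeline treats each discussion (one post or comment) as a document
and proceeds in three stages: representation, clustering, and description.

**Representation.** Documents are embedded into fixed-width vectors. The
default embedder is a signed-hashing bag-of-words: each lowercase
`[a-z0-9]+` token is hashed (keyed BLAKE2b, so independent of the process
hash seed) to one of *d* = 384 buckets with a ±1 sign, and the vector is
L2-normalized. This embedder is deterministic, dependency-free and
adequate for corpora whose topics are lexically separated; a transformer
sentence embedder can be loaded by name through the same contract for
real text, where synonymy matters. Embeddings are reduced to *k* = 5
dimensions with UMAP (cosine metric, 15 neighbors, `min_dist` 0, fixed
seed). Reduction hyperparameters are exposed in the config; *k* = 5 keeps
density estimation well-conditioned while leaving room for more clusters
than a 2-D visualization projection would.

**Topic clustering.** HDBSCAN (`min_cluster_size` defaulting to
max(15, n/500)) supplies the number of topics and, averaging non-noise
members per cluster, their centroids. A single KMeans run initialized at
exactly those centroids (no random restarts, 300 iterations max,
tolerance 1e-4) then refines the assignment. The two-step split matters:
HDBSCAN alone leaves noise points unassigned, while KMeans alone needs
the cluster count supplied; the composition fixes both, and every
discussion ends in exactly one topic. Final empty clusters (possible when
a centroid loses all points) are dropped with contiguous re-indexing.

**Description.** Topic keywords come from class-based TF-IDF
(W[c,t] = tf(t,c) · log(1 + A/f(t)); see README). The vocabulary is built
on stopword-filtered text (the English list shipped with scikit-learn),
tokens alphabetic-initial with length ≥ 2 and document frequency ≥ 2 by
default. Computing c-TF-IDF on filtered rather than raw text is a
package decision — keywords are for human readers, and stopwords carry no
topical signal. Themes are found by spectral clustering of the
L2-normalized topic rows with cosine-similarity affinity, scanning group
counts G in [2, min(T−1, 60)] and keeping the silhouette-maximizing G
(cosine distance in the same space; ties resolve to the smallest G).
Identical topic rows make the affinity degenerate and are reported as an
error rather than silently merged.

**Labeling.** Prompts bundle the topic's keywords with excerpts
(500-character truncation) of its representative documents — members
nearest the topic centroid by Euclidean distance, ties broken by
document id — and a seeded random sample of further members (defaults:
10 keywords, 3 representatives, 3 samples). Group prompts list member
topic labels. The generation client is pluggable; refusals are detected
by a configurable case-insensitive pattern list ("cannot", "illegal",
"i'm not able", ...), since LLMs decline to label clusters dominated by
illicit-drug-sourcing content, and such topics must surface as refusals
rather than vanish.

**Sentiment.** A classifier returns (negative, neutral, positive)
probability triples; triples whose sum deviates from 1 by ≤ 1e-3 are
renormalized, larger deviations are errors. The label is the argmax with
exact ties resolved to neutral — the conservative choice, since a tie
carries no directional evidence. Percentages are rounded half-up to one
decimal. Note: the published corpus-level counts (124,667 / 198,535 /
68,259 of 391,461) yield a neutral share of 50.7%, not the printed 50.1%;
the package reproduces the counts-derived value.

## Synthetic generator

`SyntheticSpec` plants K topics (default 8) nested in 3 super-themes.
Each topic's token distribution puts 0.60 of its mass on a 25-token
private core, 0.25 on its theme's shared 20-token core, and 0.15 on a
common background pool; tokens are synthetic ("tok0001", ...) so no
linguistic resources are needed. Document length is negative-binomial
(mean 40, dispersion 5), mimicking short comments. Drug mentions are
injected per lexicon category (rates 0.90 / 0.27 / 0.04 with
weight-loss-active > diabetes-only > investigational priority), chosen so
the matched-category shares land near the 97/3 split observed in the real
corpus, with "ozempic" up-weighted to ~43% within its category to mirror
its dominance. Year weights put ~96% of documents in 2022–2023; authors
number 0.3 per document; the sentiment mix defaults to 31.8/50.8/17.4
percent with 4 class-tilted lexicon words appended per document. All
draws come from one seeded generator, so corpora are byte-identical under
a fixed seed.

What the generator does **not** emulate: real linguistic variation
(synonymy, spelling errors, sarcasm), thread structure, author-specific
style, bursty posting dynamics, or topics that differ in style rather
than vocabulary. Passing recovery tests therefore show the pipeline's
clustering, weighting and aggregation machinery is correct on lexically
separable structure — not that the hashing embedder or the lexicon
sentiment stub would match transformer models on real text. The stub
classifier recovers planted sentiment almost perfectly *by construction*
(the tilt words are drawn from its own lexicon); its accuracy bound is a
wiring check, not a claim about sentiment analysis.

## Numerical and design choices

- Term matching is case-insensitive at alphanumeric word boundaries
  ("ozempic-face" matches, "bozempicx" does not); deduplication keys on
  the platform-assigned id, first occurrence kept; years are UTC.
- Multi-category discussions count toward the highest-priority category
  (weight-loss-active first) so category shares partition to 100%.
- Keyword tie-breaks are lexicographic; exemplar distance ties break by
  document id; silhouette ties across G resolve to the smallest G.
- Singleton clusters contribute silhouette 0; a single cluster is an
  error (the coefficient is undefined there).
- The pipeline's desk-scale problem size (n = 2,000, K = 8) keeps a full
  run around half a minute on one core while leaving topic sizes large
  enough (~250) for stable density initialization; the acceptance script
  and tests share these conditions.
- Stage outputs are cached by a hash of parameters plus upstream hash;
  reruns with an unchanged config skip completed stages. The manifest
  records every seed, parameter and plugin id; with deterministic
  plugins, identical manifests imply identical outputs.

## Known limitations

- The hashing embedder ignores word order and semantics entirely; on real
  corpora the transformer plugin should be used.
- Spectral clustering's internal k-means stage is seeded but, like UMAP,
  only deterministic for a fixed library version.
- No soft or hierarchical topic assignment; no per-topic sentiment
  breakdown is tested.
- The silhouette value reported for the grouped synthetic topics (~0.15)
  is not comparable across embedding spaces or metrics; it is used only
  to select G.
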