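"""Independent brute-force oracles, written before the implementations they
check. Pure python loops and dicts only — no calls into drugtopics and no
sklearn, so they cannot share a bug with the code under test."""

import math
from collections import Counter


def tokenize(text):
    """Mirror of the default keyword tokenization rule (alphabetic-initial,
    length >= 2, lowercased), restated independently."""
    out, cur = [], []
    for ch in text.lower() + " ":
        if ch.isalnum():
            cur.append(ch)
        else:
            tok = "".join(cur)
            if len(tok) >= 2 and tok[0].isalpha():
                out.append(tok)
            cur = []
    return out


def brute_ctfidf(docs_by_class, vocab):
    """W[c][t] = tf(t,c) * log(1 + A/f(t)); tf over the class's concatenated
    tokens, f the total count over all classes, A the mean tokens per class.
    Only vocabulary terms count as tokens."""
    vset = set(vocab)
    tfs = []
    for docs in docs_by_class:
        cnt = Counter(t for d in docs for t in tokenize(d) if t in vset)
        tfs.append(cnt)
    f = Counter()
    for cnt in tfs:
        f.update(cnt)
    A = sum(f.values()) / len(docs_by_class)
    W = []
    for cnt in tfs:
        W.append([cnt[t] * math.log(1 + A / f[t]) if f[t] else 0.0 for t in vocab])
    return W


def _dist(p, q, metric):
    if metric == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
    dot = sum(a * b for a, b in zip(p, q))
    np_ = math.sqrt(sum(a * a for a in p))
    nq = math.sqrt(sum(b * b for b in q))
    return 1.0 - dot / (np_ * nq)


def brute_silhouette(points, labels, metric="euclidean"):
    """Mean of s_i = (b_i - a_i) / max(a_i, b_i); singleton clusters get 0."""
    n = len(points)
    clusters = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    svals = []
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            svals.append(0.0)
            continue
        a = sum(_dist(points[i], points[j], metric) for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(_dist(points[i], points[j], metric) for j in members) / len(members)
            for lab, members in clusters.items()
            if lab != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return sum(svals) / n


def brute_adjusted_rand(a, b):
    """ARI from the contingency table, straight from the definition."""
    n = len(a)
    table = Counter(zip(a, b))
    rows = Counter(a)
    cols = Counter(b)
    comb = lambda m: m * (m - 1) // 2
    idx = sum(comb(v) for v in table.values())
    ra = sum(comb(v) for v in rows.values())
    cb = sum(comb(v) for v in cols.values())
    expected = ra * cb / comb(n)
    maxidx = (ra + cb) / 2
    if maxidx == expected:
        return 1.0
    return (idx - expected) / (maxidx - expected)
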