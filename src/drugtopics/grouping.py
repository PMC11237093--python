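"""Theme grouping: spectral clustering of topic-level c-TF-IDF vectors.

Topics discovered in embedding space can be separated by style rather than
substance, so overarching themes ("groups") are found by clustering each
topic's c-TF-IDF row instead. The group count is chosen automatically by
scanning a candidate grid and keeping the count that maximizes the mean
silhouette coefficient (cosine distance on L2-normalized rows); ties go to
the smallest count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import SpectralClustering
from sklearn.metrics import pairwise_distances
from sklearn.metrics import silhouette_score as _sk_silhouette

from .representation import CTFIDFMatrix

__all__ = ["GroupModel", "silhouette_score", "group_topics"]


def silhouette_score(X: np.ndarray, labels, metric: str = "euclidean") -> float:
    """Mean silhouette: s_i = (b_i - a_i)/max(a_i, b_i), singletons contribute 0.

    ``a_i`` is the mean distance to the point's own cluster, ``b_i`` the
    smallest mean distance to any other cluster. Raises on fewer than two
    clusters, where the quantity is undefined.
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"metric must be 'euclidean' or 'cosine', got {metric!r}")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(_sk_silhouette(np.asarray(X, dtype=float), labels, metric=metric))


@dataclass
class GroupModel:
    group_of: np.ndarray  # (T,) group index per topic
    G: int
    silhouette: float
    scan: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.group_of, minlength=self.G)


def group_topics(
    weights: CTFIDFMatrix,
    G_range: range | None = None,
    seed: int = 0,
) -> GroupModel:
    """Scan candidate group counts; keep the silhouette-maximizing one.

    Each candidate runs spectral clustering on the cosine-similarity
    affinity of L2-normalized c-TF-IDF rows. Identical topic rows make the
    affinity degenerate and raise, naming the duplicated topics.
    """
    W = np.asarray(weights.W, dtype=float)
    T = W.shape[0]
    if T < 3:
        raise ValueError(f"need at least 3 topics to group, got {T}")
    if G_range is None:
        G_range = range(2, min(T - 1, 60) + 1)
    if min(G_range) < 2 or max(G_range) > T - 1:
        raise ValueError(f"G_range must lie within [2, {T - 1}]")

    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"all-zero c-TF-IDF row(s): {np.flatnonzero(norms.ravel() == 0).tolist()}")
    Wn = W / norms

    D = pairwise_distances(Wn, metric="cosine")
    dup = np.argwhere(np.triu(D < 1e-12, k=1))
    if dup.size:
        pairs = [tuple(int(x) for x in p) for p in dup[:10]]
        raise ValueError(f"degenerate affinity: identical topic rows {pairs}")
    affinity = np.clip(1.0 - D, 0.0, 1.0)

    scan: list[tuple[int, float]] = []
    labels_by_G: dict[int, np.ndarray] = {}
    for G in G_range:
        sc = SpectralClustering(
            n_clusters=G, affinity="precomputed", random_state=seed,
            assign_labels="kmeans",
        )
        labels = sc.fit_predict(affinity)
        s = silhouette_score(Wn, labels, metric="cosine")
        scan.append((int(G), float(s)))
        labels_by_G[int(G)] = labels

    # max silhouette; tie -> smallest G (scan is ascending in G)
    best_G, best_s = max(scan, key=lambda gs: (gs[1], -gs[0]))
    return GroupModel(
        group_of=labels_by_G[best_G], G=int(best_G), silhouette=float(best_s),
        scan=scan, seed=seed,
    )
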