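"""Topic discovery: density-based initialization, centroid-based refinement.

HDBSCAN chooses the number of topics and their initial centroids from the
reduced embedding; points it labels as noise are excluded from centroid
estimation. KMeans, initialized at exactly those centroids with a single
run, then refines the assignment so that every discussion (noise included)
lands in a topic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN, KMeans

from .embedding import ReducedEmbedding

__all__ = ["TopicModel", "init_density", "refine_centroid", "discover_topics"]


@dataclass
class TopicModel:
    assignment: np.ndarray  # (n,) topic index in 0..T-1
    centroids: np.ndarray  # (T, k)
    init_report: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.centroids.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.T)

    def members(self, topic: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == topic)


def default_min_cluster_size(n: int) -> int:
    return max(15, n // 500)


def init_density(
    reduced: ReducedEmbedding,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Density clustering pass.

    Returns ``(T0, centroids0, noise_mask)`` where ``centroids0`` are the
    per-cluster means over non-noise members and ``noise_mask`` flags the
    points HDBSCAN left unassigned.
    """
    X = reduced.vectors
    mcs = min_cluster_size if min_cluster_size is not None else default_min_cluster_size(X.shape[0])
    if X.shape[0] < 2 * mcs:
        raise ValueError(f"need n >= 2*min_cluster_size ({2 * mcs}), got n={X.shape[0]}")
    labels = HDBSCAN(min_cluster_size=mcs, min_samples=min_samples, copy=True).fit_predict(X)
    noise_mask = labels == -1
    cluster_ids = np.unique(labels[~noise_mask])
    if cluster_ids.size == 0:
        raise ValueError(
            "density clustering labeled every point as noise; "
            "try a smaller min_cluster_size"
        )
    centroids0 = np.vstack([X[labels == c].mean(axis=0) for c in cluster_ids])
    return cluster_ids.size, centroids0, noise_mask


def refine_centroid(
    reduced: ReducedEmbedding,
    T0: int,
    centroids0: np.ndarray,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> TopicModel:
    """KMeans refinement from the density-derived count and centroids.

    A single KMeans run (no random restarts) started at ``centroids0``
    assigns *all* points, including density-noise ones. Clusters that end
    up empty are dropped with contiguous re-indexing.
    """
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    X = reduced.vectors
    km = KMeans(
        n_clusters=T0, init=centroids0, n_init=1, max_iter=max_iter, tol=tol,
        random_state=seed,
    )
    labels = km.fit_predict(X)
    occupied = np.unique(labels)
    remap = {old: new for new, old in enumerate(occupied)}
    assignment = np.array([remap[l] for l in labels])
    centroids = km.cluster_centers_[occupied]
    report = {
        "T0": int(T0),
        "T": int(occupied.size),
        "dropped_empty": int(T0 - occupied.size),
        "kmeans_iter": int(km.n_iter_),
        "seed": seed,
    }
    return TopicModel(assignment=assignment, centroids=centroids, init_report=report)


def discover_topics(
    reduced: ReducedEmbedding,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
    seed: int = 0,
) -> TopicModel:
    """Full topic discovery: density init then centroid refinement."""
    T0, centroids0, noise_mask = init_density(reduced, min_cluster_size, min_samples)
    model = refine_centroid(reduced, T0, centroids0, seed=seed)
    model.init_report.update(
        {
            "min_cluster_size": min_cluster_size
            if min_cluster_size is not None
            else default_min_cluster_size(reduced.n),
            "min_samples": min_samples,
            "noise_fraction_at_init": float(noise_mask.mean()),
        }
    )
    return model
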