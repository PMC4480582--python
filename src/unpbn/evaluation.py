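"""Clustering baselines and silhouette-based model-size selection.

k-means (squared-Euclidean objective, many random restarts) and Ward
hierarchical clustering are the proximity-based reference methods the
network-mixture approach is compared against; the average silhouette width
(ASW) selects the number of clusters *within* one method — silhouette widths
are not comparable between different clustering approaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .gbn import Dataset

__all__ = [
    "ClusteringResult",
    "kmeans_cluster",
    "hierarchical_cluster",
    "silhouette_values",
    "average_silhouette_width",
    "asw_model_selection",
    "ModelSizeSelection",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # length n, values in 1..k
    method: str
    k: int
    params: dict = field(default_factory=dict)
    inertia: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and np.unique(self.labels).size != self.k:
            raise ValueError("clustering produced an empty cluster")


def _as_values(data) -> np.ndarray:
    return data.values if isinstance(data, Dataset) else np.asarray(data, dtype=float)


def kmeans_cluster(data, k: int, restarts: int = 500, seed: int = 0) -> ClusteringResult:
    """Best-of-``restarts`` k-means with random starting points and the
    squared-Euclidean within-cluster objective."""
    X = _as_values(data)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= n")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        init="random",
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return ClusteringResult(
        labels=km.labels_ + 1,
        method="kmeans",
        k=k,
        params={"restarts": restarts, "seed": seed},
        inertia=float(km.inertia_),
    )


def hierarchical_cluster(data, k: int) -> ClusteringResult:
    """Ward-linkage agglomeration on Euclidean distances, cut at ``k`` clusters."""
    X = _as_values(data)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= n")
    if n == 1:
        labels = np.ones(1, dtype=np.int64)
    else:
        Z = linkage(X, method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust").astype(np.int64)
    return ClusteringResult(labels=labels, method="hierarchical", k=k, params={"linkage": "ward"})


def silhouette_values(data, labels) -> np.ndarray:
    """Per-observation silhouette values sil(x_i) = (b - a) / max(a, b) with
    Euclidean dissimilarity; singleton clusters get 0 (Rousseeuw's convention).
    Raises if fewer than two clusters are present."""
    X = _as_values(data)
    labels = np.asarray(labels).ravel()
    if labels.size != X.shape[0]:
        raise ValueError("labels length does not match data")
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return silhouette_samples(X, labels, metric="euclidean")


def average_silhouette_width(data, labels) -> float:
    """ASW: the mean of all silhouette values."""
    return float(np.mean(silhouette_values(data, labels)))


@dataclass
class ModelSizeSelection:
    k_best: int
    asw: dict[int, float]
    ties: tuple[int, ...] = ()


def asw_model_selection(data, labelings: dict[int, np.ndarray], tol: float = 1e-12) -> ModelSizeSelection:
    """Pick the number of clusters maximizing ASW among the supplied labelings
    (all from *one* method).  Ties within ``tol`` are reported, with the
    smallest tied k returned as ``k_best``."""
    if len(labelings) < 2:
        raise ValueError("need labelings for at least two values of k")
    asw: dict[int, float] = {}
    for k, lab in labelings.items():
        if np.unique(np.asarray(lab)).size < 2:
            asw[int(k)] = float("nan")  # ASW undefined for a single cluster
        else:
            asw[int(k)] = average_silhouette_width(data, lab)
    valid = {k: v for k, v in asw.items() if np.isfinite(v)}
    if len(valid) < 2:
        raise ValueError("need at least two labelings with >= 2 clusters")
    best = max(valid.values())
    tied = tuple(sorted(k for k, v in valid.items() if best - v <= tol))
    return ModelSizeSelection(k_best=tied[0], asw=asw, ties=tied if len(tied) > 1 else ())
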