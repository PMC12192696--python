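"""Silhouette-guided K-means assignment of individuals to genetic subgroups.

Individuals are clustered on their raw 0/1/2 genotype coordinates with
Euclidean distance (no standardization).  Missing calls are first replaced
by the heterozygote placeholder 1, a deliberately neutral value between the
two homozygotes.  The number of clusters is chosen by scanning k over a
search range (default 2..10), running K-means with 25 random restarts at
each k, and keeping the k with the highest mean silhouette coefficient;
ties break toward smaller k so reference panels stay large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .datatypes import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Silhouette is quadratic in sample count; larger inputs are subsampled.
SILHOUETTE_MAX_INDIVIDUALS = 2000
SILHOUETTE_MAX_MARKERS = 5000


@dataclass
class ClusterAssignment:
    """Result of silhouette-guided K selection."""

    labels: np.ndarray  # (n_individuals,) int in [0, K)
    K: int
    silhouette_by_k: dict[int, float]
    centers: np.ndarray  # (K, n_markers)

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.K)
        if self.K < 1 or (counts == 0).any():
            raise ValidationError("every cluster must be non-empty")


def fill_for_clustering(gm: GenotypeMatrix) -> np.ndarray:
    """Replace missing calls with the heterozygote placeholder 1.

    Returns a float array ready for K-means; observed calls are untouched.
    """
    x = gm.calls.astype(np.float64)
    x[gm.calls == MISSING] = 1.0
    return x


def kmeans_fit(
    X: np.ndarray, k: int, nstart: int = 25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's K-means on Euclidean 0/1/2 coordinates, best of ``nstart`` starts.

    Returns (labels, centers, inertia).
    """
    X = np.asarray(X, dtype=np.float64)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds individual count {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=nstart, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


def mean_silhouette(X: np.ndarray, labels: np.ndarray, seed: int = 0) -> float:
    """Mean silhouette coefficient s(i) = (b-a)/max(a,b) over individuals.

    Singleton clusters contribute s(i) = 0.  Inputs larger than the
    silhouette subsampling thresholds are subsampled (individuals) or
    marker-thinned before the pairwise-distance computation.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("mean_silhouette requires >= 2 clusters")
    rng = np.random.default_rng(seed)
    if X.shape[1] > SILHOUETTE_MAX_MARKERS:
        keep = np.sort(rng.choice(X.shape[1], SILHOUETTE_MAX_MARKERS, replace=False))
        X = X[:, keep]
    if X.shape[0] > SILHOUETTE_MAX_INDIVIDUALS:
        keep = np.sort(rng.choice(X.shape[0], SILHOUETTE_MAX_INDIVIDUALS, replace=False))
        sub_labels = labels[keep]
        if len(np.unique(sub_labels)) < 2:  # degenerate subsample; fall back to full
            keep = np.arange(X.shape[0])
            sub_labels = labels
        return float(np.mean(silhouette_samples(X[keep], sub_labels)))
    return float(np.mean(silhouette_samples(X, labels)))


def select_k(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    nstart: int = 25,
    seed: int = 0,
) -> ClusterAssignment:
    """Scan k in [k_min, k_max] and keep the argmax mean-silhouette clustering.

    Ties break toward smaller k.  With fewer than 3 individuals clustering
    is skipped and a single-cluster assignment returned with a warning.
    The search range is truncated to the individual count minus one
    (silhouette is undefined when every individual is its own cluster).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        logger.warning("fewer than 3 individuals; skipping clustering (K=1)")
        return ClusterAssignment(
            labels=np.zeros(n, dtype=int),
            K=1,
            silhouette_by_k={},
            centers=X.mean(axis=0, keepdims=True),
        )
    k_hi = min(k_max, n - 1)
    best = None
    trace: dict[int, float] = {}
    for k in range(k_min, k_hi + 1):
        labels, centers, _ = kmeans_fit(X, k, nstart=nstart, seed=seed)
        sil = mean_silhouette(X, labels, seed=seed)
        trace[k] = sil
        if best is None or sil > best[0] + 1e-12:  # strict improvement: ties keep smaller k
            best = (sil, k, labels, centers)
    _, k_opt, labels, centers = best
    return ClusterAssignment(labels=labels, K=k_opt, silhouette_by_k=trace, centers=centers)


def enforce_min_cluster_size(
    assignment: ClusterAssignment, X: np.ndarray, min_size: int = 3
) -> ClusterAssignment:
    """Merge clusters smaller than ``min_size`` into their nearest centroid.

    A haplotype-copying reference panel needs at least two other
    individuals, so tiny clusters are folded into their closest neighbour
    before imputation.
    """
    labels = assignment.labels.copy()
    centers = assignment.centers.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) == 1 or counts.min() >= min_size:
            break
        small = uniq[np.argmin(counts)]
        others = uniq[uniq != small]
        d = np.linalg.norm(centers[others] - centers[small], axis=1)
        target = others[np.argmin(d)]
        labels[labels == small] = target
        member = labels == target
        centers[target] = X[member].mean(axis=0)
    # relabel to consecutive 0..K-1 in first-occurrence order
    remap: dict[int, int] = {}
    new_labels = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        new_labels[i] = remap[lab]
    K = len(remap)
    new_centers = np.vstack([X[new_labels == c].mean(axis=0) for c in range(K)])
    return ClusterAssignment(
        labels=new_labels, K=K, silhouette_by_k=dict(assignment.silhouette_by_k), centers=new_centers
    )


class SilhouetteKMeans(BaseEstimator, ClusterMixin):
    """K-means with silhouette-guided selection of the cluster count.

    A scikit-learn style estimator: ``fit(X)`` scans ``k_range``, fits
    K-means with ``nstart`` restarts at each k, and keeps the clustering
    with the highest mean silhouette coefficient.

    Parameters
    ----------
    k_min, k_max : int, default 2 and 10
        Inclusive search range for the cluster count.
    nstart : int, default 25
        Random K-means restarts per k.
    min_cluster_size : int, default 3
        Clusters smaller than this are merged into their nearest
        centroid neighbour after selection (0 disables the guard).
    random_state : int, default 0

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
    n_clusters_ : int
        The selected K.
    silhouette_by_k_ : dict
        Mean silhouette at every searched k.
    cluster_centers_ : ndarray of shape (n_clusters_, n_features)
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        nstart: int = 25,
        min_cluster_size: int = 3,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.nstart = nstart
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if np.isnan(X).any():
            X = X.copy()
            X[np.isnan(X)] = 1.0  # heterozygote placeholder
        assignment = select_k(
            X, k_min=self.k_min, k_max=self.k_max, nstart=self.nstart, seed=self.random_state
        )
        if self.min_cluster_size > 0 and assignment.K > 1:
            assignment = enforce_min_cluster_size(assignment, X, self.min_cluster_size)
        self.labels_ = assignment.labels
        self.n_clusters_ = assignment.K
        self.silhouette_by_k_ = assignment.silhouette_by_k
        self.cluster_centers_ = assignment.centers
        self.assignment_ = assignment
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
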