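"""Spike sorting: PCA feature extraction followed by k-means clustering.

The feature space is the projection of mean-centered waveform snippets
onto their top principal axes (3 by default); units are then separated
with best-of-restarts k-means.  When the cluster count is unknown it is
chosen by a silhouette sweep with a floor below which the snippets are
treated as a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import defaults as d
from .types import WaveformSet


@dataclass(frozen=True)
class FeatureMatrix:
    """PCA scores (n_spikes x n_components) with per-component explained
    variance fractions, ordered non-increasing."""

    scores: np.ndarray
    explained_variance_fraction: np.ndarray


@dataclass(frozen=True)
class SortResult:
    labels: np.ndarray
    k: int
    silhouette: float
    cluster_centroids: np.ndarray


def extract_features(ws: WaveformSet, n_components: int = d.N_PCS
                     ) -> FeatureMatrix:
    """Project mean-centered snippets onto their top principal axes."""
    if ws.n_spikes < 2:
        raise ValueError("need >= 2 snippets")
    if n_components > ws.n_samples:
        raise ValueError("n_components exceeds samples per snippet")
    X = ws.snippets
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant (zero-variance) waveforms")
    n_components = min(n_components, ws.n_spikes)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return FeatureMatrix(scores, pca.explained_variance_ratio_)


def cluster_units(fm: FeatureMatrix, k: int, seed: int = 0,
                  n_restarts: int = d.KMEANS_RESTARTS) -> SortResult:
    """Best-of-restarts k-means assignment; deterministic given ``seed``.

    The silhouette is NaN for k = 1 (undefined).
    """
    n = fm.scores.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds n_spikes = {n}")
    if k == 1:
        centroid = fm.scores.mean(axis=0, keepdims=True)
        return SortResult(np.zeros(n, dtype=int), 1, float("nan"), centroid)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(fm.scores)
    sil = float(silhouette_score(fm.scores, labels)) if k < n else float("nan")
    return SortResult(labels, k, sil, km.cluster_centers_)


def select_k(fm: FeatureMatrix, k_max: int = 8, seed: int = 0,
             n_restarts: int = d.KMEANS_RESTARTS,
             silhouette_floor: float = d.SILHOUETTE_FLOOR) -> int:
    """Cluster count maximizing the mean silhouette over k in [2, k_max],
    falling back to 1 when even the best silhouette sits below the floor
    (the snippets then look like a single unit)."""
    n = fm.scores.shape[0]
    if k_max < 2 or n < 3:
        return 1
    best_k, best_sil = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        sil = cluster_units(fm, k, seed=seed, n_restarts=n_restarts).silhouette
        if sil > best_sil:
            best_k, best_sil = k, sil
    return best_k if best_sil >= silhouette_floor else 1


def sort_waveforms(ws: WaveformSet, n_components: int = d.N_PCS,
                   k: int | None = None, k_max: int = 8, seed: int = 0,
                   n_restarts: int = d.KMEANS_RESTARTS) -> SortResult:
    """Feature extraction + clustering in one call; ``k`` is chosen by the
    silhouette sweep when not given."""
    fm = extract_features(ws, n_components=n_components)
    if k is None:
        k = select_k(fm, k_max=k_max, seed=seed, n_restarts=n_restarts)
    return cluster_units(fm, k, seed=seed, n_restarts=n_restarts)


def match_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Label agreement after the best one-to-one cluster matching
    (Hungarian assignment on the contingency table)."""
    from scipy.optimize import linear_sum_assignment

    labels = np.asarray(labels)
    truth = np.asarray(truth)
    la, lb = np.unique(labels), np.unique(truth)
    table = np.zeros((la.size, lb.size), dtype=int)
    for i, a in enumerate(la):
        for j, b in enumerate(lb):
            table[i, j] = np.sum((labels == a) & (truth == b))
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / labels.size)


class WaveformSorter(ClusterMixin, BaseEstimator):
    """sklearn-style estimator wrapping the PCA + k-means sorting stage.

    Parameters mirror :func:`sort_waveforms`; ``fit`` accepts the raw
    snippet matrix (n_spikes x n_samples).  Fitted attributes:
    ``labels_``, ``k_``, ``silhouette_``, ``features_``,
    ``cluster_centroids_``.
    """

    def __init__(self, n_components: int = d.N_PCS, k: int | None = None,
                 k_max: int = 8, n_restarts: int = d.KMEANS_RESTARTS,
                 random_state: int = 0):
        self.n_components = n_components
        self.k = k
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ws = WaveformSet(X, 1.0, np.arange(X.shape[0], dtype=float))
        fm = extract_features(ws, n_components=self.n_components)
        k = self.k
        if k is None:
            k = select_k(fm, k_max=self.k_max, seed=self.random_state,
                         n_restarts=self.n_restarts)
        result = cluster_units(fm, k, seed=self.random_state,
                               n_restarts=self.n_restarts)
        self.features_ = fm
        self.labels_ = result.labels
        self.k_ = result.k
        self.silhouette_ = result.silhouette
        self.cluster_centroids_ = result.cluster_centroids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
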