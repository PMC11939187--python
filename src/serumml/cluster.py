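"""Unsupervised structure checks and low-dimensional embeddings.

Bisecting K-means (recursive 2-means splits of the highest-inertia cluster)
and BIRCH (clustering-feature tree, threshold 0.5 / branching factor 50, with
an agglomerative global step) are scored against the clinical labels by the
Rand index and adjusted mutual information. PCA / kernel PCA / t-SNE / UMAP
embeddings support 2-D/3-D visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import Birch, BisectingKMeans
from sklearn.decomposition import PCA, KernelPCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_mutual_info_score, rand_score

from .peaks import FeatureMatrix

__all__ = ["ClusteringReport", "bisecting_kmeans", "birch_cluster",
           "concordance", "embed"]


@dataclass
class ClusteringReport:
    method: str
    assignments: np.ndarray
    rand: float
    ami: float
    params: dict


def _matrix(fm, standardize: bool) -> np.ndarray:
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    return X


def bisecting_kmeans(fm, k: int = 2, seed: int = 0,
                     standardize: bool = True) -> np.ndarray:
    """Divisive clustering: repeatedly 2-means-split the cluster with the
    largest within-cluster sum of squares until k clusters exist.

    Features are standardized by default so no single high-abundance peak
    dominates the Euclidean geometry."""
    X = _matrix(fm, standardize)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of samples ({len(X)})")
    if k == 1:
        return np.zeros(len(X), dtype=int)
    model = BisectingKMeans(n_clusters=k, bisecting_strategy="biggest_inertia",
                            n_init=10, random_state=seed)
    return model.fit_predict(X)


def birch_cluster(fm, threshold: float = 0.5, branching_factor: int = 50,
                  k: int = 2, standardize: bool = True) -> np.ndarray:
    """CF-tree clustering with an agglomerative global step over leaf entries.

    The CF-radius threshold (default 0.5) is expressed in standardized-feature
    units: relative peak areas live on a ~1e-2 scale where an absolute 0.5
    radius would swallow the whole cohort into one leaf entry, so features
    are z-scored by default before tree construction."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if branching_factor < 2:
        raise ValueError("branching_factor must be >= 2")
    X = _matrix(fm, standardize)
    if k == 1:
        return np.zeros(len(X), dtype=int)
    model = Birch(threshold=threshold, branching_factor=branching_factor,
                  n_clusters=k)
    return model.fit_predict(X)


def concordance(assignments, labels) -> tuple[float, float]:
    """(Rand index, adjusted mutual information) of a clustering vs labels."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels lengths differ")
    return (float(rand_score(labels, assignments)),
            float(adjusted_mutual_info_score(labels, assignments)))


def embed(fm, method: str = "pca", dims: int = 2, seed: int = 0) -> np.ndarray:
    """Seeded low-dimensional embedding for visualisation.

    PCA components are orthonormal and variance-ordered; KPCA uses an RBF
    kernel; t-SNE and UMAP are stochastic but reproducible for a fixed seed.
    """
    X = _matrix(fm, standardize=False)
    if dims >= X.shape[1]:
        raise ValueError(f"dims={dims} must be smaller than the feature count")
    if method == "pca":
        return PCA(n_components=dims, random_state=seed).fit_transform(X)
    if method == "kpca":
        return KernelPCA(n_components=dims, kernel="rbf",
                         random_state=seed).fit_transform(X)
    if method == "tsne":
        perplexity = min(30.0, max(2.0, (len(X) - 1) / 3.0))
        return TSNE(n_components=dims, random_state=seed, init="pca",
                    perplexity=perplexity).fit_transform(X)
    if method == "umap":
        import umap
        return umap.UMAP(n_components=dims, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}; "
                     "use pca, kpca, tsne or umap")
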