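"""Standardize, project onto principal components by an explained-variance
threshold, and cluster in component space with K-means plus the elbow rule."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PCAProjection:
    n_components: int
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    threshold: float = 0.8


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray
    wcss_curve: dict[int, float]
    seed: int


def standardize(X: np.ndarray) -> np.ndarray:
    """Columns to mean 0, sd 1 (population sd); constant columns become zeros."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant columns standardized to zeros", int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    return (X - mean) / sd_safe


def fit_pca_auto(X: np.ndarray, threshold: float = 0.8) -> PCAProjection:
    """Project onto the smallest component count whose cumulative explained
    variance passes (strictly exceeds) the threshold."""
    X = np.asarray(X, dtype=float)
    full = PCA().fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    above = np.nonzero(cum > threshold)[0]
    if above.size:
        n_components = int(above[0]) + 1
    else:
        n_components = len(cum)
        logger.warning(
            "cumulative explained variance never passes %.3f; capped at %d components",
            threshold, n_components,
        )
    refit = PCA(n_components=n_components).fit(X)
    return PCAProjection(
        n_components=n_components,
        coordinates=refit.transform(X),
        explained_variance_ratio=refit.explained_variance_ratio_,
        threshold=threshold,
    )


def wcss_curve(X: np.ndarray, k_max: int, seed: int = 0) -> dict[int, float]:
    """Within-cluster sum of squares for k = 1..k_max."""
    X = np.asarray(X, dtype=float)
    k_max = min(k_max, X.shape[0])
    curve = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        curve[k] = float(km.inertia_)
    return curve


def choose_k_elbow(curve: dict[int, float]) -> int:
    """Knee of the WCSS curve: the k at maximum perpendicular distance from
    the chord joining the first and last curve points.

    A (near-)linear curve has no knee; k=1 is returned with a warning.
    """
    ks = np.array(sorted(curve))
    if ks.size < 3:
        raise ValueError("need a curve over at least 3 values of k")
    w = np.array([curve[k] for k in ks], dtype=float)
    p1 = np.array([ks[0], w[0]])
    p2 = np.array([ks[-1], w[-1]])
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    if norm == 0:
        logger.warning("flat WCSS curve; returning k=1")
        return 1
    pts = np.column_stack([ks, w]) - p1
    dist = np.abs(chord[0] * pts[:, 1] - chord[1] * pts[:, 0]) / norm
    if np.all(dist < 1e-9 * max(1.0, np.abs(w).max())):
        logger.warning("WCSS curve is linear; no elbow, returning k=1")
        return 1
    return int(ks[np.argmax(dist)])


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """Seed-deterministic K-means (multiple restarts); labels are
    canonicalized so that label 0 is the largest cluster."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    # descending size, stable for ties
    order = np.lexsort((np.arange(k), -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return ClusterAssignment(
        k=k, labels=remap[labels], wcss_curve={k: float(km.inertia_)}, seed=seed
    )


def cluster_pipeline(
    X: np.ndarray,
    *,
    threshold: float = 0.8,
    k_max: int = 10,
    k: int | None = None,
    seed: int = 0,
) -> tuple[PCAProjection, ClusterAssignment]:
    """Standardize -> PCA at the variance threshold -> elbow-chosen K-means."""
    Z = standardize(X)
    proj = fit_pca_auto(Z, threshold=threshold)
    curve = wcss_curve(proj.coordinates, k_max=k_max, seed=seed)
    chosen = k if k is not None else choose_k_elbow(curve)
    assignment = kmeans_cluster(proj.coordinates, chosen, seed=seed)
    assignment.wcss_curve = curve
    return proj, assignment
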