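"""K-medoids clustering, spectral embedding and gap-statistic model selection.

Cells are points, genes are features.  The default dissimilarity is
1 - Pearson correlation across the current gene subspace; Euclidean distance
is available as an option.  K-medoids is written here because no installed
package provides it; the implementation is the standard alternating
(Voronoi) iteration with greedy k-medoids++-style seeding, deterministic
given a seed.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import pairwise_distances

from .matrix import ClusterAssignment, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["pairwise_dissimilarity", "kmedoids", "kmedoids_cluster", "spectral_embedding", "gap_statistic_k"]


def pairwise_dissimilarity(points: np.ndarray, metric: str = "correlation") -> np.ndarray:
    """Symmetric dissimilarity matrix between rows of ``points``."""
    if metric not in ("correlation", "euclidean"):
        raise ValueError("metric must be 'correlation' or 'euclidean'")
    if metric == "correlation":
        # guard constant rows, for which Pearson correlation is undefined
        spread = points.std(axis=1)
        if np.any(spread == 0):
            points = points + 1e-12 * np.random.default_rng(0).standard_normal(points.shape)
    d = pairwise_distances(points, metric=metric)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _seed_medoids(dist: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    n = dist.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        closest = dist[:, medoids].min(axis=1)
        closest[medoids] = 0.0
        total = closest.sum()
        if total <= 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
        else:
            medoids.append(int(rng.choice(n, p=closest / total)))
    return medoids


def kmedoids(
    dist: np.ndarray, k: int, seed: int = 0, max_iter: int = 300, n_init: int = 10
) -> np.ndarray:
    """Cluster via alternating k-medoids on a precomputed dissimilarity matrix.

    Runs ``n_init`` seeded restarts and keeps the solution with the lowest
    total point-to-medoid dissimilarity (the alternating iteration is prone to
    local optima).  Returns integer labels in [0, k).  Deterministic for a
    given seed.
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    master = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(max(1, n_init)):
        labels, medoids = _kmedoids_once(dist, k, master, max_iter)
        cost = dist[np.arange(n), np.asarray(medoids)[labels]].sum()
        if cost < best_cost - 1e-12:
            best_labels, best_cost = labels, cost
    return best_labels


def _kmedoids_once(dist, k, rng, max_iter):
    n = dist.shape[0]
    medoids = _seed_medoids(dist, k, rng)
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        # update step: each medoid minimizes total dissimilarity in its cluster
        new_medoids = list(medoids)
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                # revive an empty cluster with the point farthest from its medoid
                far = int(np.argmax(dist[np.arange(n), np.asarray(medoids)[labels]]))
                new_medoids[c] = far
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[np.argmin(within)])
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if new_medoids == medoids and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids


def spectral_embedding(
    dist: np.ndarray, n_components: int, n_neighbors: int = 15
) -> np.ndarray:
    """Leading eigenvectors of the normalized k-nearest-neighbor affinity graph.

    The affinity is the symmetrized binary kNN graph built from the given
    dissimilarity matrix; rows of the returned embedding are unit-normalized.
    """
    n = dist.shape[0]
    n_neighbors = min(n_neighbors, n - 1)
    n_components = min(n_components, n - 1)
    affinity = np.zeros((n, n))
    order = np.argsort(dist, axis=1)
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:n_neighbors]
        affinity[i, neighbors] = 1.0
    affinity = np.maximum(affinity, affinity.T)
    degree = affinity.sum(axis=1)
    degree[degree == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    lap = np.eye(n) - d_inv_sqrt[:, None] * affinity * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(lap)
    emb = vecs[:, np.argsort(vals)[:n_components]]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms


def kmedoids_cluster(
    matrix: ExpressionMatrix,
    k: int,
    metric: str = "correlation",
    embedding: str = "none",
    seed: int = 0,
    genes: list[str] | None = None,
    n_components: int | None = None,
    label_prefix: str = "c",
) -> ClusterAssignment:
    """K-medoids clustering of the samples of an expression matrix.

    ``genes`` restricts the feature space (e.g. to the current
    transition/marker subspace); ``embedding='spectral'`` clusters in the
    spectral embedding of the kNN affinity graph instead of raw distances.
    """
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({matrix.n_samples})")
    sub = matrix
    if genes is not None:
        from .matrix import restrict_to_genes

        sub = restrict_to_genes(matrix, list(genes))
    points = sub.values.T  # samples x genes
    dist = pairwise_dissimilarity(points, metric=metric)
    if embedding == "spectral":
        emb = spectral_embedding(dist, n_components or k)
        dist = pairwise_dissimilarity(emb, metric="euclidean")
    elif embedding != "none":
        raise ValueError("embedding must be 'none' or 'spectral'")
    labels = kmedoids(dist, k, seed=seed)
    return ClusterAssignment(
        {s: f"{label_prefix}{labels[j]}" for j, s in enumerate(matrix.sample_ids)}
    )


def _within_dispersion(dist_sq: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        if members.size > 1:
            total += dist_sq[np.ix_(members, members)].sum() / (2.0 * members.size)
    return total


def gap_statistic_k(
    matrix: ExpressionMatrix | np.ndarray,
    k_max: int = 10,
    n_refs: int = 10,
    seed: int = 0,
    metric: str = "euclidean",
    n_init: int = 10,
) -> int:
    """Choose the number of clusters by the gap statistic.

    Compares log within-cluster dispersion against ``n_refs`` reference
    datasets drawn uniformly over the observed feature ranges, and returns the
    smallest K with Gap(K) >= Gap(K+1) - s_{K+1}.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    points = matrix.values.T if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    n = points.shape[0]
    if np.allclose(points, points[0]):
        logger.warning("gap_statistic_k: all points identical; returning K=1")
        return 1
    k_max = min(k_max, n - 1)
    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)

    def dispersions(data: np.ndarray, child_seed: int) -> np.ndarray:
        dist = pairwise_dissimilarity(data, metric=metric)
        dist_sq = dist**2
        out = np.empty(k_max + 1)
        for k in range(1, k_max + 2):
            if k > data.shape[0]:
                out[k - 1 :] = np.finfo(float).tiny
                break
            labels = kmedoids(dist, k, seed=child_seed, n_init=n_init)
            out[k - 1] = max(_within_dispersion(dist_sq, labels), np.finfo(float).tiny)
        return np.log(out)

    log_w = dispersions(points, int(rng.integers(2**31)))
    log_w_ref = np.empty((n_refs, k_max + 1))
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=points.shape)
        log_w_ref[b] = dispersions(ref, int(rng.integers(2**31)))
    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    for k in range(1, k_max + 1):
        if gap[k - 1] >= gap[k] - s[k]:
            return k
    return k_max
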