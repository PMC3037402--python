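"""Reliability of the ICA decomposition.

Two checks are provided: an ICASSO-style resampling analysis (repeated
Infomax runs on bootstrapped data, cross-run clustering of components,
per-cluster stability index) and the spatial correlation of components
across independently analysed cohorts.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .core import InvalidArgumentError
from .gica import ComponentSet, infomax, zscore_maps

__all__ = ["IcassoStability", "icasso", "cross_cohort_similarity"]


def _abs_corr(maps: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between rows, clipped to [0, 1]."""
    z = zscore_maps(maps)
    sim = np.abs(z @ z.T) / z.shape[1]
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def icasso(
    X: np.ndarray,
    K: int,
    n_runs: int = 10,
    seed: int = 0,
    bootstrap: bool = True,
    max_iter: int = 512,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Repeated-Infomax stability analysis of an M x N concatenated matrix.

    Infomax is run ``n_runs`` times with different initial update orders
    and (optionally) time-row bootstrap resamples of X.  All runs'
    component maps are pooled, their pairwise similarity is the absolute
    spatial correlation, and average-linkage agglomerative clustering
    partitions the pool into K clusters.  Each cluster's stability index
    is its average intra-cluster similarity minus its average similarity
    to out-of-cluster components (in [-1, 1]; 1 means perfectly
    reproducible and isolated).  The canonical map of each cluster is
    its centrotype: the member with the largest within-cluster
    similarity sum.

    Returns (stability, centrotypes, info): stability sorted descending,
    centrotypes as a K x N array aligned with it.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_runs < 2:
        raise InvalidArgumentError(f"n_runs must be >= 2, got {n_runs}")
    if K * n_runs < 4:
        raise InvalidArgumentError("component pool too small for clustering")
    rng = np.random.default_rng(seed)
    pool = []
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    for r in range(n_runs):
        Xr = X
        if bootstrap and r > 0:   # first run on the original data
            rows = rng.integers(0, X.shape[0], size=X.shape[0])
            Xr = X[rows]
        maps, _, _ = infomax(Xr, K, seed=int(run_seeds[r]), max_iter=max_iter, tol=tol)
        pool.append(maps)
    pooled = np.vstack(pool)                      # (n_runs*K, N)
    sim = _abs_corr(pooled)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Zl = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Zl, t=K, criterion="maxclust")

    stability = np.empty(K)
    centrotypes = np.empty((K, pooled.shape[1]))
    sizes = np.empty(K, dtype=int)
    for c in range(1, K + 1):
        members = np.where(labels == c)[0]
        others = np.where(labels != c)[0]
        intra = sim[np.ix_(members, members)].mean()
        extra = sim[np.ix_(members, others)].mean() if len(others) else 0.0
        stability[c - 1] = intra - extra
        within_sums = sim[np.ix_(members, members)].sum(axis=1)
        centrotypes[c - 1] = pooled[members[np.argmax(within_sums)]]
        sizes[c - 1] = len(members)
    order = np.argsort(stability)[::-1]
    info = {"cluster_sizes": sizes[order], "n_runs": n_runs, "pool_size": pooled.shape[0]}
    return stability[order], zscore_maps(centrotypes[order]), info


class IcassoStability(BaseEstimator):
    """Estimator wrapper around :func:`icasso`.

    Attributes (after ``fit`` on an M x N concatenated matrix):
    ``stability_`` (K,), ``centrotypes_`` (K, N) Z-scored, ``info_``.
    """

    def __init__(self, n_components: int = 40, n_runs: int = 10, bootstrap: bool = True,
                 random_state: int = 0, max_iter: int = 512, tol: float = 1e-6):
        self.n_components = n_components
        self.n_runs = n_runs
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y=None) -> "IcassoStability":
        self.stability_, self.centrotypes_, self.info_ = icasso(
            X,
            self.n_components,
            n_runs=self.n_runs,
            seed=self.random_state,
            bootstrap=self.bootstrap,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return self


def cross_cohort_similarity(
    setA: ComponentSet | np.ndarray, setB: ComponentSet | np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Spatial correlation between two component sets in the same voxel space.

    Returns the K_A x K_B Pearson correlation matrix of the Z-scored
    maps and a greedy one-to-one match list of (i_A, i_B, r) pairs in
    descending |r| order.
    """
    mapsA = setA.group_maps if isinstance(setA, ComponentSet) else np.asarray(setA)
    mapsB = setB.group_maps if isinstance(setB, ComponentSet) else np.asarray(setB)
    if mapsA.shape[1] != mapsB.shape[1]:
        raise InvalidArgumentError(
            f"component sets live in different voxel spaces: {mapsA.shape[1]} vs {mapsB.shape[1]}"
        )
    zA, zB = zscore_maps(mapsA), zscore_maps(mapsB)
    R = (zA @ zB.T) / zA.shape[1]
    matches: list[tuple[int, int, float]] = []
    absr = np.abs(R.copy())
    for _ in range(min(R.shape)):
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        matches.append((int(i), int(j), float(R[i, j])))
        absr[i, :] = -1.0
        absr[:, j] = -1.0
    return R, matches
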