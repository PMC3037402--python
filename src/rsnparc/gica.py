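"""Group spatial ICA: PCA reduction, temporal concatenation, Infomax
unmixing, back-reconstruction of subject maps/time courses, Z-scoring.

The group model follows the temporal-concatenation scheme: each
subject's ``T x N`` matrix is reduced to ``C`` temporal dimensions by
PCA, the reduced matrices are stacked vertically into an ``M x N``
matrix (M = n_subjects x C), and spatially independent components are
estimated by Infomax ICA with a logistic nonlinearity and natural
gradient updates.  Subject maps and time courses are recovered by
partitioning the group mixing matrix into per-subject blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import InvalidArgumentError, RsnparcError

__all__ = [
    "ReducedData",
    "ComponentSet",
    "GroupICA",
    "pca_reduce",
    "concatenate",
    "infomax",
    "back_reconstruct",
    "zscore_maps",
]


class InvalidDimensionError(RsnparcError):
    pass


@dataclass
class ReducedData:
    """Per-subject PCA reductions: ``reduced[i]`` is C x N, ``bases[i]`` is T_i x C
    with orthonormal columns, ``singular_values[i]`` the retained singular values."""

    reduced: list[np.ndarray]
    bases: list[np.ndarray]
    singular_values: list[np.ndarray]
    discarded_variance: list[float]
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.reduced)

    @property
    def C(self) -> int:
        return self.reduced[0].shape[0]


@dataclass
class ComponentSet:
    """Group ICA output: Z-scored group maps plus per-subject partitions."""

    group_maps: np.ndarray                      # K x N, Z-scored rows
    mixing: np.ndarray                          # M x K
    subject_maps: list[np.ndarray]              # each K x N
    subject_timecourses: list[np.ndarray]       # each T x K
    subject_ids: list[str]
    stability: np.ndarray | None = None         # per-component index in [-1, 1]
    converged: bool = True
    n_iter: int = 0
    degenerate: np.ndarray | None = None        # flags for zero-variance maps

    @property
    def K(self) -> int:
        return self.group_maps.shape[0]


def pca_reduce(matrices: list[np.ndarray], C: int, subject_ids: list[str] | None = None) -> ReducedData:
    """Reduce each subject's T x N matrix to its top-C temporal subspace.

    The reduced matrix ``B^T X`` spans the top-C variance subspace of the
    time covariance; the squared reconstruction error equals the sum of
    discarded eigenvalues of ``X X^T``.
    """
    if not matrices:
        raise InvalidArgumentError("no subject matrices given")
    reduced, bases, svals, discarded = [], [], [], []
    for X in matrices:
        X = np.asarray(X, dtype=np.float64)
        if C > X.shape[0]:
            raise InvalidDimensionError(f"C={C} exceeds time length {X.shape[0]}")
        if C > X.shape[1]:
            raise InvalidDimensionError(
                f"C={C} exceeds voxel count {X.shape[1]}; reduction rank is limited by both axes"
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        bases.append(U[:, :C])
        svals.append(s[:C])
        reduced.append(s[:C, None] * Vt[:C])
        discarded.append(float((s[C:] ** 2).sum()))
    ids = subject_ids if subject_ids is not None else [f"sub-{i:03d}" for i in range(len(matrices))]
    return ReducedData(reduced, bases, svals, discarded, list(ids))


def concatenate(reduced: ReducedData) -> np.ndarray:
    """Stack per-subject reduced matrices vertically into M x N (M = n_subjects x C)."""
    ns = {r.shape[1] for r in reduced.reduced}
    if len(ns) != 1:
        raise InvalidArgumentError(f"inconsistent voxel counts across subjects: {sorted(ns)}")
    return np.vstack(reduced.reduced)


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -30, 30)))


def infomax(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    lr: float | None = None,
    block: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Infomax spatial ICA of an M x N matrix.

    X is row-centered and whitened internally to K dimensions; sources
    (spatial maps) are the rows of the returned ``maps`` (K x N) and the
    mixing matrix (M x K) satisfies ``X ~ mixing @ maps`` up to the
    discarded PCA residual.  The natural-gradient update with a logistic
    nonlinearity favors super-Gaussian (sparse) spatial sources.  The
    learning rate is annealed when the update blows up; convergence is
    declared when the relative weight change per pass falls below
    ``tol``.  Component signs are canonicalized to nonnegative map
    skewness.

    Returns (maps, mixing, info) where info reports convergence.
    """
    X = np.asarray(X, dtype=np.float64)
    m, n = X.shape
    if K > m:
        raise InvalidDimensionError(f"K={K} exceeds M={m}")
    rng = np.random.default_rng(seed)
    row_mean = X.mean(axis=1, keepdims=True)
    Xc = X - row_mean
    cov = (Xc @ Xc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:K]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 1e-12)
    wh = evecs / np.sqrt(evals)           # M x K; whitening = wh.T
    dewh = evecs * np.sqrt(evals)         # M x K; de-whitening
    Z = wh.T @ Xc                         # K x N, identity covariance

    W = np.eye(K)
    lr = 0.01 / np.log(K + 2) if lr is None else lr
    block = max(8, int(np.sqrt(n / 3))) if block is None else block
    eye = np.eye(K)
    converged = False
    n_iter = 0
    delta = np.inf
    for it in range(max_iter):
        n_iter = it + 1
        W_prev = W.copy()
        perm = rng.permutation(n)
        blown = False
        for start in range(0, n, block):
            idx = perm[start : start + block]
            u = W @ Z[:, idx]
            y = _logistic(u)
            grad = (len(idx) * eye + (1.0 - 2.0 * y) @ u.T) @ W
            W = W + (lr / len(idx)) * grad
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                blown = True
                break
        if blown:
            lr *= 0.5
            W = W_prev
            continue
        prev_delta = delta
        delta = np.linalg.norm(W - W_prev) / max(np.linalg.norm(W_prev), 1e-12)
        if delta < tol:
            converged = True
            break
        # anneal when the update stops shrinking (oscillation at the lr
        # scale), plus a mild unconditional decay after burn-in so the
        # stochastic updates settle below tol
        if np.isfinite(prev_delta) and delta >= prev_delta:
            lr *= 0.9
        if it >= 64:
            lr *= 0.985
    if not converged:
        warnings.warn(
            f"Infomax did not reach tol={tol} within {n_iter} passes (last relative "
            f"update {delta:.2e}); returning current estimate",
            RuntimeWarning,
        )
    maps = W @ Z                          # K x N
    mixing = dewh @ np.linalg.inv(W)      # M x K
    # unit-variance source normalization, then nonnegative-skewness sign
    sd = maps.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    maps = maps / sd[:, None]
    mixing = mixing * sd[None, :]
    flip = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    mixing = mixing * flip[None, :]
    info = {"converged": converged, "n_iter": n_iter, "final_delta": float(delta)}
    return maps, mixing, info


def back_reconstruct(
    mixing: np.ndarray, reduced: ReducedData, maps: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Recover per-subject maps and time courses from the group mixing matrix.

    The group mixing matrix is partitioned into consecutive per-subject
    C x K blocks A_i.  Subject time courses are ``bases_i @ A_i`` (T x K)
    and subject maps are ``pinv(A_i) @ reduced_i`` (K x N).  With a
    single subject this degenerates to ordinary ICA.
    """
    m, K = mixing.shape
    C = reduced.C
    if m != reduced.n_subjects * C:
        raise InvalidArgumentError(
            f"mixing has {m} rows but expected {reduced.n_subjects} subjects x C={C}"
        )
    subj_maps, subj_tcs = [], []
    for i in range(reduced.n_subjects):
        A_i = mixing[i * C : (i + 1) * C]
        subj_tcs.append(reduced.bases[i] @ A_i)
        subj_maps.append(np.linalg.pinv(A_i) @ reduced.reduced[i])
    return subj_maps, subj_tcs


def zscore_maps(maps: np.ndarray, return_degenerate: bool = False):
    """Z-score each component map over voxels (population SD).

    Zero-variance rows are flagged degenerate and returned as zeros.
    """
    maps = np.asarray(maps, dtype=np.float64)
    mean = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (maps - mean) / sd
    z[degenerate] = 0.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance component map(s) flagged degenerate")
    if return_degenerate:
        return z, degenerate
    return z


class GroupICA(BaseEstimator):
    """Temporal-concatenation group spatial ICA estimator.

    Parameters
    ----------
    n_components : int
        Number of group independent components K (the reference
        full-size analysis uses 40).
    n_reduced : int or None
        Per-subject retained PCA dimensions C; defaults to
        ``n_components``.
    max_iter, tol : Infomax stopping controls.
    random_state : int
        Seed for the Infomax update ordering.

    Attributes
    ----------
    components_ : (K, N) Z-scored group spatial maps.
    mixing_ : (M, K) group mixing matrix, M = n_subjects * C.
    subject_maps_ : list of (K, N) per-subject Z-scored maps.
    subject_timecourses_ : list of (T, K) per-subject time courses.
    converged_, n_iter_ : Infomax convergence report.
    """

    def __init__(
        self,
        n_components: int = 40,
        n_reduced: int | None = None,
        max_iter: int = 512,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_reduced = n_reduced
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: list[np.ndarray], y=None, subject_ids: list[str] | None = None) -> "GroupICA":
        """Fit on a list of per-subject ``T x N`` matrices."""
        C = self.n_reduced if self.n_reduced is not None else self.n_components
        reduced = pca_reduce([np.asarray(x) for x in X], C, subject_ids=subject_ids)
        M = concatenate(reduced)
        maps, mixing, info = infomax(
            M, self.n_components, seed=self.random_state, max_iter=self.max_iter, tol=self.tol
        )
        subj_maps, subj_tcs = back_reconstruct(mixing, reduced, maps)
        self.reduced_ = reduced
        self.components_, self.degenerate_ = zscore_maps(maps, return_degenerate=True)
        self.mixing_ = mixing
        self.subject_maps_ = [zscore_maps(sm) for sm in subj_maps]
        self.subject_timecourses_ = subj_tcs
        self.converged_ = info["converged"]
        self.n_iter_ = info["n_iter"]
        return self

    def to_component_set(self, stability: np.ndarray | None = None) -> ComponentSet:
        return ComponentSet(
            group_maps=self.components_,
            mixing=self.mixing_,
            subject_maps=self.subject_maps_,
            subject_timecourses=self.subject_timecourses_,
            subject_ids=self.reduced_.subject_ids,
            stability=stability,
            converged=self.converged_,
            n_iter=self.n_iter_,
            degenerate=self.degenerate_,
        )
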