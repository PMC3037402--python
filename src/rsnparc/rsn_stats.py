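"""Voxelwise group statistics on back-reconstructed component maps.

Within-group one-sample t maps build an intersection analysis mask;
between-group differences use a per-voxel general linear model (group
indicator plus a motion covariate); clusters of suprathreshold voxels
are screened by a minimum extent (k >= 5) and a permutation-based
family-wise-error correction on maximum cluster extent; clinical
correlations are assessed around a-priori peaks inside a small-volume
sphere with Bonferroni correction over in-sphere voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import GridSpec, InvalidArgumentError, RsnparcError

__all__ = [
    "StatMap",
    "RankDeficiencyError",
    "group_mask",
    "two_sample_t_cov",
    "cluster_threshold",
    "clinical_correlation",
]

#: 6-face connectivity structure for cluster labelling (configurable to 18/26
#: by passing a different structure to cluster_threshold).
FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


class RankDeficiencyError(RsnparcError):
    """The covariate is collinear with the group indicator."""


@dataclass
class StatMap:
    """A voxelwise statistic volume with cluster bookkeeping."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    cluster_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant_clusters(self) -> pd.DataFrame:
        if self.clusters.empty:
            return self.clusters
        return self.clusters[self.clusters["significant"]]


def _one_sample_t(maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t over subjects (axis 0); zero-variance voxels get t=0."""
    n = maps.shape[0]
    if n < 2:
        raise InvalidArgumentError("need >= 2 subjects for a one-sample t test")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t, n - 1


def group_mask(maps_by_group: dict[str, np.ndarray], p_thresh: float = 0.001) -> np.ndarray:
    """Intersection mask of per-group one-sample activation maps.

    Each group's subject x voxel-grid stack is tested against zero
    (one-sided, positive); a voxel enters the mask only if it is
    suprathreshold at ``p_thresh`` in every group.
    """
    if not maps_by_group:
        raise InvalidArgumentError("no groups given")
    mask = None
    for name, maps in maps_by_group.items():
        maps = np.asarray(maps, dtype=float)
        t, df = _one_sample_t(maps)
        crit = stats.t.ppf(1.0 - p_thresh, df)
        this = t > crit
        mask = this if mask is None else (mask & this)
    if not mask.any():
        warnings.warn("intersection mask is empty", RuntimeWarning)
    return mask


def _design(group: np.ndarray, covariate: np.ndarray | None) -> np.ndarray:
    n = len(group)
    cols = [np.ones(n), np.asarray(group, dtype=float)]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if np.ptp(cov) > 0:
            # collinearity of covariate with [1, group]
            base = np.column_stack(cols)
            resid = cov - base @ np.linalg.lstsq(base, cov, rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(cov), 1.0):
                raise RankDeficiencyError("covariate is collinear with the group indicator")
            cols.append(cov)
        # zero-variance covariate carries no information: drop it
    return np.column_stack(cols)


def _glm_group_t(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic for the group column (index 1) of design X, per column of Y."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise InvalidArgumentError(f"not enough subjects for {p} design columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t = np.where(se > 0, beta[1] / se, 0.0)
    return t, df


def two_sample_t_cov(
    mapsA: np.ndarray,
    mapsB: np.ndarray,
    covariate: np.ndarray | None = None,
) -> StatMap:
    """Between-group voxelwise GLM: group indicator plus confounding covariate.

    ``mapsA``/``mapsB`` are ``(n_subjects, ...)`` arrays (trailing axes
    are the voxel grid).  ``covariate`` concatenates A then B.  The t
    statistic tests the A-minus-B contrast with ``n_A + n_B - 3``
    degrees of freedom (or n-2 when the covariate is constant and thus
    dropped).  Two-sided p values are returned.
    """
    mapsA = np.asarray(mapsA, dtype=float)
    mapsB = np.asarray(mapsB, dtype=float)
    if mapsA.shape[0] < 2 or mapsB.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 subjects per group")
    if mapsA.shape[1:] != mapsB.shape[1:]:
        raise InvalidArgumentError("group map shapes differ")
    spatial = mapsA.shape[1:]
    nA, nB = mapsA.shape[0], mapsB.shape[0]
    Y = np.concatenate([mapsA, mapsB]).reshape(nA + nB, -1)
    group = np.concatenate([np.ones(nA), np.zeros(nB)])
    X = _design(group, covariate)
    t, df = _glm_group_t(Y, X)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return StatMap(t_values=t.reshape(spatial), p_values=p.reshape(spatial), df=df)


def _label_signed(t_vol: np.ndarray, crit: float, structure: np.ndarray) -> np.ndarray:
    """Label suprathreshold clusters, positive and negative excursions separately."""
    pos, n_pos = ndimage.label(t_vol > crit, structure=structure)
    neg, n_neg = ndimage.label(t_vol < -crit, structure=structure)
    labels = pos.astype(int)
    labels[neg > 0] = neg[neg > 0] + n_pos
    return labels


def _max_extent(labels: np.ndarray) -> int:
    if labels.max() == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_threshold(
    mapsA: np.ndarray,
    mapsB: np.ndarray,
    covariate: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    p_voxel: float = 0.001,
    k_min: int = 5,
    alpha_fwe: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    grid: GridSpec | None = None,
    structure: np.ndarray = FACE_CONNECTIVITY,
) -> StatMap:
    """Cluster-extent inference with permutation family-wise-error correction.

    The observed GLM t volume is thresholded two-sided at ``p_voxel``
    (cluster-forming); suprathreshold voxels are grouped into clusters by
    face connectivity, positive and negative excursions separately.  A
    null distribution of the maximum cluster extent is built by
    permuting group labels (covariate refit each time); a cluster is
    reported significant iff its extent is >= ``k_min`` and its
    FWE-corrected p is < ``alpha_fwe``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; FWE p values will be coarse", RuntimeWarning)
    mapsA = np.asarray(mapsA, dtype=float)
    mapsB = np.asarray(mapsB, dtype=float)
    spatial = mapsA.shape[1:]
    nA, nB = mapsA.shape[0], mapsB.shape[0]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flatmask = mask.reshape(-1)
    Y = np.concatenate([mapsA, mapsB]).reshape(nA + nB, -1)[:, flatmask]
    group = np.concatenate([np.ones(nA), np.zeros(nB)])
    cov = None if covariate is None else np.asarray(covariate, dtype=float)

    X = _design(group, cov)
    t_flat, df = _glm_group_t(Y, X)
    crit = stats.t.ppf(1.0 - p_voxel / 2.0, df)
    t_vol = np.zeros(spatial)
    t_vol.reshape(-1)[flatmask] = t_flat
    labels = _label_signed(np.where(mask, t_vol, 0.0), crit, structure)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    perm_vol = np.zeros(spatial)
    for b in range(n_perm):
        perm = rng.permutation(len(group))
        Xp = _design(group[perm], cov)
        tp, _ = _glm_group_t(Y, Xp)
        perm_vol.fill(0.0)
        perm_vol.reshape(-1)[flatmask] = tp
        null_max[b] = _max_extent(_label_signed(perm_vol, crit, structure))

    rows = []
    for lab in range(1, labels.max() + 1):
        where = labels == lab
        extent = int(where.sum())
        if extent == 0:
            continue
        tv = np.where(where, t_vol, 0.0)
        peak_flat = int(np.argmax(np.abs(tv)))
        peak_ijk = np.unravel_index(peak_flat, spatial)
        p_fwe = float((1 + (null_max >= extent).sum()) / (n_perm + 1))
        row = {
            "label": lab,
            "extent": extent,
            "peak_ijk": tuple(int(i) for i in peak_ijk),
            "peak_t": float(t_vol[peak_ijk]),
            "p_fwe": p_fwe,
            "significant": (extent >= k_min) and (p_fwe < alpha_fwe),
        }
        if grid is not None:
            row["peak_world"] = tuple(grid.voxel_to_world(np.array(peak_ijk))[0])
        rows.append(row)
    clusters = pd.DataFrame(rows)
    p_vol = np.ones(spatial)
    p_vol.reshape(-1)[flatmask] = 2.0 * stats.t.sf(np.abs(t_flat), df)
    return StatMap(
        t_values=t_vol, p_values=p_vol, df=df, cluster_labels=labels, clusters=clusters
    )


def _sphere_indices(peak_ijk: np.ndarray, radius_mm: float, grid: GridSpec) -> np.ndarray:
    """Voxel coordinates within a world-space radius of a peak voxel."""
    vs = np.asarray(grid.voxel_size)
    half = np.ceil(radius_mm / vs).astype(int)
    ranges = [
        np.arange(max(0, peak_ijk[a] - half[a]), min(grid.dims[a], peak_ijk[a] + half[a] + 1))
        for a in range(3)
    ]
    grid_ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm((grid_ijk - peak_ijk) * vs, axis=1)
    return grid_ijk[d <= radius_mm + 1e-9]


def clinical_correlation(
    maps: np.ndarray,
    score: np.ndarray,
    peaks: list[tuple[int, int, int]],
    grid: GridSpec,
    svc_radius: float = 10.0,
    method: str = "pearson",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Map-score correlation around a-priori peaks with small-volume correction.

    For each peak, every voxel inside a ``svc_radius``-mm sphere is
    correlated with the per-subject clinical score; the in-sphere peak
    correlation is reported with a Bonferroni correction over the number
    of in-sphere voxels (the small-volume correction).  With radius 0
    the test is the single peak voxel, uncorrected.
    """
    maps = np.asarray(maps, dtype=float)
    score = np.asarray(score, dtype=float)
    if maps.shape[0] < 5:
        raise InvalidArgumentError("need >= 5 subjects for clinical correlation")
    if np.ptp(score) == 0:
        raise InvalidArgumentError("constant clinical score: correlation undefined")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for peak in peaks:
        peak = np.asarray(peak, dtype=int)
        sphere = _sphere_indices(peak, svc_radius, grid)
        best = None
        for ijk in sphere:
            vals = maps[(slice(None), *ijk)]
            if np.ptp(vals) == 0:
                continue
            r, p = corr(vals, score)
            if best is None or abs(r) > abs(best[0]):
                best = (float(r), float(p), tuple(int(i) for i in ijk))
        n_vox = len(sphere)
        if best is None:
            rows.append(
                {"peak_ijk": tuple(int(i) for i in peak), "r": np.nan, "p": np.nan,
                 "p_svc": np.nan, "n_sphere_voxels": n_vox, "significant": False}
            )
            continue
        r, p, at = best
        p_svc = min(1.0, p * n_vox)
        rows.append(
            {
                "peak_ijk": tuple(int(i) for i in peak),
                "best_ijk": at,
                "r": r,
                "p": p,
                "p_svc": p_svc,
                "n_sphere_voxels": n_vox,
                "significant": p_svc < alpha,
            }
        )
    return pd.DataFrame(rows)
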