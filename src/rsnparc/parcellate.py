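"""Connectivity-based cortical parcellation.

Seeds are extracted at the gray/white-matter boundary of a cortical
probability map (per-slice 2D Sobel gradient of the GM probability,
masked by the thresholded ROI map, CSF-facing seeds removed).  Each
seed's streamline visitation counts are aggregated into a seed-by-region
connectivity profile; profiles from all subjects of a group are
concatenated and clustered by k-means, with the cluster number chosen
by the mean silhouette over k = 2..15.  Groups are clustered
separately; cluster-centroid profiles are matched across groups and
compared region by region, and per-subject seed counts per cluster feed
between-group t tests and Spearman correlations with clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances, silhouette_samples

from .core import InvalidArgumentError, RsnparcError

__all__ = [
    "SeedSet",
    "ParcellationResult",
    "CentroidComparison",
    "ConnectivityParcellation",
    "extract_seeds",
    "aggregate_profiles",
    "concat_profiles",
    "silhouette_mean",
    "choose_k",
    "compare_centroids",
    "seed_count_stats",
]


class EmptyRoiError(RsnparcError):
    """No seeds survive extraction within the ROI."""


@dataclass
class SeedSet:
    roi_name: str
    coords: np.ndarray          # (n_seeds, 3) voxel coordinates
    subject_id: str = ""

    @property
    def n_seeds(self) -> int:
        return len(self.coords)


@dataclass
class ParcellationResult:
    """Output of silhouette-selected k-means on a group's profile matrix."""

    labels: np.ndarray | None            # per-seed labels in [1, k], or None
    centroids: pd.DataFrame | None       # k x regions (normalized space)
    silhouette_curve: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    chosen_k: int | None = None
    seed_counts: pd.DataFrame = field(default_factory=pd.DataFrame)  # subjects x cluster
    no_structure: bool = False
    group: str = ""


def extract_seeds(
    gm_prob: np.ndarray,
    csf_prob: np.ndarray,
    roi_prob: np.ndarray,
    roi_thresh: float = 0.5,
    gradient_frac: float = 0.25,
    csf_cutoff: float = 0.5,
    roi_name: str = "roi",
    subject_id: str = "",
) -> SeedSet:
    """Seed voxels at the GM/WM boundary inside a cortical ROI.

    A 2D Sobel filter is applied to each axial (z) slice of the
    non-binarized GM probability map; voxels whose gradient magnitude
    reaches ``gradient_frac`` of the slice maximum, and whose ROI
    probability is >= ``roi_thresh``, are candidate seeds.  Seeds with
    any 6-neighbor CSF probability above ``csf_cutoff`` are removed
    (the automated analogue of removing seeds that face the CSF).
    """
    gm_prob = np.asarray(gm_prob, dtype=float)
    csf_prob = np.asarray(csf_prob, dtype=float)
    roi_prob = np.asarray(roi_prob, dtype=float)
    if not (gm_prob.shape == csf_prob.shape == roi_prob.shape):
        raise InvalidArgumentError("gm/csf/roi volumes must share a voxel space")
    boundary = np.zeros(gm_prob.shape, dtype=bool)
    for z in range(gm_prob.shape[2]):
        sl = gm_prob[:, :, z]
        gx = ndimage.sobel(sl, axis=0)
        gy = ndimage.sobel(sl, axis=1)
        mag = np.hypot(gx, gy)
        if mag.max() <= 0:
            continue
        boundary[:, :, z] = mag >= gradient_frac * mag.max()
    candidates = boundary & (roi_prob >= roi_thresh)
    # remove seeds with a CSF-dominant face neighbor
    csf_mask = csf_prob > csf_cutoff
    near_csf = ndimage.binary_dilation(
        csf_mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    keep = candidates & ~near_csf & ~csf_mask
    coords = np.argwhere(keep)
    if len(coords) == 0:
        raise EmptyRoiError(f"no seeds found in ROI '{roi_name}'")
    return SeedSet(roi_name=roi_name, coords=coords, subject_id=subject_id)


def _majority_downsample(atlas: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Downsample an integer label volume by block-majority vote."""
    dims = np.array(atlas.shape)
    f = np.array(factors)
    pad = (-dims) % f
    padded = np.pad(atlas, [(0, p) for p in pad], constant_values=0)
    nx, ny, nz = np.array(padded.shape) // f
    blocks = (
        padded.reshape(nx, f[0], ny, f[1], nz, f[2])
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nx * ny * nz, -1)
    )
    out = stats.mode(blocks, axis=1, keepdims=False).mode
    return out.reshape(nx, ny, nz)


def aggregate_profiles(
    visit_counts: np.ndarray,
    atlas: np.ndarray,
    exclude: tuple = (),
    region_names: dict[int, str] | None = None,
    seed_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Sum per-seed visitation counts within atlas regions.

    ``visit_counts`` is ``(n_seeds, nx, ny, nz)`` (possibly at a coarser
    resolution than the atlas: the atlas is then block-majority
    downsampled to the count grid).  ``exclude`` lists region labels or
    names to drop — the seed-containing regions and all contralateral
    regions, per the analysis rules.  Background label 0 is never a
    region.
    """
    visit_counts = np.asarray(visit_counts)
    atlas = np.asarray(atlas)
    if np.any(visit_counts < 0):
        raise InvalidArgumentError("visitation counts must be nonnegative")
    cshape = np.array(visit_counts.shape[1:])
    ashape = np.array(atlas.shape)
    if not np.array_equal(cshape, ashape):
        ratio = ashape / cshape
        f = np.round(ratio).astype(int)
        if np.any(f < 1) or np.any(np.ceil(ashape / f) != cshape):
            raise InvalidArgumentError(
                f"atlas shape {atlas.shape} is not an integer multiple of count shape "
                f"{tuple(cshape)}"
            )
        atlas = _majority_downsample(atlas, tuple(f))[: cshape[0], : cshape[1], : cshape[2]]
    labels = sorted(int(v) for v in np.unique(atlas) if v != 0)
    names = {lab: (region_names or {}).get(lab, f"region_{lab:02d}") for lab in labels}
    unknown = [e for e in exclude if e not in labels and e not in names.values()]
    if unknown:
        raise InvalidArgumentError(f"exclusion list names unknown regions: {unknown}")
    keep = [
        lab for lab in labels if lab not in exclude and names[lab] not in exclude
    ]
    flat_atlas = atlas.reshape(-1)
    flat_counts = visit_counts.reshape(visit_counts.shape[0], -1)
    cols = {names[lab]: flat_counts[:, flat_atlas == lab].sum(axis=1) for lab in keep}
    idx = seed_ids if seed_ids is not None else [f"seed{j:03d}" for j in range(len(visit_counts))]
    return pd.DataFrame(cols, index=idx)


def concat_profiles(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject profile matrices, keeping subject provenance.

    Returns a DataFrame with a (subject, seed) MultiIndex; all inputs
    must share the same region columns.
    """
    frames = []
    for df in profiles:
        sub = df.attrs.get("subject_id", "sub-unknown")
        f = df.copy()
        f.index = pd.MultiIndex.from_product([[sub], df.index], names=["subject", "seed"])
        frames.append(f)
    out = pd.concat(frames)
    if out.columns.duplicated().any() or any(
        not df.columns.equals(profiles[0].columns) for df in profiles
    ):
        raise InvalidArgumentError("profile matrices have mismatching region columns")
    return out


def _normalize_rows(X: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return X.astype(float)
    if how == "l1":
        totals = X.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        return X / totals
    raise InvalidArgumentError(f"unknown normalization '{how}'")


def silhouette_mean(
    profiles: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    metric: str = "euclidean",
    variant: str = "rousseeuw",
    normalize: str = "none",
) -> float:
    """Mean silhouette of a labelling of profile rows.

    ``variant="rousseeuw"`` is the canonical form
    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a = mean intra-cluster
    distance and b = min mean distance to another cluster.
    ``variant="similarity_ratio"`` implements the similarity-ratio
    reading (similarity kernel 1/(1+d), per-seed ratio of mean
    within-cluster similarity to the maximum other-cluster mean
    similarity, mapped to [-1, 1] via (ratio-1)/(ratio+1)).
    """
    X = profiles.to_numpy() if isinstance(profiles, pd.DataFrame) else np.asarray(profiles)
    X = _normalize_rows(X, normalize)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("need >= 2 clusters for a silhouette")
    if np.all(counts == 1):
        raise InvalidArgumentError("silhouette undefined: all clusters are singletons")
    if variant == "rousseeuw":
        return float(np.mean(silhouette_samples(X, labels, metric=metric)))
    if variant != "similarity_ratio":
        raise InvalidArgumentError(f"unknown silhouette variant '{variant}'")
    D = pairwise_distances(X, metric=metric)
    S = 1.0 / (1.0 + D)
    vals = []
    for i in range(len(X)):
        own = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not own.any():
            vals.append(0.0)
            continue
        a_sim = S[i, own].mean()
        b_sim = max(S[i, labels == c].mean() for c in uniq if c != labels[i])
        ratio = a_sim / max(b_sim, 1e-12)
        vals.append((ratio - 1.0) / (ratio + 1.0))
    return float(np.mean(vals))


class ConnectivityParcellation(ClusterMixin, BaseEstimator):
    """Silhouette-selected k-means clustering of connectivity profiles.

    k-means (k-means++ init, ``n_restarts`` restarts, best inertia) is
    run for every k in ``k_range`` (inclusive; default 2..15) on
    row-normalized profiles; the chosen k maximizes the mean silhouette,
    ties broken toward smaller k.  When the best mean silhouette falls
    below ``structure_threshold`` the data are flagged as unstructured
    and no k is chosen.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive sweep range for the cluster number.
    normalize : {"l1", "none"}
        Row normalization before clustering (L1 removes seed-depth count
        biases).
    metric : str
        Distance for the silhouette (clustering itself is Euclidean
        k-means).
    structure_threshold : float
        Minimum acceptable best mean silhouette.

    Attributes
    ----------
    labels_ : per-seed cluster labels in [1, k_] (None when unstructured).
    cluster_centers_ : (k_, n_regions) centroids in normalized space.
    silhouette_curve_ : pd.Series of mean silhouette per k.
    k_ : selected cluster count (None when unstructured).
    no_structure_ : bool.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 15),
        n_restarts: int = 20,
        random_state: int = 0,
        normalize: str = "l1",
        metric: str = "euclidean",
        variant: str = "rousseeuw",
        structure_threshold: float = 0.25,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.normalize = normalize
        self.metric = metric
        self.variant = variant
        self.structure_threshold = structure_threshold

    def fit(self, X: np.ndarray | pd.DataFrame, y=None) -> "ConnectivityParcellation":
        Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        self.feature_names_in_ = (
            np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        Xn = _normalize_rows(Xa, self.normalize)
        k_lo, k_hi = self.k_range
        if Xn.shape[0] <= k_hi:
            raise InvalidArgumentError(
                f"need more seeds ({Xn.shape[0]}) than the largest k ({k_hi})"
            )
        if np.allclose(Xn, Xn[0]):
            self.no_structure_ = True
            self.k_ = None
            self.labels_ = None
            self.cluster_centers_ = None
            self.silhouette_curve_ = pd.Series(dtype=float)
            return self
        curve = {}
        fits = {}
        for k in range(k_lo, k_hi + 1):
            km = KMeans(
                n_clusters=k, n_init=self.n_restarts, random_state=self.random_state
            ).fit(Xn)
            fits[k] = km
            curve[k] = silhouette_mean(
                Xn, km.labels_, metric=self.metric, variant=self.variant
            )
        self.silhouette_curve_ = pd.Series(curve, name="mean_silhouette")
        best_k = int(self.silhouette_curve_.idxmax())   # first max -> smaller k on ties
        if self.silhouette_curve_.max() < self.structure_threshold:
            self.no_structure_ = True
            self.k_ = None
            self.labels_ = None
            self.cluster_centers_ = None
            return self
        self.no_structure_ = False
        self.k_ = best_k
        self.labels_ = fits[best_k].labels_ + 1   # 1-based cluster labels
        self.cluster_centers_ = fits[best_k].cluster_centers_
        return self


def choose_k(
    profiles: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 15),
    n_restarts: int = 20,
    seed: int = 0,
    normalize: str = "l1",
    metric: str = "euclidean",
    variant: str = "rousseeuw",
    structure_threshold: float = 0.25,
    group: str = "",
) -> ParcellationResult:
    """Run the silhouette-selected k-means sweep on one group's profiles.

    ``profiles`` ideally carries a (subject, seed) MultiIndex (see
    :func:`concat_profiles`) so that per-subject seed counts per cluster
    can be tabulated.
    """
    est = ConnectivityParcellation(
        k_range=k_range,
        n_restarts=n_restarts,
        random_state=seed,
        normalize=normalize,
        metric=metric,
        variant=variant,
        structure_threshold=structure_threshold,
    ).fit(profiles)
    if est.no_structure_:
        return ParcellationResult(
            labels=None,
            centroids=None,
            silhouette_curve=est.silhouette_curve_,
            chosen_k=None,
            no_structure=True,
            group=group,
        )
    columns = (
        list(profiles.columns)
        if isinstance(profiles, pd.DataFrame)
        else [f"region_{j:02d}" for j in range(est.cluster_centers_.shape[1])]
    )
    centroids = pd.DataFrame(
        est.cluster_centers_, index=range(1, est.k_ + 1), columns=columns
    )
    seed_counts = pd.DataFrame()
    if isinstance(profiles, pd.DataFrame) and isinstance(profiles.index, pd.MultiIndex):
        subj = profiles.index.get_level_values(0)
        seed_counts = (
            pd.crosstab(subj, est.labels_)
            .reindex(columns=range(1, est.k_ + 1), fill_value=0)
        )
        seed_counts.columns = [f"cluster_{c}" for c in seed_counts.columns]
    return ParcellationResult(
        labels=est.labels_,
        centroids=centroids,
        silhouette_curve=est.silhouette_curve_,
        chosen_k=est.k_,
        seed_counts=seed_counts,
        group=group,
    )


@dataclass
class CentroidComparison:
    matches: list[tuple[int, int, float]]          # (cluster_a, cluster_b, r)
    unmatched_a: list[int]
    unmatched_b: list[int]
    table: pd.DataFrame                            # per matched pair x region


def compare_centroids(
    resA: ParcellationResult,
    resB: ParcellationResult,
    peak_threshold: float = 0.05,
    change_threshold: float = 0.3,
) -> CentroidComparison:
    """Match clusters across groups and classify per-region centroid differences.

    Clusters are matched one-to-one by maximal centroid correlation
    (Hungarian assignment); unmatched clusters (unequal k) are reported
    as group-unique.  Within each matched pair, a region is a "peak"
    when its (normalized) centroid weight reaches ``peak_threshold``;
    regions are classified as present-in-A-only / present-in-B-only /
    increased / decreased (relative change beyond ``change_threshold``,
    A vs B) / unchanged / absent.
    """
    if resA.centroids is None or resB.centroids is None:
        raise InvalidArgumentError("both parcellations must have chosen clusters")
    if list(resA.centroids.columns) != list(resB.centroids.columns):
        raise InvalidArgumentError("centroid region columns differ between groups")
    A = resA.centroids.to_numpy()
    B = resB.centroids.to_numpy()
    R = np.corrcoef(A, B)[: len(A), len(A):]
    rows_idx, cols_idx = linear_sum_assignment(-R)
    matches = [
        (int(resA.centroids.index[i]), int(resB.centroids.index[j]), float(R[i, j]))
        for i, j in zip(rows_idx, cols_idx)
    ]
    matched_a = {m[0] for m in matches}
    matched_b = {m[1] for m in matches}
    unmatched_a = [int(c) for c in resA.centroids.index if c not in matched_a]
    unmatched_b = [int(c) for c in resB.centroids.index if c not in matched_b]

    rows = []
    for ca, cb, r in matches:
        pa = resA.centroids.loc[ca]
        pb = resB.centroids.loc[cb]
        for region in resA.centroids.columns:
            va, vb = float(pa[region]), float(pb[region])
            in_a, in_b = va >= peak_threshold, vb >= peak_threshold
            if in_a and not in_b:
                cls = "present-in-A-only"
            elif in_b and not in_a:
                cls = "present-in-B-only"
            elif not in_a and not in_b:
                cls = "absent"
            elif va > vb * (1.0 + change_threshold):
                cls = "increased"
            elif vb > va * (1.0 + change_threshold):
                cls = "decreased"
            else:
                cls = "unchanged"
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "match_r": r,
                    "region": region,
                    "value_a": va,
                    "value_b": vb,
                    "class": cls,
                }
            )
    return CentroidComparison(
        matches=matches,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        table=pd.DataFrame(rows),
    )


def seed_count_stats(
    resA: ParcellationResult,
    resB: ParcellationResult,
    scores: pd.DataFrame | None = None,
    comparison: CentroidComparison | None = None,
) -> dict[str, pd.DataFrame]:
    """Between-group seed-count tests and clinical correlations per cluster.

    For each matched cluster pair, the per-subject number of seeds
    assigned to the cluster is compared between groups with a Welch t
    test.  With ``scores`` (DataFrame indexed by subject id, one column
    per clinical score), Spearman rank correlations of counts vs scores
    are computed within each group.  Subjects without seeds in a cluster
    count as 0.
    """
    if resA.seed_counts.empty or resB.seed_counts.empty:
        raise InvalidArgumentError("parcellation results carry no per-subject seed counts")
    if comparison is None:
        comparison = compare_centroids(resA, resB)
    t_rows, rho_rows = [], []
    for ca, cb, r in comparison.matches:
        xa = resA.seed_counts.get(f"cluster_{ca}", pd.Series(0, index=resA.seed_counts.index))
        xb = resB.seed_counts.get(f"cluster_{cb}", pd.Series(0, index=resB.seed_counts.index))
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            tval, pval = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            tval, pval = stats.ttest_ind(xa, xb, equal_var=False)
        t_rows.append(
            {
                "cluster_a": ca,
                "cluster_b": cb,
                "mean_a": float(xa.mean()),
                "sd_a": float(xa.std(ddof=1)),
                "mean_b": float(xb.mean()),
                "sd_b": float(xb.std(ddof=1)),
                "t": float(tval),
                "p": float(pval),
            }
        )
        if scores is not None:
            for grp, counts in (("A", xa), ("B", xb)):
                common = counts.index.intersection(scores.index)
                if len(common) < 3:
                    continue
                for col in scores.columns:
                    rho, p = stats.spearmanr(counts.loc[common], scores.loc[common, col])
                    rho_rows.append(
                        {
                            "group": grp,
                            "cluster": ca if grp == "A" else cb,
                            "score": col,
                            "rho": float(rho),
                            "p": float(p),
                            "n": len(common),
                        }
                    )
    return {"t_tests": pd.DataFrame(t_rows), "correlations": pd.DataFrame(rho_rows)}
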