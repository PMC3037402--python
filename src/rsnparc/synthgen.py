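"""Synthetic cohorts with planted ground truth.

Two families of inputs are generated:

* resting-state 4D cohorts: spatially independent network maps confined
  to a gray-matter shell of an ellipsoidal head phantom, driven by
  band-limited (0.01-0.08 Hz) Gaussian time courses, with a
  multiplicative group amplitude effect on designated networks and
  additive Gaussian noise.  Optional confound components (CSF-shaped
  maps, high-frequency time courses) exercise the component-selection
  criteria.

* seed-by-region connectivity-profile cohorts: Poisson visitation
  counts around per-cluster archetype profiles, with the number of
  planted clusters allowed to differ between groups.  A toy Monte-Carlo
  streamline tracker can generate visitation-count volumes from an
  orientation field as an alternative source of profiles.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import GridSpec, Image4D, InvalidArgumentError, RsnparcError

__all__ = [
    "GroundTruth",
    "InfeasibleGeometryError",
    "tissue_phantom",
    "bandlimited_timecourses",
    "make_network_maps",
    "make_rsfmri_cohort",
    "make_profile_cohort",
    "toy_tracker",
    "downsample_counts",
]

GROUPS = ("patient", "control")


class InfeasibleGeometryError(RsnparcError):
    """The grid is too small to host the requested network layout."""


@dataclass
class GroundTruth:
    """Everything the generators planted, for downstream recovery checks."""

    grid: GridSpec | None = None
    network_maps: np.ndarray | None = None          # (K, nx, ny, nz), peak 1
    component_labels: list[str] = field(default_factory=list)  # "network"/"csf"/"highfreq"
    timecourses: np.ndarray | None = None           # (n_subjects, T, K), unit SD
    amplitudes: np.ndarray | None = None            # (n_subjects, K)
    groups: list[str] = field(default_factory=list)  # per subject
    effect_networks: tuple[int, ...] = ()
    group_effect: float = 1.0
    noise_sd: float = 0.0
    tissue_priors: dict[str, np.ndarray] = field(default_factory=dict)
    # connectivity-profile truth
    planted_k: dict[str, int] = field(default_factory=dict)
    planted_labels: dict[str, np.ndarray] = field(default_factory=dict)  # subject_id -> labels
    archetypes: dict[str, np.ndarray] = field(default_factory=dict)      # group -> (k, n_regions)


# ---------------------------------------------------------------------------
# head phantom and functional cohort
# ---------------------------------------------------------------------------

def tissue_phantom(grid: GridSpec) -> dict[str, np.ndarray]:
    """Build GM/WM/CSF probability volumes for an ellipsoidal head phantom.

    Concentric compartments (inside out): a central CSF ventricle, a WM
    core, a GM shell, and a thin CSF rim, softened by a light Gaussian
    blur.  Probabilities sum to <= 1 per voxel.
    """
    nx, ny, nz = grid.dims
    ax = np.arange(nx) - (nx - 1) / 2
    ay = np.arange(ny) - (ny - 1) / 2
    az = np.arange(nz) - (nz - 1) / 2
    # normalized ellipsoidal radius: 1 at the head surface
    rx, ry, rz = 0.46 * nx, 0.46 * ny, 0.46 * nz
    r = np.sqrt(
        (ax[:, None, None] / rx) ** 2
        + (ay[None, :, None] / ry) ** 2
        + (az[None, None, :] / rz) ** 2
    )
    csf = ((r <= 0.18) | ((r > 0.90) & (r <= 1.0))).astype(float)
    wm = ((r > 0.18) & (r <= 0.58)).astype(float)
    gm = ((r > 0.58) & (r <= 0.90)).astype(float)
    out = {}
    for name, vol in (("gm", gm), ("wm", wm), ("csf", csf)):
        out[name] = ndimage.gaussian_filter(vol, sigma=0.6, mode="constant")
    total = out["gm"] + out["wm"] + out["csf"]
    over = total > 1.0
    for name in out:
        out[name][over] /= total[over]
    return out


def bandlimited_timecourses(
    n_timepoints: int,
    n_series: int,
    tr: float,
    band: tuple[float, float] = (0.01, 0.08),
    rng: np.random.Generator | None = None,
    spectral_slope: float = 1.0,
) -> np.ndarray:
    """Unit-SD Gaussian time courses band-limited to ``band`` (Hz).

    In-band power falls off as ``1/f**spectral_slope`` (default pink,
    matching the low-frequency-dominated spectrum of spontaneous
    fluctuations).  Returns an array of shape (n_timepoints, n_series).
    """
    rng = np.random.default_rng() if rng is None else rng
    low, high = band
    x = rng.standard_normal((n_timepoints, n_series))
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise InvalidArgumentError(f"no FFT bins inside band {band} at T={n_timepoints}, TR={tr}")
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    if spectral_slope:
        shaping = np.ones_like(freqs)
        shaping[keep] = (freqs[keep] / low) ** (-spectral_slope / 2.0)
        spec *= shaping[:, None]
    tc = np.fft.irfft(spec, n=n_timepoints, axis=0)
    sd = tc.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return tc / sd


def make_network_maps(
    grid: GridSpec,
    n_networks: int,
    rng: np.random.Generator,
    gm: np.ndarray | None = None,
    blob_sigma_vox: float = 1.6,
    blobs_per_network: int = 3,
    max_pairwise_corr: float = 0.2,
    max_tries: int = 2000,
) -> np.ndarray:
    """Place GM-confined network maps, spatially quasi-independent.

    Each network is the union (voxelwise max) of ``blobs_per_network``
    Gaussian foci centered on strong-GM voxels — resting-state networks
    are distributed sets of regions, not single foci.  Maps are
    peak-normalized to 1 and accepted only while every pairwise spatial
    correlation stays below ``max_pairwise_corr``.
    """
    if gm is None:
        gm = tissue_phantom(grid)["gm"]
    cand = np.argwhere(gm > 0.5)
    if len(cand) < n_networks * blobs_per_network:
        raise InfeasibleGeometryError(
            f"grid {grid.dims} has only {len(cand)} strong-GM voxels for "
            f"{n_networks} x {blobs_per_network} network foci"
        )
    nx, ny, nz = grid.dims
    coords = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).astype(float)
    maps: list[np.ndarray] = []
    flats: list[np.ndarray] = []
    tries = 0
    while len(maps) < n_networks:
        tries += 1
        if tries > max_tries:
            raise InfeasibleGeometryError(
                f"could not place {n_networks} networks with pairwise |r| < {max_pairwise_corr} "
                f"on grid {grid.dims}"
            )
        blob = np.zeros(grid.dims)
        for _ in range(blobs_per_network):
            center = cand[rng.integers(len(cand))]
            d2 = ((coords - center) ** 2).sum(axis=-1)
            blob = np.maximum(blob, np.exp(-d2 / (2.0 * blob_sigma_vox**2)))
        blob = blob * (gm > 0.1)
        if blob.max() <= 0:
            continue
        blob = blob / blob.max()
        f = blob.ravel()
        ok = True
        for g in flats:
            r = np.corrcoef(f, g)[0, 1]
            if abs(r) >= max_pairwise_corr:
                ok = False
                break
        if ok:
            maps.append(blob)
            flats.append(f)
    return np.stack(maps)


def make_rsfmri_cohort(
    grid: GridSpec,
    n_subjects_per_group: int,
    n_networks: int,
    seed: int,
    n_timepoints: int = 100,
    noise_sd: float = 0.5,
    group_effect: float = 1.5,
    effect_networks: tuple[int, ...] = (0,),
    n_csf_confounds: int = 0,
    n_highfreq_confounds: int = 0,
    amplitude: float = 1.0,
    amplitude_overrides: dict[tuple[int, int], float] | None = None,
) -> tuple[list[Image4D], GroundTruth]:
    """Generate a two-group resting-state cohort with planted networks.

    Each subject's data is ``sum_k a_sk * tc_sk(t) * map_k(v) + noise``;
    subjects in the patient group have their designated networks'
    amplitude multiplied by ``group_effect``.  ``noise_sd`` is in units
    of the peak-voxel signal SD of a unit-amplitude network.  Confound
    components (CSF-shaped map with an in-band time course; GM map with
    a 0.12-0.16 Hz time course) are appended after the networks.
    """
    if n_subjects_per_group < 1 or n_networks < 1 or n_timepoints < 2:
        raise InvalidArgumentError("counts must be positive")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if any(i < 0 or i >= n_networks for i in effect_networks):
        raise InvalidArgumentError(f"effect_networks {effect_networks} out of range")
    rng = np.random.default_rng(seed)
    priors = tissue_phantom(grid)
    net_maps = make_network_maps(grid, n_networks, rng, gm=priors["gm"])
    labels = ["network"] * n_networks

    extra_maps = []
    if n_csf_confounds:
        csf_map = priors["csf"] / max(priors["csf"].max(), 1e-12)
        extra_maps += [csf_map] * n_csf_confounds
        labels += ["csf"] * n_csf_confounds
    if n_highfreq_confounds:
        hf_maps = make_network_maps(grid, n_highfreq_confounds, rng, gm=priors["gm"])
        extra_maps += list(hf_maps)
        labels += ["highfreq"] * n_highfreq_confounds
    all_maps = np.concatenate([net_maps] + ([np.stack(extra_maps)] if extra_maps else []))
    k_total = all_maps.shape[0]

    n_sub = 2 * n_subjects_per_group
    groups = ["patient"] * n_subjects_per_group + ["control"] * n_subjects_per_group
    amplitudes = np.full((n_sub, k_total), amplitude)
    for s, g in enumerate(groups):
        if g == "patient":
            for k in effect_networks:
                amplitudes[s, k] *= group_effect
    for (s, k), a in (amplitude_overrides or {}).items():
        amplitudes[s, k] = a

    timecourses = np.empty((n_sub, n_timepoints, k_total))
    images: list[Image4D] = []
    flat_maps = all_maps.reshape(k_total, -1)
    n_low = n_networks + (n_csf_confounds or 0)
    for s in range(n_sub):
        tc = np.empty((n_timepoints, k_total))
        tc[:, :n_low] = bandlimited_timecourses(n_timepoints, n_low, grid.tr, (0.01, 0.08), rng)
        if n_highfreq_confounds:
            tc[:, n_low:] = bandlimited_timecourses(
                n_timepoints, k_total - n_low, grid.tr, (0.12, 0.16), rng
            )
        timecourses[s] = tc
        sig = (tc * amplitudes[s]) @ flat_maps
        if noise_sd > 0:
            sig = sig + noise_sd * rng.standard_normal(sig.shape)
        data = sig.reshape(n_timepoints, *grid.dims)
        motion = float(abs(rng.normal(1.5, 0.3)))
        images.append(
            Image4D(data=data, grid=grid, subject_id=f"sub-{s:03d}", mean_motion=motion, group=groups[s])
        )

    truth = GroundTruth(
        grid=grid,
        network_maps=all_maps,
        component_labels=labels,
        timecourses=timecourses,
        amplitudes=amplitudes,
        groups=groups,
        effect_networks=tuple(effect_networks),
        group_effect=group_effect,
        noise_sd=noise_sd,
        tissue_priors=priors,
    )
    return images, truth


# ---------------------------------------------------------------------------
# connectivity-profile cohort
# ---------------------------------------------------------------------------

def _archetypes(n_regions: int, k: int, separation: float, baseline: float, peak: float,
                support_per_cluster: int) -> np.ndarray:
    """Cluster archetype rate profiles: shared baseline + separated support peaks."""
    need = k * support_per_cluster
    if need > n_regions:
        raise InvalidArgumentError(
            f"{k} clusters x {support_per_cluster} support regions exceed {n_regions} regions"
        )
    arch = np.full((k, n_regions), baseline)
    for c in range(k):
        sl = slice(c * support_per_cluster, (c + 1) * support_per_cluster)
        arch[c, sl] += separation * peak
    return arch


def make_profile_cohort(
    n_seeds: int,
    n_regions: int,
    planted_k: int | tuple[int, int] | dict[str, int],
    separation: float,
    seed: int,
    n_subjects_per_group: int = 13,
    baseline_rate: float = 1.5,
    peak_rate: float = 8.0,
    support_per_cluster: int = 3,
    roi_name: str = "roi",
) -> tuple[list["pd.DataFrame"], GroundTruth]:
    """Generate per-subject seed-by-region connectivity count profiles.

    ``planted_k`` may be a single cluster count, a ``(patient, control)``
    pair, or a dict keyed by group name.  Counts are Poisson around the
    archetype rate of each seed's true cluster; ``separation`` scales the
    cluster-specific support peaks (0 = all archetypes identical).

    Returns one DataFrame per subject (rows = seeds, columns = region
    names, attrs carry subject/group/true labels) plus the ground truth.
    """
    if separation < 0:
        raise InvalidArgumentError(f"separation must be >= 0, got {separation}")
    if n_seeds < 1 or n_regions < 1 or n_subjects_per_group < 1:
        raise InvalidArgumentError("counts must be positive")
    if isinstance(planted_k, dict):
        k_by_group = {g: int(planted_k[g]) for g in GROUPS}
    elif isinstance(planted_k, (tuple, list)):
        k_by_group = {"patient": int(planted_k[0]), "control": int(planted_k[1])}
    else:
        k_by_group = {g: int(planted_k) for g in GROUPS}
    for g, k in k_by_group.items():
        if k < 1 or k > n_seeds:
            raise InvalidArgumentError(f"planted_k for {g} must be in [1, n_seeds], got {k}")

    rng = np.random.default_rng(seed)
    regions = [f"region_{j:02d}" for j in range(n_regions)]
    truth = GroundTruth(planted_k=dict(k_by_group), noise_sd=0.0)
    profiles: list[pd.DataFrame] = []
    sidx = 0
    for group in GROUPS:
        k = k_by_group[group]
        arch = _archetypes(n_regions, k, separation, baseline_rate, peak_rate, support_per_cluster)
        truth.archetypes[group] = arch
        for _ in range(n_subjects_per_group):
            subject_id = f"sub-{sidx:03d}"
            labels = np.tile(np.arange(k), n_seeds // k + 1)[:n_seeds]
            rng.shuffle(labels)
            counts = rng.poisson(arch[labels])
            df = pd.DataFrame(counts, columns=regions,
                              index=[f"{subject_id}_seed{j:03d}" for j in range(n_seeds)])
            df.attrs.update(subject_id=subject_id, group=group, roi_name=roi_name)
            truth.planted_labels[subject_id] = labels
            truth.groups.append(group)
            profiles.append(df)
            sidx += 1
    return profiles, truth


# ---------------------------------------------------------------------------
# toy streamline tracker
# ---------------------------------------------------------------------------

def toy_tracker(
    orientation_field: np.ndarray,
    seeds: np.ndarray,
    n_samples: int = 100,
    step: float = 1.0,
    angle_sd: float = 10.0,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_length: float = 200.0,
) -> np.ndarray:
    """Monte-Carlo streamline propagation through an orientation field.

    Streamlines start at each seed voxel's center and advance by ``step``
    mm along the local orientation, perturbed by angular noise of roughly
    ``angle_sd`` degrees (small-angle Gaussian on the direction vector),
    until they leave the volume or exceed ``max_length`` mm.  Each
    streamline contributes one visit per voxel it enters.

    Parameters
    ----------
    orientation_field : (nx, ny, nz, 3) array of unit vectors.
    seeds : (n_seeds, 3) integer voxel coordinates.

    Returns
    -------
    counts : (n_seeds, nx, ny, nz) visitation-count array.
    """
    field_arr = np.asarray(orientation_field, dtype=float)
    if field_arr.ndim != 4 or field_arr.shape[-1] != 3:
        raise InvalidArgumentError("orientation_field must have shape (nx, ny, nz, 3)")
    if step <= 0:
        raise InvalidArgumentError(f"step must be > 0, got {step}")
    dims = np.array(field_arr.shape[:3])
    seeds = np.atleast_2d(np.asarray(seeds, dtype=int))
    if np.any(seeds < 0) or np.any(seeds >= dims):
        raise InvalidArgumentError("seeds outside volume")
    vs = np.asarray(voxel_size, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = np.tan(np.deg2rad(angle_sd)) if angle_sd > 0 else 0.0
    max_steps = int(np.ceil(max_length / step))
    counts = np.zeros((len(seeds), *dims), dtype=np.int64)

    for i, sd_vox in enumerate(seeds):
        pos = np.repeat(((sd_vox + 0.5) * vs)[None, :], n_samples, axis=0)
        alive = np.ones(n_samples, dtype=bool)
        visited = [set() for _ in range(n_samples)]
        for _ in range(max_steps):
            vox = np.floor(pos / vs).astype(int)
            inside = np.all((vox >= 0) & (vox < dims), axis=1)
            alive &= inside
            if not alive.any():
                break
            act = np.where(alive)[0]
            for j in act:
                visited[j].add(tuple(vox[j]))
            dirs = field_arr[vox[act, 0], vox[act, 1], vox[act, 2]]
            norms = np.linalg.norm(dirs, axis=1)
            dead = norms < 1e-9
            if dead.any():
                alive[act[dead]] = False
                act = act[~dead]
                dirs = dirs[~dead]
                norms = norms[~dead]
                if len(act) == 0:
                    break
            dirs = dirs / norms[:, None]
            if sigma > 0:
                dirs = dirs + sigma * rng.standard_normal(dirs.shape)
                dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
            pos[act] += step * dirs
        for j in range(n_samples):
            for v in visited[j]:
                counts[i][v] += 1
    return counts


def downsample_counts(counts: np.ndarray, factor: int) -> np.ndarray:
    """Sum-pool a 3D count volume by an integer factor per axis.

    Emulates saving tractography visitation output at a coarser (e.g.
    5 mm) resolution before regional aggregation.  The volume is
    zero-padded up to a multiple of ``factor``.
    """
    if factor < 1:
        raise InvalidArgumentError("factor must be >= 1")
    if factor == 1:
        return counts.copy()
    dims = np.array(counts.shape)
    pad = (-dims) % factor
    padded = np.pad(counts, [(0, p) for p in pad])
    nx, ny, nz = np.array(padded.shape) // factor
    return (
        padded.reshape(nx, factor, ny, factor, nz, factor)
        .sum(axis=(1, 3, 5))
    )
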