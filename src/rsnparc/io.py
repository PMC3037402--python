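"""NIfTI, table and report I/O."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import GridSpec, Image4D, InvalidArgumentError, RsnparcError
from .synthgen import GroundTruth

__all__ = [
    "AlignmentError",
    "read_nifti",
    "write_nifti",
    "read_cohort",
    "save_ground_truth",
    "save_covariates",
    "load_covariates",
]


class AlignmentError(RsnparcError):
    """Cohort volumes do not share a voxel-to-world affine."""


def _grid_from(img: nib.Nifti1Image, tr: float | None) -> GridSpec:
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return GridSpec(dims=tuple(int(d) for d in img.shape[:3]),
                    voxel_size=tuple(float(z) for z in zooms[:3]), tr=tr)


def write_nifti(obj: Image4D | np.ndarray, path: str | Path,
                grid: GridSpec | None = None, affine: np.ndarray | None = None) -> Path:
    """Write an Image4D or plain 3D/4D array as NIfTI-1.

    Image4D data is stored spatial-first (x, y, z, t) with the grid's
    affine and TR; plain arrays use ``affine`` (default identity) or the
    given grid.
    """
    path = Path(path)
    if isinstance(obj, Image4D):
        data = obj.data.transpose(1, 2, 3, 0)
        aff = obj.grid.affine
        img = nib.Nifti1Image(data, aff)
        img.header.set_zooms((*obj.grid.voxel_size, obj.grid.tr))
    else:
        data = np.asarray(obj)
        if affine is None:
            affine = grid.affine if grid is not None else np.eye(4)
        img = nib.Nifti1Image(data, affine)
        if grid is not None:
            zooms = (*grid.voxel_size, grid.tr)[: data.ndim]
            img.header.set_zooms(zooms)
    nib.save(img, path)
    return path


def read_nifti(path: str | Path, tr: float | None = None):
    """Read a NIfTI-1 file.

    Returns an :class:`Image4D` for 4D files (data reordered to
    time-first) or a plain 3D ``np.ndarray`` for volumes.  Use
    ``nibabel`` directly when the affine of a 3D volume is needed.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several classes for bad format
        raise InvalidArgumentError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        grid = _grid_from(img, tr)
        return Image4D(data=data.transpose(3, 0, 1, 2), grid=grid, subject_id=path.stem)
    if data.ndim == 3:
        return data
    raise InvalidArgumentError(f"unsupported dimensionality {data.ndim} in {path}")


def read_cohort(paths: list[str | Path], tr: float | None = None) -> list[Image4D]:
    """Read a cohort of 4D files, enforcing a shared affine."""
    imgs = []
    ref_affine = None
    for p in paths:
        nimg = nib.load(Path(p))
        if ref_affine is None:
            ref_affine = nimg.affine
        elif not np.allclose(nimg.affine, ref_affine):
            raise AlignmentError(f"{p} has a different affine than the first cohort image")
        imgs.append(read_nifti(p, tr=tr))
    return imgs


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write the generator's planted truth as a JSON sidecar (scalars and labels;
    large volumes are summarized by shape)."""
    path = Path(path)
    doc = {
        "groups": truth.groups,
        "component_labels": truth.component_labels,
        "effect_networks": list(truth.effect_networks),
        "group_effect": truth.group_effect,
        "noise_sd": truth.noise_sd,
        "planted_k": truth.planted_k,
        "planted_labels": {k: np.asarray(v).tolist() for k, v in truth.planted_labels.items()},
        "network_maps_shape": (
            list(truth.network_maps.shape) if truth.network_maps is not None else None
        ),
        "grid": (
            {"dims": list(truth.grid.dims), "voxel_size": list(truth.grid.voxel_size),
             "tr": truth.grid.tr}
            if truth.grid is not None else None
        ),
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def save_covariates(images: list[Image4D], path: str | Path) -> Path:
    """Write subject id / group / mean motion as a CSV covariate table."""
    df = pd.DataFrame(
        {
            "subject_id": [im.subject_id for im in images],
            "group": [im.group for im in images],
            "mean_motion": [im.mean_motion for im in images],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def load_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
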