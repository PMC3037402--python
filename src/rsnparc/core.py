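"""Core data containers shared across the pipeline.

The raster currency of the functional pipeline is :class:`Image4D`: a
``(T, nx, ny, nz)`` float array tied to a :class:`GridSpec` describing
voxel geometry and repetition time.  Flattening to ``time x voxel``
matrices uses a fixed x-fastest raster order (the NIfTI convention), so
that voxel column ``i`` corresponds to grid index
``(i % nx, (i // nx) % ny, i // (nx * ny))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "Image4D",
    "RsnparcError",
    "InvalidArgumentError",
    "flatten",
    "unflatten",
]


class RsnparcError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidArgumentError(RsnparcError):
    """An argument violates a documented precondition."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry for a 3D (+time) acquisition.

    Parameters
    ----------
    dims : tuple of int
        Voxels per spatial axis ``(nx, ny, nz)``.
    voxel_size : tuple of float
        Voxel edge lengths in mm per axis.
    tr : float
        Repetition time in seconds (temporal sampling interval).
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    tr: float = 3.0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise InvalidArgumentError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidArgumentError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if self.tr <= 0:
            raise InvalidArgumentError(f"TR must be > 0, got {self.tr}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def nyquist(self) -> float:
        """Temporal Nyquist frequency in Hz."""
        return 0.5 / self.tr

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine: scaling by voxel size, origin at voxel (0,0,0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk * np.asarray(self.voxel_size)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz / np.asarray(self.voxel_size)


@dataclass
class Image4D:
    """A voxel time-series volume: ``data[t, x, y, z]`` on a :class:`GridSpec`.

    ``mean_motion`` carries the per-subject summary motion estimate (mean of
    the six rigid-body realignment parameters, arbitrary units) used as a
    confounding covariate in group statistics.
    """

    data: np.ndarray
    grid: GridSpec
    subject_id: str = ""
    mean_motion: float = 0.0
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidArgumentError(f"Image4D data must be 4D (t,x,y,z), got shape {self.data.shape}")
        if self.data.shape[1:] != self.grid.dims:
            raise InvalidArgumentError(
                f"data spatial shape {self.data.shape[1:]} does not match grid dims {self.grid.dims}"
            )
        if self.data.shape[0] < 2:
            raise InvalidArgumentError("time length must be >= 2")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("Image4D data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray) -> "Image4D":
        return Image4D(
            data=data,
            grid=self.grid,
            subject_id=self.subject_id,
            mean_motion=self.mean_motion,
            group=self.group,
        )


def _raster(volume_stack: np.ndarray) -> np.ndarray:
    """Reorder a (T, nx, ny, nz) stack into (T, N) with x-fastest columns."""
    t = volume_stack.shape[0]
    # transpose to (T, z, y, x): C-order flatten then runs x fastest
    return volume_stack.transpose(0, 3, 2, 1).reshape(t, -1)


def flatten(img: Image4D, mask: np.ndarray | None = None) -> np.ndarray:
    """Flatten a 4D image to a ``time x N`` matrix in x-fastest raster order.

    With a boolean ``mask``, only in-mask voxels are kept (N = mask count);
    with ``mask=None`` the full grid is used.  The full 53x63x35 acquisition
    grid yields N = 116865 columns.
    """
    flat = _raster(img.data)
    if mask is None:
        return flat
    mask = np.asarray(mask)
    if mask.shape != img.grid.dims:
        raise InvalidArgumentError(f"mask shape {mask.shape} does not match grid dims {img.grid.dims}")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if not mask.any():
        raise InvalidArgumentError("mask is empty: no voxels selected")
    return flat[:, _raster(mask[None])[0]]


def unflatten(matrix: np.ndarray, grid: GridSpec, mask: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`flatten`: rebuild a (T, nx, ny, nz) stack.

    Out-of-mask voxels are filled with zero.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    t = matrix.shape[0]
    nx, ny, nz = grid.dims
    full = np.zeros((t, grid.n_voxels))
    if mask is None:
        if matrix.shape[1] != grid.n_voxels:
            raise InvalidArgumentError(
                f"matrix has {matrix.shape[1]} columns but grid has {grid.n_voxels} voxels"
            )
        full = matrix
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.dims:
            raise InvalidArgumentError("mask shape does not match grid dims")
        idx = _raster(mask[None].astype(float))[0] > 0.5
        if matrix.shape[1] != idx.sum():
            raise InvalidArgumentError("matrix column count does not match mask voxel count")
        full[:, idx] = matrix
    # invert the (T, z, y, x) C-order raster
    return full.reshape(t, nz, ny, nx).transpose(0, 3, 2, 1)
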