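"""Temporal and spatial conditioning of 4D data before ICA.

Linear detrending plus band-pass filtering restricts each voxel time
series to the slow spontaneous-fluctuation band (default 0.01-0.08 Hz);
Gaussian smoothing (default 6 mm FWHM) conditions the spatial maps.  Both
are exposed as scikit-learn style transformers operating on ``time x N``
matrices, with :class:`~rsnparc.core.Image4D` convenience wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .core import Image4D, InvalidArgumentError, flatten, unflatten

__all__ = [
    "BandSpec",
    "BandpassDetrender",
    "GaussianSmoother",
    "detrend_bandpass",
    "smooth_gaussian",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandSpec:
    """A temporal pass band in Hz; must sit strictly inside (0, Nyquist)."""

    low: float = 0.01
    high: float = 0.08

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not (0.0 < self.low < self.high):
            raise InvalidArgumentError(f"need 0 < low < high, got [{self.low}, {self.high}]")
        if self.high >= nyquist:
            raise InvalidArgumentError(
                f"band high {self.high} Hz >= Nyquist {nyquist} Hz for TR={tr} s"
            )


def _band_response(freqs: np.ndarray, band: BandSpec, transition: float) -> np.ndarray:
    """Frequency response of the band-pass mask.

    ``transition`` is the half-cosine roll-off width as a fraction of each
    band edge; 0 gives a pure projection mask (exactly idempotent).  DC is
    always zeroed.
    """
    h = np.zeros_like(freqs)
    if transition <= 0:
        h[(freqs >= band.low) & (freqs <= band.high)] = 1.0
    else:
        lo0 = band.low * (1.0 - transition)
        hi1 = band.high * (1.0 + transition)
        ramp_up = (freqs >= lo0) & (freqs < band.low)
        ramp_dn = (freqs > band.high) & (freqs <= hi1)
        h[(freqs >= band.low) & (freqs <= band.high)] = 1.0
        if band.low > lo0:
            h[ramp_up] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp_up] - lo0) / (band.low - lo0)))
        if hi1 > band.high:
            h[ramp_dn] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp_dn] - band.high) / (hi1 - band.high)))
    h[freqs == 0.0] = 0.0
    return h


class BandpassDetrender(BaseEstimator, TransformerMixin):
    """Linear detrend followed by FFT-domain band-pass masking.

    Operates column-wise on ``time x N`` matrices.  The default mask is a
    brick-wall projection (transition=0), which is exactly idempotent and
    attenuates anything one octave outside the band completely; setting
    ``transition`` > 0 adds a half-cosine roll-off of that relative width
    at each edge.

    Parameters
    ----------
    low, high : float
        Pass band edges in Hz (default 0.01-0.08).
    tr : float
        Sampling interval in seconds.
    transition : float
        Relative half-cosine roll-off width per edge (0 = none).
    """

    def __init__(self, low: float = 0.01, high: float = 0.08, tr: float = 3.0, transition: float = 0.0):
        self.low = low
        self.high = high
        self.tr = tr
        self.transition = transition

    def fit(self, X: np.ndarray, y=None) -> "BandpassDetrender":
        X = np.asarray(X)
        BandSpec(self.low, self.high).validate(self.tr)
        t = X.shape[0]
        self.n_timepoints_ = t
        freqs = np.fft.rfftfreq(t, d=self.tr)
        self.response_ = _band_response(freqs, BandSpec(self.low, self.high), self.transition)
        # In-band leak of the linear-trend basis.  Removing it after
        # masking makes the operator the exact orthogonal projection onto
        # (band-limited ∩ trend-free), hence exactly idempotent.
        trend = np.arange(t, dtype=np.float64)
        trend -= trend.mean()
        leak = np.fft.irfft(np.fft.rfft(trend) * self.response_, n=t)
        norm2 = float(leak @ leak)
        self._trend_leak_ = leak if norm2 > 1e-12 else None
        self._trend_leak_norm2_ = norm2
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if not hasattr(self, "response_") or X.shape[0] != self.n_timepoints_:
            self.fit(X)
        out = signal.detrend(X, axis=0, type="linear")
        spec = np.fft.rfft(out, axis=0)
        spec *= self.response_[:, None] if out.ndim == 2 else self.response_
        out = np.fft.irfft(spec, n=X.shape[0], axis=0)
        if self._trend_leak_ is not None:
            coef = np.tensordot(self._trend_leak_, out, axes=(0, 0)) / self._trend_leak_norm2_
            out = out - self._trend_leak_[(slice(None),) + (None,) * (out.ndim - 1)] * coef
        return out


def detrend_bandpass(img: Image4D, band: BandSpec = BandSpec()) -> Image4D:
    """Remove per-voxel linear trends and restrict to the given pass band."""
    band.validate(img.grid.tr)
    est = BandpassDetrender(band.low, band.high, tr=img.grid.tr)
    flat = flatten(img)
    out = est.fit(flat).transform(flat)
    return img.copy_with(unflatten(out, img.grid))


class GaussianSmoother(BaseEstimator, TransformerMixin):
    """Volume-wise 3D Gaussian smoothing at a given FWHM in mm.

    The kernel width is converted per axis using the voxel sizes
    (sigma_vox = FWHM / (2 sqrt(2 ln 2)) / voxel_size).  Boundary handling
    is zero-padding without renormalization, so only interior voxels obey
    the constant-preservation property.
    """

    def __init__(self, fwhm_mm: float = 6.0, voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)):
        self.fwhm_mm = fwhm_mm
        self.voxel_size = voxel_size

    def fit(self, X=None, y=None) -> "GaussianSmoother":
        if self.fwhm_mm < 0:
            raise InvalidArgumentError(f"FWHM must be >= 0, got {self.fwhm_mm}")
        self.sigma_vox_ = tuple(
            self.fwhm_mm * FWHM_TO_SIGMA / v for v in self.voxel_size
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Smooth a (t, nx, ny, nz) stack or a single 3D volume."""
        self.fit()
        X = np.asarray(X, dtype=np.float64)
        if self.fwhm_mm == 0:
            return X.copy()
        if X.ndim == 3:
            return ndimage.gaussian_filter(X, sigma=self.sigma_vox_, mode="constant", cval=0.0)
        out = np.empty_like(X)
        for t in range(X.shape[0]):
            out[t] = ndimage.gaussian_filter(X[t], sigma=self.sigma_vox_, mode="constant", cval=0.0)
        return out


def smooth_gaussian(img: Image4D, fwhm_mm: float = 6.0) -> Image4D:
    """Smooth every volume of a 4D image with a 3D Gaussian of given FWHM."""
    sm = GaussianSmoother(fwhm_mm=fwhm_mm, voxel_size=img.grid.voxel_size)
    return img.copy_with(sm.transform(img.data))
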