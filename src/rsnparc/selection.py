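"""Automatic identification of functionally relevant components.

A component is kept when (i) its spatial map associates with the gray
matter rather than white matter or CSF prior maps, and (ii) its time
course concentrates at least half of its spectral power in the
low-frequency band 0.01-0.05 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator

from .core import InvalidArgumentError, RsnparcError

__all__ = [
    "SelectionCriteria",
    "ComponentSelector",
    "tissue_correlation",
    "spectral_power_fraction",
]


class DegenerateSeriesError(RsnparcError):
    """Spectral power fraction is undefined for a constant series."""


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for the keep/reject decision.

    ``gm_corr_min`` is an absolute floor on the GM correlation; WM and
    CSF use a relative rule by default (reject when either exceeds the
    GM correlation), optionally tightened by absolute ceilings.
    """

    lowband: tuple[float, float] = (0.01, 0.05)
    power_fraction_min: float = 0.5
    gm_corr_min: float = 0.15
    wm_corr_max: float | None = None
    csf_corr_max: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.power_fraction_min <= 1.0):
            raise InvalidArgumentError("power_fraction_min must be in [0, 1]")
        if not (0.0 < self.lowband[0] < self.lowband[1]):
            raise InvalidArgumentError(f"invalid low band {self.lowband}")


def tissue_correlation(
    component_map: np.ndarray,
    priors: dict[str, np.ndarray],
    brain_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson correlation of a spatial map with GM/WM/CSF priors over in-brain voxels.

    ``brain_mask`` defaults to voxels where the summed tissue probability
    exceeds 0.1.
    """
    for name in ("gm", "wm", "csf"):
        if name not in priors:
            raise InvalidArgumentError(f"missing tissue prior '{name}'")
        if not np.any(priors[name] > 0):
            raise InvalidArgumentError(f"tissue prior '{name}' is all zero")
    cmap = np.asarray(component_map, dtype=float)
    if brain_mask is None:
        brain_mask = (priors["gm"] + priors["wm"] + priors["csf"]) > 0.1
    x = cmap.reshape(-1)[brain_mask.reshape(-1)]
    out = {}
    for name in ("gm", "wm", "csf"):
        y = priors[name].reshape(-1)[brain_mask.reshape(-1)]
        out[name] = float(np.corrcoef(x, y)[0, 1])
    return out


def spectral_power_fraction(
    timecourse: np.ndarray, tr: float, lowband: tuple[float, float] = (0.01, 0.05)
) -> float:
    """Fraction of periodogram power inside ``lowband``, DC excluded.

    The denominator is the total power over (0, Nyquist].
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.ndim != 1 or tc.size < 16:
        raise InvalidArgumentError("timecourse must be 1D with length >= 16")
    if np.ptp(tc) == 0:
        raise DegenerateSeriesError("constant time series has no defined power fraction")
    freqs, power = signal.periodogram(tc, fs=1.0 / tr, detrend=False)
    nonzero = freqs > 0
    total = power[nonzero].sum()
    if total <= 0:
        raise DegenerateSeriesError("zero total power after removing DC")
    inband = nonzero & (freqs >= lowband[0]) & (freqs <= lowband[1])
    return float(power[inband].sum() / total)


class ComponentSelector(BaseEstimator):
    """Keep/reject classification of ICA components.

    Parameters
    ----------
    priors : dict with 'gm', 'wm', 'csf' probability volumes.
    tr : float
        Sampling interval of the component time courses, seconds.
    criteria : SelectionCriteria

    After ``fit(maps, timecourses)`` (maps ``(K, ...)`` spatial arrays,
    timecourses ``(T, K)`` or a list of per-subject ``(T, K)`` whose
    power fractions are averaged):

    ``keep_`` boolean (K,), ``gm_corr_``/``wm_corr_``/``csf_corr_``,
    ``power_fraction_``, ``reasons_`` (list of rejection reasons, empty
    for kept components).
    """

    def __init__(self, priors: dict[str, np.ndarray], tr: float = 3.0,
                 criteria: SelectionCriteria = SelectionCriteria()):
        self.priors = priors
        self.tr = tr
        self.criteria = criteria

    def fit(self, maps: np.ndarray, timecourses) -> "ComponentSelector":
        maps = np.asarray(maps)
        K = maps.shape[0]
        tc_list = timecourses if isinstance(timecourses, (list, tuple)) else [timecourses]
        gm = np.empty(K)
        wm = np.empty(K)
        csf = np.empty(K)
        pf = np.zeros(K)
        for k in range(K):
            corrs = tissue_correlation(maps[k], self.priors)
            gm[k], wm[k], csf[k] = corrs["gm"], corrs["wm"], corrs["csf"]
            fracs = [
                spectral_power_fraction(np.asarray(tc)[:, k], self.tr, self.criteria.lowband)
                for tc in tc_list
            ]
            pf[k] = float(np.mean(fracs))
        crit = self.criteria
        reasons: list[list[str]] = []
        keep = np.ones(K, dtype=bool)
        for k in range(K):
            why = []
            if gm[k] < crit.gm_corr_min:
                why.append(f"low GM correlation ({gm[k]:.2f} < {crit.gm_corr_min})")
            if wm[k] > gm[k] or (crit.wm_corr_max is not None and wm[k] > crit.wm_corr_max):
                why.append(f"high WM correlation ({wm[k]:.2f})")
            if csf[k] > gm[k] or (crit.csf_corr_max is not None and csf[k] > crit.csf_corr_max):
                why.append(f"high CSF correlation ({csf[k]:.2f})")
            if pf[k] < crit.power_fraction_min:
                why.append(
                    f"low-frequency power fraction {pf[k]:.2f} < {crit.power_fraction_min}"
                )
            keep[k] = not why
            reasons.append(why)
        self.gm_corr_, self.wm_corr_, self.csf_corr_ = gm, wm, csf
        self.power_fraction_ = pf
        self.keep_ = keep
        self.reasons_ = reasons
        return self

    def transform(self, maps: np.ndarray) -> np.ndarray:
        """Return only the kept components' maps."""
        return np.asarray(maps)[self.keep_]

    def match_templates(self, maps: np.ndarray, templates: dict[str, np.ndarray]) -> dict[str, int]:
        """Label kept components by their best-correlated user-supplied template map."""
        from .gica import zscore_maps

        flat = zscore_maps(np.asarray(maps).reshape(maps.shape[0], -1))
        out = {}
        for name, tmpl in templates.items():
            tz = zscore_maps(np.asarray(tmpl).reshape(1, -1))[0]
            r = flat @ tz / flat.shape[1]
            out[name] = int(np.argmax(np.abs(r)))
        return out
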