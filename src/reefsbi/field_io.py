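"""Ingest measured radiometry and turbidity.

Sub-surface radiometer pairs (downwelling irradiance Ed(0-) and upwelling
radiance Lu(0-), ~3.3 nm native resolution) are replicate-averaged before
taking the ratio rrs = mean(Lu)/mean(Ed), converted above-surface via
Rrs = 0.5 rrs / (1 - 1.5 rrs), and cubic-spline resampled to the 5 nm
working grid.  Turbidity readings bound suspended-particulate-matter
concentration through SPM = m x turbidity with the conversion factor m
between 1 and 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .forward_model import rrs_to_Rrs
from .spectra import Spectrum, WavelengthGrid

__all__ = [
    "RadiometrySample",
    "TurbiditySample",
    "compute_Rrs",
    "resample_spectrum",
    "spm_range",
    "read_radiometry_csv",
    "read_benthic_csv",
]


@dataclass(frozen=True)
class RadiometrySample:
    """Replicate Ed/Lu spectra on a shared native wavelength grid."""

    grid: WavelengthGrid
    ed_replicates: np.ndarray  # (n_rep, n_wl)
    lu_replicates: np.ndarray  # (n_rep, n_wl)
    site: str = ""

    def __post_init__(self):
        ed = np.atleast_2d(np.asarray(self.ed_replicates, dtype=float))
        lu = np.atleast_2d(np.asarray(self.lu_replicates, dtype=float))
        for name, arr in (("Ed", ed), ("Lu", lu)):
            if arr.shape[1] != len(self.grid):
                raise ValueError(f"{name} replicates do not match the native grid")
            if arr.shape[0] < 1:
                raise ValueError(f"need at least one {name} replicate")
        object.__setattr__(self, "ed_replicates", ed)
        object.__setattr__(self, "lu_replicates", lu)


@dataclass(frozen=True)
class TurbiditySample:
    """Scalar turbidity (NTU) with SPM conversion-factor bounds."""

    turbidity: float
    m_lo: float = 1.0
    m_hi: float = 5.0

    def __post_init__(self):
        if self.turbidity < 0:
            raise ValueError("turbidity must be non-negative")
        if not self.m_lo <= self.m_hi:
            raise ValueError("m_lo must be <= m_hi")


def compute_Rrs(sample: RadiometrySample) -> Spectrum:
    """Above-surface Rrs from replicate-averaged Ed and Lu.

    Replicates are averaged before taking the ratio; any zero mean Ed at a
    wavelength is rejected.
    """
    ed = sample.ed_replicates.mean(axis=0)
    lu = sample.lu_replicates.mean(axis=0)
    if np.any(ed == 0):
        bad = sample.grid.values[ed == 0][0]
        raise ValueError(f"mean Ed is zero at {bad} nm; cannot form rrs")
    rrs = lu / ed
    return Spectrum(sample.grid, rrs_to_Rrs(rrs), kind="abovesurface_Rrs")


def resample_spectrum(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Cubic-spline (not-a-knot) resampling onto ``target``.

    Exact at coincident nodes; extrapolation beyond the native range is
    rejected.
    """
    native = spectrum.grid.values
    if target.values[0] < native[0] or target.values[-1] > native[-1]:
        raise ValueError(
            f"target grid {target.values[0]}-{target.values[-1]} nm extends "
            f"beyond the native range {native[0]}-{native[-1]} nm"
        )
    spline = CubicSpline(native, spectrum.values)  # not-a-knot ends
    return Spectrum(target, spline(target.values), kind=spectrum.kind)


def spm_range(sample: TurbiditySample) -> dict:
    """SPM concentration range (g m^-3) implied by the turbidity reading."""
    lo = sample.m_lo * sample.turbidity
    hi = sample.m_hi * sample.turbidity
    return {"lower": lo, "upper": hi, "midpoint": 0.5 * (lo + hi)}


def _read_two_column_csv(path, value_name: str):
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (wavelength_nm, {value_name})")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(wl)) or np.any(~np.isfinite(vals)):
        bad = int(np.argwhere(~(np.isfinite(wl) & np.isfinite(vals)))[0, 0]) + 2
        raise ValueError(f"{path}: non-numeric value at row {bad}")
    return wl, vals


def read_radiometry_csv(ed_paths, lu_paths, site: str = "") -> RadiometrySample:
    """Read replicate Ed and Lu CSV files (wavelength_nm, value).

    All files must share an identical native grid; missing bands are
    rejected rather than gap-filled.
    """
    grids, ed_rows, lu_rows = [], [], []
    for paths, rows, name in ((ed_paths, ed_rows, "Ed"), (lu_paths, lu_rows, "Lu")):
        for p in paths:
            wl, vals = _read_two_column_csv(p, name)
            grids.append(wl)
            rows.append(vals)
    ref = grids[0]
    for wl in grids[1:]:
        if wl.shape != ref.shape or not np.allclose(wl, ref):
            raise ValueError("replicate files do not share one native grid")
    return RadiometrySample(
        WavelengthGrid(ref), np.stack(ed_rows), np.stack(lu_rows), site=site
    )


def read_benthic_csv(path, target: WavelengthGrid):
    """Read a 2-column benthic reflectance CSV and resample to ``target``."""
    from .spectra import BenthicSpectrum

    wl, rho = _read_two_column_csv(path, "reflectance")
    spline = CubicSpline(wl, rho)
    if target.values[0] < wl[0] or target.values[-1] > wl[-1]:
        raise ValueError("target grid extends beyond the benthic file range")
    return BenthicSpectrum(target, np.clip(spline(target.values), 0.0, 1.0))
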