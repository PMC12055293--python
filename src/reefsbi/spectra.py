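"""Wavelength grids and spectral containers.

The canonical working grid for the simulator is 400–700 nm at 5 nm
resolution (61 bands); a multispectral product reduces that to discrete
sensor band centers.  All spectra carry their grid so grid mismatches are
caught at the point of use rather than propagating silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "make_wavelength_grid",
    "Spectrum",
    "BenthicSpectrum",
    "IOPSpectra",
    "ParameterVector",
    "PARAM_NAMES",
]

#: Names and order of the five inferred quantities.
PARAM_NAMES = ("phytoplankton", "cdom440", "minerals", "wind", "depth")


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered set of wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if vals.size > 1 and not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


def make_wavelength_grid(
    start_nm: float, stop_nm: float, step_nm: float
) -> WavelengthGrid:
    """Build an inclusive uniform grid from ``start_nm`` to ``stop_nm``.

    The range must divide evenly by ``step_nm``; the canonical
    hyperspectral grid ``make_wavelength_grid(400, 700, 5)`` has 61 bands.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if stop_nm < start_nm:
        raise ValueError("stop_nm must be >= start_nm")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"range {start_nm}-{stop_nm} nm is not divisible by step {step_nm} nm"
        )
    n = int(round(n_steps)) + 1
    return WavelengthGrid(start_nm + step_nm * np.arange(n))


def _check_on_grid(values: np.ndarray, grid: WavelengthGrid, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (len(grid),):
        raise ValueError(
            f"{what} has {values.shape} values for a {len(grid)}-band grid"
        )
    return values


@dataclass(frozen=True)
class Spectrum:
    """Remote-sensing reflectance (sr^-1) on a wavelength grid.

    ``kind`` distinguishes sub-surface rrs(0-) from above-surface Rrs(0+).
    Noise-free simulated spectra are non-negative; noisy spectra may dip
    below zero because the additive Gaussian noise model is unclipped.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "abovesurface_Rrs"

    _KINDS = ("subsurface_rrs", "abovesurface_Rrs")

    def __post_init__(self):
        vals = _check_on_grid(self.values, self.grid, "spectrum")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite values")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class BenthicSpectrum:
    """Bottom (benthic) irradiance reflectance, dimensionless in [0, 1]."""

    grid: WavelengthGrid
    rho: np.ndarray

    def __post_init__(self):
        rho = _check_on_grid(self.rho, self.grid, "benthic reflectance")
        if np.any(rho < 0) or np.any(rho > 1):
            raise ValueError("benthic reflectance must lie in [0, 1]")
        object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class IOPSpectra:
    """Total absorption a and backscattering b_b of the water column (m^-1)."""

    grid: WavelengthGrid
    a: np.ndarray
    bb: np.ndarray

    def __post_init__(self):
        a = _check_on_grid(self.a, self.grid, "absorption")
        bb = _check_on_grid(self.bb, self.grid, "backscatter")
        if np.any(a <= 0) or np.any(bb <= 0):
            raise ValueError("absorption and backscatter must be strictly positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "bb", bb)

    @property
    def u(self) -> np.ndarray:
        """Backscatter fraction u = b_b / (a + b_b), in (0, 1)."""
        return self.bb / (self.a + self.bb)

    @property
    def kappa(self) -> np.ndarray:
        """Extinction-like sum kappa = a + b_b (m^-1)."""
        return self.a + self.bb


# Prior truncation / range bounds shared by validation and inference.
PARAM_BOUNDS = {
    "phytoplankton": (0.0, 7.0),
    "cdom440": (0.0, 2.5),
    "minerals": (0.0, 30.0),
    "wind": (0.0, np.inf),
    "depth": (0.10, 20.00),
}


@dataclass(frozen=True)
class ParameterVector:
    """The five inferred quantities theta.

    Units: phytoplankton mg m^-3, cdom440 m^-1 at 440 nm, minerals g m^-3,
    wind m s^-1, depth m.  Bounds follow the prior truncation thresholds
    (7 / 2.5 / 30) and the depth range 0.10–20.00 m.
    """

    phytoplankton: float
    cdom440: float
    minerals: float
    wind: float
    depth: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            lo, hi = PARAM_BOUNDS[name]
            strict_low = name != "depth"  # constituents and wind are > 0
            if (v < lo) or (strict_low and v <= lo) or (v > hi):
                raise ValueError(
                    f"{name}={v} outside allowed range "
                    f"{'(' if strict_low else '['}{lo}, {hi}]"
                )
            object.__setattr__(self, name, v)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {arr.shape}")
        return cls(*arr)


def in_support(theta_array: np.ndarray) -> np.ndarray:
    """Vectorized support check for an (n, 5) array of parameter draws.

    Returns a boolean mask: constituents and wind strictly positive and
    within the truncation bounds; depth within its closed range.
    """
    th = np.atleast_2d(np.asarray(theta_array, dtype=float))
    ok = np.ones(th.shape[0], dtype=bool)
    for j, name in enumerate(PARAM_NAMES):
        lo, hi = PARAM_BOUNDS[name]
        col = th[:, j]
        if name == "depth":
            ok &= (col >= lo) & (col <= hi)
        else:
            ok &= (col > lo) & (col <= hi) if np.isfinite(hi) else (col > lo)
    return ok
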