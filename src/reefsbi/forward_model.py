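"""Deterministic forward simulator: parameters -> remote-sensing reflectance.

The water column is described by bio-optical models that map constituent
concentrations to inherent optical properties (absorption a and
backscatter b_b), and the two-term semi-analytical shallow-water solution
converts those, together with depth and a benthic albedo, to sub-surface
remote-sensing reflectance:

    rrs = rrs_deep * (1 - exp(-(1/cos(th_w) + 1.03 (1+2.4 u)^0.5) kappa H))
          + (rho_b / pi) * exp(-(1/cos(th_w) + 1.04 (1+5.4 u)^0.5) kappa H)

with u = b_b/(a+b_b), kappa = a + b_b and the optically deep reflectance
rrs_deep = (g0 + g1 u) u, g0 = 0.084, g1 = 0.170.  Above-surface
reflectance follows from Rrs = 0.5 rrs / (1 - 1.5 rrs) plus a spectrally
flat wind-dependent surface term.  The simulator is deterministic; all
coefficients live in :class:`BioOpticsConfig` and are overridable, and any
callable matching :class:`Simulator` can replace the bundled model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from . import optics_data
from .spectra import (
    BenthicSpectrum,
    IOPSpectra,
    ParameterVector,
    Spectrum,
    WavelengthGrid,
)

__all__ = [
    "BioOpticsConfig",
    "Simulator",
    "ShallowWaterSimulator",
    "total_absorption",
    "total_backscatter",
    "simulate_rrs",
    "rrs_to_Rrs",
    "Rrs_to_rrs",
]


@dataclass(frozen=True)
class BioOpticsConfig:
    """Constituent optical coefficients and viewing geometry.

    Defaults are literature-standard values with linear concentration
    scaling.  ``aph440``: chlorophyll-specific absorption at 440 nm
    (m^2 mg^-1); ``s_cdom``/``s_mineral``: exponential spectral slopes
    (nm^-1); ``am440``: mineral-specific absorption at 440 nm (m^2 g^-1);
    ``k_glint``: flat above-surface wind term (sr^-1 per m s^-1);
    ``sun_zenith_deg``: solar zenith in air, refracted with index 1.34.
    """

    aph440: float = 0.05
    s_cdom: float = 0.015
    am440: float = 0.03
    s_mineral: float = 0.011
    bbph_coeff: float = 0.01
    bbm_coeff: float = 0.012
    bbm_exponent: float = 0.8
    g0: float = 0.084
    g1: float = 0.170
    k_glint: float = 2e-5
    sun_zenith_deg: float = 30.0
    refractive_index: float = 1.34

    @property
    def cos_theta_w(self) -> float:
        """Cosine of the in-water solar zenith after refraction."""
        sin_air = np.sin(np.deg2rad(self.sun_zenith_deg))
        sin_w = sin_air / self.refractive_index
        return float(np.sqrt(1.0 - sin_w**2))


def _theta_values(theta) -> tuple[float, float, float, float, float]:
    """Unpack a ParameterVector or a plain 5-sequence (chl, cdom, min, wind, H).

    Plain sequences skip prior-bound validation so that physical limits
    (e.g. effectively infinite depth) can be exercised directly.
    """
    if isinstance(theta, ParameterVector):
        return (
            theta.phytoplankton,
            theta.cdom440,
            theta.minerals,
            theta.wind,
            theta.depth,
        )
    arr = np.asarray(theta, dtype=float)
    if arr.shape != (5,):
        raise ValueError("theta must be a ParameterVector or a length-5 sequence")
    return tuple(arr)


def total_absorption(
    theta, grid: WavelengthGrid, config: BioOpticsConfig | None = None
) -> np.ndarray:
    """Total absorption a(lambda) = a_w + a_ph + a_g + a_m (m^-1)."""
    cfg = config or BioOpticsConfig()
    chl, cdom440, minerals, _, _ = _theta_values(theta)
    lam = grid.values
    a_w = optics_data.pure_water_absorption(grid)
    a_ph = cfg.aph440 * chl * optics_data.phytoplankton_absorption_shape(grid)
    a_g = cdom440 * np.exp(-cfg.s_cdom * (lam - 440.0))
    a_m = minerals * cfg.am440 * np.exp(-cfg.s_mineral * (lam - 440.0))
    return a_w + a_ph + a_g + a_m


def total_backscatter(
    theta, grid: WavelengthGrid, config: BioOpticsConfig | None = None
) -> np.ndarray:
    """Total backscatter bb(lambda) = bb_w + bb_ph + bb_m (m^-1).

    CDOM is dissolved and contributes no backscatter.
    """
    cfg = config or BioOpticsConfig()
    chl, _, minerals, _, _ = _theta_values(theta)
    lam = grid.values
    bb_w = optics_data.pure_water_backscatter(grid)
    bb_ph = cfg.bbph_coeff * (0.30 * chl**0.62) * (550.0 / lam)
    bb_m = minerals * cfg.bbm_coeff * (550.0 / lam) ** cfg.bbm_exponent
    return bb_w + bb_ph + bb_m


def compute_iops(
    theta, grid: WavelengthGrid, config: BioOpticsConfig | None = None
) -> IOPSpectra:
    cfg = config or BioOpticsConfig()
    return IOPSpectra(
        grid, total_absorption(theta, grid, cfg), total_backscatter(theta, grid, cfg)
    )


def rrs_to_Rrs(rrs):
    """Sub-surface to above-surface reflectance: Rrs = 0.5 rrs / (1 - 1.5 rrs).

    Elementwise; rejects values at or beyond the pole rrs = 2/3.
    """
    rrs = np.asarray(rrs, dtype=float)
    if np.any(rrs >= 2.0 / 3.0):
        raise ValueError("rrs >= 2/3 is non-physical (pole of the conversion)")
    out = 0.5 * rrs / (1.0 - 1.5 * rrs)
    return out if out.ndim else float(out)


def Rrs_to_rrs(Rrs):
    """Inverse conversion: rrs = Rrs / (0.5 + 1.5 Rrs)."""
    Rrs = np.asarray(Rrs, dtype=float)
    out = Rrs / (0.5 + 1.5 * Rrs)
    return out if out.ndim else float(out)


def simulate_rrs(
    theta,
    benthic: BenthicSpectrum,
    grid: WavelengthGrid,
    config: BioOpticsConfig | None = None,
) -> Spectrum:
    """Forward-simulate above-surface remote-sensing reflectance.

    Deterministic: no internal randomness.  Depth controls the blend
    between the optically deep water-column term and the bottom term; wind
    adds a spectrally flat surface perturbation above the surface.
    ``theta`` may be a :class:`ParameterVector` or a plain 5-sequence.
    """
    cfg = config or BioOpticsConfig()
    if benthic.grid != grid:
        raise ValueError("benthic spectrum grid does not match the working grid")
    _, _, _, wind, depth = _theta_values(theta)
    if depth < 0:
        raise ValueError("depth must be non-negative")

    iops = compute_iops(theta, grid, cfg)
    u = iops.u
    kappa = iops.kappa
    inv_cos = 1.0 / cfg.cos_theta_w

    rrs_deep = (cfg.g0 + cfg.g1 * u) * u
    du_c = inv_cos + 1.03 * np.sqrt(1.0 + 2.4 * u)   # water-column path factor
    du_b = inv_cos + 1.04 * np.sqrt(1.0 + 5.4 * u)   # bottom path factor
    kh = kappa * depth
    rrs = rrs_deep * (1.0 - np.exp(-du_c * kh)) + (benthic.rho / np.pi) * np.exp(
        -du_b * kh
    )

    Rrs = rrs_to_Rrs(rrs) + cfg.k_glint * wind
    return Spectrum(grid, Rrs, kind="abovesurface_Rrs")


class Simulator(Protocol):
    """Contract for pluggable forward simulators."""

    grid: WavelengthGrid

    def __call__(self, theta: ParameterVector) -> Spectrum: ...


@dataclass
class ShallowWaterSimulator:
    """Bundled semi-analytical simulator bound to a grid and benthic albedo.

    Satisfies the :class:`Simulator` contract; alternative radiative
    transfer engines can be substituted anywhere a simulator is accepted.
    """

    grid: WavelengthGrid
    benthic: BenthicSpectrum | None = None
    config: BioOpticsConfig = field(default_factory=BioOpticsConfig)

    def __post_init__(self):
        if self.benthic is None:
            self.benthic = optics_data.default_benthic_spectrum(self.grid)
        elif self.benthic.grid != self.grid:
            raise ValueError("benthic spectrum must be on the simulator grid")

    def __call__(self, theta: ParameterVector) -> Spectrum:
        return simulate_rrs(theta, self.benthic, self.grid, self.config)

    def simulate_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Vectorized forward run over an (n, 5) parameter array.

        Equivalent to calling the simulator row by row; used by the
        simulation campaign for speed.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        cfg = self.config
        lam = self.grid.values[None, :]
        chl = thetas[:, 0:1]
        cdom = thetas[:, 1:2]
        mins = thetas[:, 2:3]
        wind = thetas[:, 3:4]
        depth = thetas[:, 4:5]

        a = (
            optics_data.pure_water_absorption(self.grid)[None, :]
            + cfg.aph440 * chl * optics_data.phytoplankton_absorption_shape(self.grid)[None, :]
            + cdom * np.exp(-cfg.s_cdom * (lam - 440.0))
            + mins * cfg.am440 * np.exp(-cfg.s_mineral * (lam - 440.0))
        )
        bb = (
            optics_data.pure_water_backscatter(self.grid)[None, :]
            + cfg.bbph_coeff * (0.30 * chl**0.62) * (550.0 / lam)
            + mins * cfg.bbm_coeff * (550.0 / lam) ** cfg.bbm_exponent
        )
        u = bb / (a + bb)
        kappa = a + bb
        inv_cos = 1.0 / cfg.cos_theta_w
        rrs_deep = (cfg.g0 + cfg.g1 * u) * u
        du_c = inv_cos + 1.03 * np.sqrt(1.0 + 2.4 * u)
        du_b = inv_cos + 1.04 * np.sqrt(1.0 + 5.4 * u)
        kh = kappa * depth
        rho = self.benthic.rho[None, :]
        rrs = rrs_deep * (1.0 - np.exp(-du_c * kh)) + (rho / np.pi) * np.exp(-du_b * kh)
        return 0.5 * rrs / (1.0 - 1.5 * rrs) + cfg.k_glint * wind

    def with_benthic(self, benthic: BenthicSpectrum) -> "ShallowWaterSimulator":
        return ShallowWaterSimulator(self.grid, benthic, self.config)
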