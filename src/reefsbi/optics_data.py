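"""Bundled literature optical tables and default benthic reflectance.

Pure-water absorption follows the standard laboratory measurements for
clear natural water (tabulated at 10 nm, 400-710 nm, cubic-interpolated to
the working grid).  Pure seawater backscatter uses the classical power law
in wavelength.  The default benthic spectrum is a smooth brown-coral-like
curve: low reflectance in the blue, a chlorophyll absorption dip near
675 nm from the symbiont pigments, and a steep red-edge rise.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .spectra import BenthicSpectrum, WavelengthGrid

# Pure-water absorption a_w (m^-1), 400-710 nm at 10 nm.
_AW_WAVELENGTHS = np.arange(400.0, 711.0, 10.0)
_AW_VALUES = np.array(
    [
        0.00663, 0.00473, 0.00454, 0.00495, 0.00635, 0.00922, 0.00979, 0.0106,
        0.0127, 0.0150, 0.0204, 0.0325, 0.0409, 0.0434, 0.0474, 0.0565,
        0.0619, 0.0695, 0.0896, 0.1351, 0.2224, 0.2644, 0.2755, 0.2916,
        0.3108, 0.340, 0.410, 0.439, 0.465, 0.516, 0.624, 0.827,
    ]
)

_aw_spline = CubicSpline(_AW_WAVELENGTHS, _AW_VALUES)


def pure_water_absorption(grid: WavelengthGrid) -> np.ndarray:
    """Pure-water absorption a_w(lambda) in m^-1 on ``grid``."""
    lam = grid.values
    if lam[0] < _AW_WAVELENGTHS[0] or lam[-1] > _AW_WAVELENGTHS[-1]:
        raise ValueError(
            f"grid {lam[0]}-{lam[-1]} nm outside bundled pure-water table "
            f"range {_AW_WAVELENGTHS[0]}-{_AW_WAVELENGTHS[-1]} nm"
        )
    return _aw_spline(lam)


def pure_water_backscatter(grid: WavelengthGrid) -> np.ndarray:
    """Pure-seawater backscatter bb_w(lambda) = 0.5 * 0.0049 * (450/lambda)^4.32."""
    return 0.5 * 0.0049 * (450.0 / grid.values) ** 4.32


def phytoplankton_absorption_shape(grid: WavelengthGrid) -> np.ndarray:
    """Normalized chlorophyll-specific absorption shape, unit peak at 440 nm.

    Sum of Gaussians reproducing the twin absorption maxima near 440 and
    675 nm with a shoulder in the blue-green.
    """
    lam = grid.values
    shape = (
        np.exp(-0.5 * ((lam - 440.0) / 30.0) ** 2)
        + 0.25 * np.exp(-0.5 * ((lam - 490.0) / 35.0) ** 2)
        + 0.55 * np.exp(-0.5 * ((lam - 675.0) / 11.0) ** 2)
    )
    peak = (
        np.exp(-0.5 * ((440.0 - 440.0) / 30.0) ** 2)
        + 0.25 * np.exp(-0.5 * ((440.0 - 490.0) / 35.0) ** 2)
        + 0.55 * np.exp(-0.5 * ((440.0 - 675.0) / 11.0) ** 2)
    )
    return shape / peak


def default_benthic_spectrum(grid: WavelengthGrid) -> BenthicSpectrum:
    """Synthetic brown-coral-like bottom reflectance on ``grid``.

    A constructed stand-in for a measured coral albedo: not a library
    spectrum, but shares the qualitative features used in shallow-water
    inversion work (dark blue, brighter red, 675 nm pigment dip).
    """
    lam = grid.values
    base = 0.03 + 0.13 / (1.0 + np.exp(-(lam - 605.0) / 35.0))
    dip = 0.035 * np.exp(-0.5 * ((lam - 675.0) / 12.0) ** 2)
    rho = np.clip(base - dip, 0.0, 1.0)
    return BenthicSpectrum(grid, rho)
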