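"""Simulation campaign, observation noise, band reduction and persistence.

A campaign pairs prior draws theta with forward-simulated spectra x.
Observation noise is additive zero-mean Gaussian with a per-spectrum
variance set by a signal-to-noise ratio:

    SNR = E[signal_l^2] / E[noise_l^2],   sigma^2 = (sum_l signal_l^2 / N) / SNR

where N is the number of wavelengths of that spectrum.  Noisy values are
not clipped at zero, preserving the additive Gaussian model for the
estimator.  Band reduction to a multispectral sensor takes the value at
the nearest grid wavelength per band center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import PARAM_NAMES, Spectrum, WavelengthGrid

__all__ = [
    "NoiseModel",
    "SensorDef",
    "MICASENSE_DUAL",
    "SimulatedDataset",
    "run_campaign",
    "add_noise",
    "add_noise_batch",
    "downsample_to_bands",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]

SNR_PRESETS = (50, 100, 500)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise at a fixed signal-to-noise ratio."""

    snr: float
    mode: str = "additive"

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.mode != "additive":
            raise ValueError("only additive noise is supported")

    def sigma(self, values: np.ndarray) -> float:
        """Per-spectrum noise s.d.: sigma^2 = mean(signal^2) / SNR."""
        values = np.asarray(values, dtype=float)
        return float(np.sqrt(np.mean(values**2) / self.snr))


@dataclass(frozen=True)
class SensorDef:
    """A multispectral sensor as a named list of band centers (nm)."""

    name: str
    band_centers: tuple

    def __post_init__(self):
        centers = tuple(float(c) for c in self.band_centers)
        if list(centers) != sorted(centers):
            raise ValueError("band centers must be sorted")
        object.__setattr__(self, "band_centers", centers)


#: MicaSense RedEdge-MX Dual Camera visible + red-edge band set.
MICASENSE_DUAL = SensorDef(
    "micasense_rededge_mx_dual", (444, 475, 531, 560, 650, 668, 705)
)


@dataclass
class SimulatedDataset:
    """Paired (theta, x) records plus campaign metadata.

    ``theta`` is (n, 5) in canonical parameter order; ``X`` is (n, B) on
    ``grid``.  ``metadata`` records seed, SNR, sensor and counts.
    """

    theta: np.ndarray
    X: np.ndarray
    grid: WavelengthGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.theta.shape[0] != self.X.shape[0]:
            raise ValueError("theta and X must have the same number of records")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("spectra do not match the stated grid")
        self.metadata = dict(self.metadata)
        self.metadata.setdefault("n_records", self.theta.shape[0])

    def __len__(self) -> int:
        return self.theta.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.X[i])


def run_campaign(priors, simulator, n: int, seed) -> SimulatedDataset:
    """Draw n prior samples and forward-simulate each (noise-free)."""
    from .priors import sample_prior

    if n < 1:
        raise ValueError("n must be >= 1")
    thetas = sample_prior(priors, n, seed)
    if hasattr(simulator, "simulate_batch"):
        X = simulator.simulate_batch(thetas)
    else:
        rows = []
        for i, t in enumerate(thetas):
            try:
                rows.append(simulator(t).values)
            except Exception as err:
                raise RuntimeError(f"simulator failed on draw {i}: theta={t}") from err
        X = np.stack(rows)
    if not np.all(np.isfinite(X)):
        bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0, 0])
        raise RuntimeError(f"simulator produced non-finite output for theta={thetas[bad]}")
    meta = {"seed": int(seed), "snr": None, "sensor": None, "n_records": n}
    return SimulatedDataset(thetas, X, simulator.grid, meta)


def add_noise(spectrum: Spectrum, noise: NoiseModel, seed) -> Spectrum:
    """Add i.i.d. zero-mean Gaussian noise with the SNR-implied sigma."""
    rng = np.random.default_rng(seed)
    sigma = noise.sigma(spectrum.values)
    return Spectrum(
        spectrum.grid,
        spectrum.values + rng.normal(0.0, sigma, size=spectrum.values.shape),
        kind=spectrum.kind,
    )


def add_noise_batch(X: np.ndarray, noise: NoiseModel, seed) -> np.ndarray:
    """Vectorized noise injection: one sigma per spectrum (row)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.mean(X**2, axis=1, keepdims=True) / noise.snr)
    return X + rng.normal(size=X.shape) * sigma


def add_noise_dataset(dataset: SimulatedDataset, noise: NoiseModel, seed) -> SimulatedDataset:
    Xn = add_noise_batch(dataset.X, noise, seed)
    meta = dict(dataset.metadata)
    meta["snr"] = noise.snr
    return SimulatedDataset(dataset.theta.copy(), Xn, dataset.grid, meta)


def _band_indices(grid: WavelengthGrid, sensor: SensorDef) -> np.ndarray:
    lam = grid.values
    step = float(np.median(np.diff(lam))) if len(grid) > 1 else np.inf
    idx = []
    for c in sensor.band_centers:
        if c < lam[0] - step or c > lam[-1] + step:
            raise ValueError(
                f"band center {c} nm farther than one grid step beyond "
                f"the grid range {lam[0]}-{lam[-1]} nm"
            )
        dist = np.abs(lam - c)
        # ties resolve toward the lower wavelength (argmin takes the first)
        idx.append(int(np.argmin(dist)))
    return np.asarray(idx)


def downsample_to_bands(spectrum: Spectrum, sensor: SensorDef) -> Spectrum:
    """Reduce a spectrum to sensor bands by nearest-grid-point sampling."""
    idx = _band_indices(spectrum.grid, sensor)
    return Spectrum(
        WavelengthGrid(np.asarray(sensor.band_centers, dtype=float)),
        spectrum.values[idx],
        kind=spectrum.kind,
    )


def downsample_dataset(dataset: SimulatedDataset, sensor: SensorDef) -> SimulatedDataset:
    idx = _band_indices(dataset.grid, sensor)
    meta = dict(dataset.metadata)
    meta["sensor"] = sensor.name
    return SimulatedDataset(
        dataset.theta.copy(),
        dataset.X[:, idx],
        WavelengthGrid(np.asarray(sensor.band_centers, dtype=float)),
        meta,
    )


def split_dataset(dataset: SimulatedDataset, n_test: int, seed):
    """Random disjoint train/test split, reproducible under seed."""
    n = len(dataset)
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])

    def _sub(idx, role):
        meta = dict(dataset.metadata)
        meta["n_records"] = idx.size
        meta["split"] = role
        return SimulatedDataset(dataset.theta[idx], dataset.X[idx], dataset.grid, meta)

    return _sub(train_idx, "train"), _sub(test_idx, "test")


def write_dataset(dataset: SimulatedDataset, path) -> None:
    """Persist as theta CSV + spectra CSV + JSON metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dataset.theta, columns=list(PARAM_NAMES)).to_csv(
        path / "theta.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        dataset.X, columns=[f"{w:g}" for w in dataset.grid.values]
    ).to_csv(path / "spectra.csv", index=False, float_format="%.17g")
    meta = {k: v for k, v in dataset.metadata.items()}
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_dataset(path) -> SimulatedDataset:
    path = Path(path)
    try:
        theta = pd.read_csv(path / "theta.csv", float_precision="round_trip")
        spectra = pd.read_csv(path / "spectra.csv", float_precision="round_trip")
    except Exception as err:
        raise ValueError(f"malformed dataset under {path}: {err}") from err
    if list(theta.columns) != list(PARAM_NAMES):
        raise ValueError(f"unexpected theta columns {list(theta.columns)}")
    grid = WavelengthGrid(np.asarray([float(c) for c in spectra.columns]))
    with open(path / "metadata.json") as fh:
        meta = json.load(fh)
    return SimulatedDataset(theta.to_numpy(), spectra.to_numpy(), grid, meta)
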