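"""End-to-end convenience: campaign -> train -> evaluation-ready bundle.

One call reproduces the standard study design: draw parameters from the
priors, forward-simulate reflectance, split train/test, train the MDN
posterior estimator with minibatch noise re-sampling at the configured
SNR, and apply one fixed noise realization to the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dataset as ds
from .config import stage_seed
from .dataset import NoiseModel, SensorDef, SimulatedDataset
from .forward_model import BioOpticsConfig, ShallowWaterSimulator
from .mdn import MDNConfig
from .npe import PosteriorEstimator, train_estimator
from .priors import PriorSet, default_priors
from .spectra import make_wavelength_grid

__all__ = ["PipelineResult", "run_pipeline"]


class BandSimulator:
    """Simulator contract adapter: hyperspectral forward run + band reduction."""

    def __init__(self, base: ShallowWaterSimulator, sensor: SensorDef):
        from .dataset import _band_indices
        from .spectra import Spectrum, WavelengthGrid

        self._base = base
        self._idx = _band_indices(base.grid, sensor)
        self.grid = WavelengthGrid(np.asarray(sensor.band_centers, dtype=float))
        self._Spectrum = Spectrum

    def __call__(self, theta):
        return self._Spectrum(self.grid, self._base(theta).values[self._idx])

    def simulate_batch(self, thetas):
        return self._base.simulate_batch(thetas)[:, self._idx]


@dataclass
class PipelineResult:
    estimator: PosteriorEstimator
    train: SimulatedDataset  # noise-free spectra
    test: SimulatedDataset   # fixed noisy realization
    simulator: object        # produces spectra on the estimator's grid
    noise: NoiseModel


def run_pipeline(
    n_simulations: int = 30000,
    n_test: int = 1000,
    snr: float = 100.0,
    seed: int = 0,
    priors: PriorSet | None = None,
    mdn_config: MDNConfig | None = None,
    sensor: SensorDef | None = None,
    bio_config: BioOpticsConfig | None = None,
) -> PipelineResult:
    """Run the full simulation + training pipeline.

    All stage seeds derive from ``seed``.  With ``sensor`` given, the
    simulation grid is extended to cover the red-edge band and spectra
    are reduced to the sensor bands before noise and training.
    """
    priors = priors or default_priors()
    grid_stop = 700.0 if sensor is None else max(700.0, max(sensor.band_centers))
    grid = make_wavelength_grid(400.0, grid_stop, 5.0)
    sim = ShallowWaterSimulator(grid, config=bio_config or BioOpticsConfig())
    noise = NoiseModel(snr)

    data = ds.run_campaign(priors, sim, n_simulations, stage_seed(seed, "campaign"))
    if sensor is not None:
        data = ds.downsample_dataset(data, sensor)
    train, test = ds.split_dataset(data, n_test, stage_seed(seed, "split"))
    train.metadata["snr"] = snr
    train.metadata["noise"] = "resampled-at-train"
    test = ds.add_noise_dataset(test, noise, stage_seed(seed, "noise"))
    test.metadata["noise"] = "applied"

    est = train_estimator(
        train, mdn_config or MDNConfig(), seed=stage_seed(seed, "train"), noise=noise
    )
    out_sim = sim if sensor is None else BandSimulator(sim, sensor)
    return PipelineResult(estimator=est, train=train, test=test, simulator=out_sim, noise=noise)
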