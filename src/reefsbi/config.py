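"""Run configuration: one YAML file drives the whole pipeline.

A single master seed is split into independent per-stage child seeds
(prior sampling, noise, training, diagnostics, inference) so the full
workflow is reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dataset import MICASENSE_DUAL, NoiseModel, SensorDef
from .forward_model import BioOpticsConfig
from .mdn import MDNConfig
from .priors import PriorSet, TruncatedLognormalSpec, UniformSpec, default_priors
from .spectra import WavelengthGrid, make_wavelength_grid

__all__ = ["RunConfig", "load_config", "stage_seed"]

_STAGES = ("campaign", "noise", "split", "train", "diagnose", "infer")


@dataclass
class RunConfig:
    priors: PriorSet = field(default_factory=default_priors)
    bio_optics: BioOpticsConfig = field(default_factory=BioOpticsConfig)
    mdn: MDNConfig = field(default_factory=MDNConfig)
    grid_start: float = 400.0
    grid_stop: float = 700.0
    grid_step: float = 5.0
    n_simulations: int = 30000
    n_test: int = 1000
    snr: float = 100.0
    sensor: str | None = None  # None = hyperspectral; "micasense" = 7-band
    master_seed: int = 0

    def grid(self) -> WavelengthGrid:
        stop = self.grid_stop
        if self.sensor is not None:
            # extend so the red-edge band center stays within one grid step
            stop = max(stop, max(self.sensor_def().band_centers))
        return make_wavelength_grid(self.grid_start, stop, self.grid_step)

    def sensor_def(self) -> SensorDef:
        if self.sensor in (None, "hyperspectral"):
            raise ValueError("no multispectral sensor configured")
        if self.sensor in ("micasense", MICASENSE_DUAL.name):
            return MICASENSE_DUAL
        raise ValueError(f"unknown sensor {self.sensor!r}")

    def noise(self) -> NoiseModel:
        return NoiseModel(self.snr)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _prior_from_dict(d: dict) -> PriorSet:
    defaults = default_priors()
    kwargs = {}
    for name in ("phytoplankton", "cdom440", "minerals", "wind"):
        spec = d.get(name)
        if spec is None:
            kwargs[name] = getattr(defaults, name)
        else:
            kwargs[name] = TruncatedLognormalSpec(
                mu=float(spec["mu"]),
                sigma=float(spec["sigma"]),
                upper=float(spec.get("upper", np.inf)),
            )
    spec = d.get("depth")
    kwargs["depth"] = (
        getattr(defaults, "depth")
        if spec is None
        else UniformSpec(float(spec["low"]), float(spec["high"]))
    )
    return PriorSet(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = RunConfig()
    known = {
        "grid_start", "grid_stop", "grid_step", "n_simulations", "n_test",
        "snr", "sensor", "master_seed",
    }
    for key, val in raw.items():
        if key in known:
            setattr(cfg, key, val)
        elif key == "priors":
            cfg.priors = _prior_from_dict(val)
        elif key == "bio_optics":
            cfg.bio_optics = BioOpticsConfig(**val)
        elif key == "mdn":
            cfg.mdn = MDNConfig(**val)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    if cfg.n_simulations < 2 or not 0 < cfg.n_test < cfg.n_simulations:
        raise ValueError("need 0 < n_test < n_simulations")
    if cfg.snr <= 0:
        raise ValueError("snr must be positive")
    return cfg
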