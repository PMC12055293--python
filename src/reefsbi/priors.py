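"""Prior distributions over the five inferred parameters.

Truncated lognormals for the three optically active constituents
(phytoplankton, CDOM, minerals) and for wind speed, a uniform for depth.
The lognormal shape assigns high probability to the low concentrations
typical of reef waters while accommodating episodic sediment plumes; hard
truncation excludes unrealistically high values (7 mg m^-3 phytoplankton,
2.5 m^-1 CDOM at 440 nm, 30 g m^-3 minerals).  Parameters are assumed
uncorrelated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .spectra import PARAM_NAMES, Spectrum

__all__ = [
    "TruncatedLognormalSpec",
    "UniformSpec",
    "PriorSet",
    "default_priors",
    "sample_prior",
    "prior_density",
    "prior_predictive_check",
]


@dataclass(frozen=True)
class TruncatedLognormalSpec:
    """Lognormal on (0, upper]: mu/sigma are the log-scale location/spread."""

    mu: float
    sigma: float
    upper: float = np.inf

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.upper <= 0:
            raise ValueError("upper truncation bound must be positive")

    def _dist(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # Rejection keeps truncation exact; the rejection rate is
        # negligible at the default parameters.
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(self.mu, self.sigma, size=n - filled)
            keep = draw[draw <= self.upper]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = self._dist()
        z = d.cdf(self.upper) if np.isfinite(self.upper) else 1.0
        pdf = np.where((x > 0) & (x <= self.upper), d.pdf(np.maximum(x, 1e-300)) / z, 0.0)
        return pdf if pdf.ndim else float(pdf)

    @property
    def mean(self) -> float:
        return float(self._dist().mean())

    @property
    def std(self) -> float:
        return float(self._dist().std())


@dataclass(frozen=True)
class UniformSpec:
    """Uniform on [low, high]."""

    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("low must be < high")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        pdf = np.where(
            (x >= self.low) & (x <= self.high), 1.0 / (self.high - self.low), 0.0
        )
        return pdf if pdf.ndim else float(pdf)


@dataclass(frozen=True)
class PriorSet:
    """One marginal prior per parameter, in the canonical parameter order."""

    phytoplankton: TruncatedLognormalSpec
    cdom440: TruncatedLognormalSpec
    minerals: TruncatedLognormalSpec
    wind: TruncatedLognormalSpec
    depth: UniformSpec

    def specs(self) -> Sequence:
        return [getattr(self, name) for name in PARAM_NAMES]


def default_priors() -> PriorSet:
    """Default priors for oligotrophic reef waters.

    Medians: 0.3 mg m^-3 phytoplankton, 0.05 m^-1 CDOM, 0.5 g m^-3
    minerals (heavy right tail up to the 30 g m^-3 cap for sediment
    events), 6 m s^-1 wind; depth uniform on 0.10-20.00 m.
    """
    return PriorSet(
        phytoplankton=TruncatedLognormalSpec(mu=np.log(0.3), sigma=1.0, upper=7.0),
        cdom440=TruncatedLognormalSpec(mu=np.log(0.05), sigma=1.0, upper=2.5),
        minerals=TruncatedLognormalSpec(mu=np.log(0.5), sigma=1.2, upper=30.0),
        wind=TruncatedLognormalSpec(mu=np.log(6.0), sigma=0.5),
        depth=UniformSpec(0.10, 20.00),
    )


def sample_prior(priors: PriorSet, n: int, seed) -> np.ndarray:
    """Draw n independent parameter vectors; returns an (n, 5) array.

    Columns follow :data:`~reefsbi.spectra.PARAM_NAMES`; reproducible
    under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [spec.sample(n, rng) for spec in priors.specs()]
    return np.column_stack(cols)


def prior_density(priors: PriorSet, theta) -> float:
    """Joint prior density at theta (product of independent marginals).

    Exactly zero outside any truncation or range bound; truncated
    lognormals are renormalized over their support.
    """
    arr = np.asarray(
        theta.to_array() if hasattr(theta, "to_array") else theta, dtype=float
    )
    dens = 1.0
    for spec, x in zip(priors.specs(), arr):
        dens *= float(spec.density(x))
    return dens


def prior_predictive_check(
    priors: PriorSet,
    simulator,
    observations: Sequence[Spectrum],
    n: int = 1000,
    seed=0,
    noise=None,
) -> dict:
    """Check observed spectra against the prior-predictive envelope.

    Simulates ``n`` spectra from prior draws (optionally with observation
    noise) and flags, per observation and wavelength, whether the observed
    value lies within the simulated [min, max] envelope.  Overall pass
    requires every flag true.
    """
    thetas = sample_prior(priors, n, seed)
    if hasattr(simulator, "simulate_batch"):
        sims = simulator.simulate_batch(thetas)
    else:
        sims = np.stack([simulator(t).values for t in thetas])
    if noise is not None:
        from .dataset import add_noise_batch

        sims = add_noise_batch(sims, noise, np.random.default_rng(seed).integers(2**31))
    env_lo = sims.min(axis=0)
    env_hi = sims.max(axis=0)

    per_obs = []
    for obs in observations:
        if obs.grid != simulator.grid:
            raise ValueError("observation grid does not match the simulator grid")
        inside = (obs.values >= env_lo) & (obs.values <= env_hi)
        per_obs.append(
            {
                "inside": inside.tolist(),
                "all_inside": bool(inside.all()),
                "n_outside": int((~inside).sum()),
            }
        )
    return {
        "n_simulations": n,
        "envelope_min": env_lo.tolist(),
        "envelope_max": env_hi.tolist(),
        "observations": per_obs,
        "pass": all(o["all_inside"] for o in per_obs),
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
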