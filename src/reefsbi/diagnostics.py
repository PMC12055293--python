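"""Calibration and validation diagnostics for a trained posterior estimator.

Three checks mirror standard simulation-based-inference practice:

* **Posterior predictive check (PPC)** — given a ground-truth spectrum,
  forward-simulate from posterior draws (with observation noise) and ask
  whether the spectrum lies within the 5th-95th percentile envelope at
  every wavelength.
* **Simulation-based calibration (SBC)** — over a test set, rank each true
  parameter among L posterior samples; calibrated posteriors give
  uniformly distributed ranks, visualized as rank ECDFs against a 95%
  band for the uniform distribution.
* **Coverage probability** — the fraction of test records whose true
  parameter falls inside the marginal posterior percentile interval; a
  (5, 95) interval should cover about 90% of cases when calibrated.

Credible-interval width (at (2.5, 97.5) by default) quantifies how
confidently each parameter is retrieved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import NoiseModel, SimulatedDataset, add_noise_batch
from .npe import PosteriorEstimator, marginal_interval, sample_posterior
from .spectra import PARAM_NAMES, Spectrum

__all__ = [
    "SBCResult",
    "posterior_predictive_check",
    "sbc",
    "coverage",
    "ci_width",
    "diagnostics_report",
]


@dataclass
class SBCResult:
    """Per-parameter SBC ranks and their ECDF band checks.

    ``ranks`` is (n_test, P) with entries in {0, ..., L}; ``L`` the number
    of posterior samples per record.
    """

    ranks: np.ndarray
    L: int
    param_names: tuple = PARAM_NAMES

    def ecdf(self, j: int):
        """ECDF of parameter j's normalized ranks: (grid, ecdf values)."""
        u = np.sort((self.ranks[:, j] + 0.5) / (self.L + 1))
        return u, np.arange(1, u.size + 1) / u.size

    def band_check(self, level: float = 0.95) -> dict:
        """Pointwise binomial band check of each rank ECDF (for plots).

        At each normalized rank value t the ECDF of n uniform draws is
        Binomial(n, t)/n; the band is its equal-tailed ``level`` interval.
        Returns per-parameter fraction of evaluation points inside.  Note
        the ECDF is strongly autocorrelated, so this fraction fluctuates
        widely even for perfectly uniform ranks; it mirrors the visual
        band inspection, while :meth:`passes` applies a proper
        simultaneous criterion.
        """
        n = self.ranks.shape[0]
        alpha = 1.0 - level
        out = {}
        for j, name in enumerate(self.param_names[: self.ranks.shape[1]]):
            t, e = self.ecdf(j)
            lo = stats.binom.ppf(alpha / 2, n, t) / n
            hi = stats.binom.ppf(1 - alpha / 2, n, t) / n
            inside = (e >= lo) & (e <= hi)
            out[name] = float(inside.mean())
        return out

    def max_deviation(self) -> dict:
        """Per-parameter sup-distance between the rank ECDF and uniform."""
        out = {}
        for j, name in enumerate(self.param_names[: self.ranks.shape[1]]):
            t, e = self.ecdf(j)
            # sup over the step function: check both step edges
            n = e.size
            d = np.maximum(np.abs(e - t), np.abs(e - 1.0 / n - t))
            out[name] = float(d.max())
        return out

    def passes(self, level: float = 0.95) -> bool:
        """Simultaneous uniformity check of every rank ECDF.

        Uses the Dvoretzky-Kiefer-Wolfowitz band with a Bonferroni
        correction across the P parameters, so a perfectly calibrated
        estimator keeps *all* ECDFs within the band with probability
        >= ``level``: each ECDF must stay within
        sqrt(log(2 P / alpha) / (2 n)) of the uniform CDF.
        """
        n, P = self.ranks.shape
        alpha = 1.0 - level
        bound = np.sqrt(np.log(2.0 * P / alpha) / (2.0 * n))
        return all(v <= bound for v in self.max_deviation().values())


def posterior_predictive_check(
    estimator: PosteriorEstimator,
    simulator,
    x_gt: Spectrum,
    noise: NoiseModel | None,
    n: int = 1000,
    seed=0,
) -> dict:
    """PPC: is x_gt within the 5-95 percentile posterior-predictive envelope?"""
    if x_gt.grid != estimator.grid:
        raise ValueError("ground-truth spectrum grid does not match the estimator")
    if simulator.grid != estimator.grid:
        raise ValueError("simulator grid does not match the estimator")
    rng = np.random.default_rng(seed)
    thetas = sample_posterior(estimator, x_gt.values, n, seed=rng.integers(2**31))
    if hasattr(simulator, "simulate_batch"):
        sims = simulator.simulate_batch(thetas)
    else:
        sims = np.stack([simulator(t).values for t in thetas])
    if noise is not None:
        sims = add_noise_batch(sims, noise, rng.integers(2**31))
    lo = np.percentile(sims, 5, axis=0)
    hi = np.percentile(sims, 95, axis=0)
    inside = (x_gt.values >= lo) & (x_gt.values <= hi)
    return {
        "envelope_lo": lo,
        "envelope_hi": hi,
        "envelope_mean": sims.mean(axis=0),
        "inside": inside,
        "all_inside": bool(inside.all()),
        "n_outside": int((~inside).sum()),
    }


def sbc(estimator: PosteriorEstimator, test: SimulatedDataset, L: int, seed=0) -> SBCResult:
    """Rank each true parameter among L posterior samples per test record."""
    if L < 10:
        raise ValueError("L must be >= 10")
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    rng = np.random.default_rng(seed)
    ranks = np.empty((len(test), test.theta.shape[1]), dtype=int)
    for i in range(len(test)):
        samples = sample_posterior(
            estimator, test.X[i], L, seed=rng.integers(2**31)
        )
        ranks[i] = (samples < test.theta[i]).sum(axis=0)
    return SBCResult(ranks=ranks, L=L)


def coverage(
    estimator: PosteriorEstimator,
    test: SimulatedDataset,
    p_lo: float = 5.0,
    p_hi: float = 95.0,
    n_samples: int = 1000,
    seed=0,
) -> dict:
    """Per-parameter coverage of the (p_lo, p_hi) marginal interval."""
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    rng = np.random.default_rng(seed)
    P = test.theta.shape[1]
    hits = np.zeros(P)
    for i in range(len(test)):
        iv = marginal_interval(
            estimator, test.X[i], p_lo, p_hi, n=n_samples, seed=rng.integers(2**31)
        )
        hits += (test.theta[i] >= iv[:, 0]) & (test.theta[i] <= iv[:, 1])
    frac = hits / len(test)
    names = PARAM_NAMES[:P] if P <= len(PARAM_NAMES) else tuple(f"p{j}" for j in range(P))
    report = {name: float(f) for name, f in zip(names, frac)}
    report["minimum"] = float(frac.min())
    return report


def ci_width(
    estimator: PosteriorEstimator,
    inputs,
    p_lo: float = 2.5,
    p_hi: float = 97.5,
    n_samples: int = 1000,
    seed=0,
) -> dict:
    """Mean credible-interval width per parameter across inputs.

    ``inputs`` may be a SimulatedDataset or an array of spectra (rows).
    """
    X = inputs.X if isinstance(inputs, SimulatedDataset) else np.atleast_2d(inputs)
    rng = np.random.default_rng(seed)
    widths = np.zeros(estimator.t_mean.size)
    for i in range(X.shape[0]):
        iv = marginal_interval(
            estimator, X[i], p_lo, p_hi, n=n_samples, seed=rng.integers(2**31)
        )
        widths += iv[:, 1] - iv[:, 0]
    widths /= X.shape[0]
    names = (
        PARAM_NAMES[: widths.size]
        if widths.size <= len(PARAM_NAMES)
        else tuple(f"p{j}" for j in range(widths.size))
    )
    return {name: float(w) for name, w in zip(names, widths)}


def diagnostics_report(
    estimator: PosteriorEstimator,
    simulator,
    test: SimulatedDataset,
    noise: NoiseModel | None,
    L: int = 100,
    n_samples: int = 1000,
    seed=0,
) -> dict:
    """Full validation: PPC on one test record, SBC ranks, coverage, widths."""
    rng = np.random.default_rng(seed)
    ppc = posterior_predictive_check(
        estimator, simulator, test.spectrum(0), noise, n=n_samples,
        seed=rng.integers(2**31),
    )
    sbc_res = sbc(estimator, test, L, seed=rng.integers(2**31))
    cov = coverage(estimator, test, n_samples=n_samples, seed=rng.integers(2**31))
    widths = ci_width(estimator, test, n_samples=n_samples, seed=rng.integers(2**31))
    return {
        "ppc": {"all_inside": ppc["all_inside"], "n_outside": ppc["n_outside"]},
        "sbc": {
            "band_fractions": sbc_res.band_check(),
            "max_ecdf_deviation": sbc_res.max_deviation(),
            "pass": sbc_res.passes(),
            "L": L,
        },
        "coverage": cov,
        "ci_width": widths,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=2)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
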