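"""Diagnostic figures: SBC rank ECDFs, PPC envelopes, CI-width bars.

Thin matplotlib wrappers over the diagnostics results; each function
returns the figure so callers can save or embed it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .diagnostics import SBCResult
from .spectra import Spectrum

__all__ = ["plot_sbc_ecdf", "plot_ppc_envelope", "plot_ci_widths"]


def plot_sbc_ecdf(result: SBCResult, level: float = 0.95):
    """Rank ECDFs per parameter with the pointwise binomial uniform band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    n = result.ranks.shape[0]
    t = np.linspace(1e-4, 1 - 1e-4, 200)
    alpha = 1.0 - level
    lo = stats.binom.ppf(alpha / 2, n, t) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, t) / n
    ax.fill_between(t, lo, hi, color="0.85", label=f"{level:.0%} uniform band")
    for j, name in enumerate(result.param_names[: result.ranks.shape[1]]):
        u, e = result.ecdf(j)
        ax.step(u, e, where="post", label=name, lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("normalized rank")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_ppc_envelope(report: dict, x_gt: Spectrum):
    """Ground-truth spectrum against the 5-95 posterior-predictive band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    lam = x_gt.grid.values
    ax.fill_between(lam, report["envelope_lo"], report["envelope_hi"],
                    color="lightgreen", label="posterior predictive 5-95%")
    ax.plot(lam, report["envelope_mean"], color="darkgreen", lw=1,
            label="predictive mean")
    ax.plot(lam, x_gt.values, color="navy", lw=1.2, label="ground truth")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(r"$R_{rs}$ (sr$^{-1}$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_ci_widths(widths: dict, prior_widths: dict | None = None):
    """Bar chart of mean credible-interval widths per parameter."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = list(widths)
    vals = [widths[n] for n in names]
    if prior_widths:
        vals = [widths[n] / prior_widths[n] for n in names]
        ax.set_ylabel("posterior / prior interval width")
    else:
        ax.set_ylabel("interval width (natural units)")
    ax.bar(names, vals, color="steelblue")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    return fig
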