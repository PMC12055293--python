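"""Validate a trained estimator: coverage, SBC ranks and a PPC envelope.

Uses a compact pipeline for speed, prints the diagnostics the full study
reports, and saves the three diagnostic figures under scratch/.
"""

from pathlib import Path

import reefsbi as rb
from reefsbi.plots import plot_ci_widths, plot_ppc_envelope, plot_sbc_ecdf

result = rb.run_pipeline(
    n_simulations=5000,
    n_test=250,
    snr=100.0,
    seed=5,
    mdn_config=rb.MDNConfig(max_epochs=100),
)

cov = rb.coverage(result.estimator, result.test, n_samples=600, seed=6)
print("coverage of the 5-95% posterior interval per parameter "
      "(0.90 is perfectly calibrated):")
for name in rb.PARAM_NAMES:
    print(f"  {name:<14}{cov[name]:.3f}")
print(f"  minimum        {cov['minimum']:.3f}")

sbc = rb.sbc(result.estimator, result.test, L=100, seed=7)
print(f"\nSBC rank uniformity (DKW simultaneous band): pass={sbc.passes()}")
print("  max ECDF deviation per parameter:",
      {k: round(v, 3) for k, v in sbc.max_deviation().items()})

ppc = rb.posterior_predictive_check(
    result.estimator, result.simulator, result.test.spectrum(0),
    result.noise, n=500, seed=8,
)
print(f"\nPPC: ground truth outside the 5-95 envelope at "
      f"{ppc['n_outside']} of {len(result.test.grid)} bands "
      "(a handful is expected: a sharp posterior leaves the envelope "
      "close to the noise quantiles)")

out = Path("scratch")
out.mkdir(exist_ok=True)
plot_sbc_ecdf(sbc).savefig(out / "sbc_ecdf.png", dpi=120)
plot_ppc_envelope(ppc, result.test.spectrum(0)).savefig(out / "ppc.png", dpi=120)
w = rb.ci_width(result.estimator, result.test.X[:50], n_samples=500, seed=9)
plot_ci_widths(w).savefig(out / "ci_widths.png", dpi=120)
print(f"figures saved to {out}/")
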