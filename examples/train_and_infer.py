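"""Train a compact posterior estimator and invert one reflectance spectrum.

Runs a reduced pipeline (4,000 simulations, shortened training) so it
finishes in about half a minute, then prints the posterior mean and 5-95%
credible interval for each parameter next to the true value that
generated the spectrum.  The full-scale study uses 30,000 simulations and
default training settings; expect tighter, better-calibrated posteriors
there.
"""

import numpy as np

import reefsbi as rb

result = rb.run_pipeline(
    n_simulations=4000,
    n_test=200,
    snr=100.0,
    seed=3,
    mdn_config=rb.MDNConfig(max_epochs=100),
)
log = result.estimator.training_log
print(f"trained 3x90 MDN with 6 components: {log['epochs_run']} epochs, "
      f"best validation loss {log['best_val_loss']:.3f}")

x_obs = result.test.X[0]
truth = result.test.theta[0]
samples = rb.sample_posterior(result.estimator, x_obs, 4000, seed=4)
iv = rb.marginal_interval(result.estimator, x_obs, 5, 95, n=4000, seed=4)

units = ["mg m^-3", "m^-1", "g m^-3", "m s^-1", "m"]
print(f"\n{'parameter':<14}{'true':>8}{'post.mean':>11}{'5-95% interval':>22}")
for j, (name, unit) in enumerate(zip(rb.PARAM_NAMES, units)):
    print(f"{name:<14}{truth[j]:8.3f}{samples[:, j].mean():11.3f}"
          f"   [{iv[j, 0]:7.3f}, {iv[j, 1]:7.3f}] {unit}")

inside = ((truth >= iv[:, 0]) & (truth <= iv[:, 1])).sum()
print(f"\n{inside} of 5 true values fall inside their 5-95% marginal interval; "
      "wind is typically the least identifiable (interval nearly as wide as "
      "its prior), phytoplankton and minerals the most informative.")
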