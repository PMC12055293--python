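# Methods

This note documents the models implemented in `reefsbi`, the choices made
where the design was genuinely open, and what the simulation-based tests
do and do not establish about real data.

## Forward model

The simulator maps θ = (phytoplankton, cdom440, minerals, wind, depth) to
above-surface remote-sensing reflectance on a wavelength grid (canonical:
400–700 nm at 5 nm, 61 bands; extended to 705 nm when a multispectral
sensor is configured).

**Inherent optical properties.**  Total absorption and backscatter are
sums of constituent terms, each linear in its concentration:

    a(λ)  = a_w(λ) + a*_ph(λ)·chl + cdom440·e^(−S_g (λ−440)) + minerals·a*_m(440)·e^(−S_m (λ−440))
    b_b(λ) = bb_w(λ) + 0.01·(0.30·chl^0.62)·(550/λ) + minerals·0.012·(550/λ)^0.8

Defaults: `a*_ph` is a bundled normalized shape (Gaussian mixture peaking
at 440 and 675 nm with a blue-green shoulder) scaled by
a*_ph(440) = 0.05 m² mg⁻¹; S_g = 0.015 nm⁻¹; a*_m(440) = 0.03 m² g⁻¹,
S_m = 0.011 nm⁻¹.  Pure-water absorption comes from a bundled
literature table (400–710 nm at 10 nm, spline-interpolated); pure-water
backscatter from bb_w = ½·0.0049·(450/λ)^4.32.  CDOM is dissolved and
contributes no backscatter.  All coefficients live in `BioOpticsConfig`
and can be overridden; they are literature-standard stand-ins, not a
reconstruction of any particular radiative-transfer configuration.

**Shallow-water solution.**  With u = b_b/(a+b_b) and κ = a+b_b, the
two-term semi-analytical form blends an optically deep term with the
benthic reflection:

    rrs = (0.084 + 0.170u)u · (1 − e^(−D_C κ H)) + (ρ_b/π) · e^(−D_B κ H)
    D_C = 1/cosθ_w + 1.03(1+2.4u)^0.5,   D_B = 1/cosθ_w + 1.04(1+5.4u)^0.5

Geometry is a fixed 30° solar zenith in air refracted with index 1.34
(nadir viewing); configurable.  Above-surface conversion is
Rrs = 0.5·rrs/(1−1.5·rrs).  Wind enters as a spectrally flat additive
surface term k_glint·W with k_glint = 2×10⁻⁵ sr⁻¹ per m s⁻¹ — large
enough that wind perturbs the observable, small enough that wind remains
weakly identified (its posterior stays close to the prior), which is the
qualitatively expected behaviour.  The default benthic spectrum is a
synthetic brown-coral-like curve (dark blue, 675 nm pigment dip, red-edge
rise); any spectrum on the grid, e.g. from a 2-column CSV, replaces it.

The exact limits H→0 (rrs → ρ_b/π) and H→∞ (bottom term vanishes) hold
to 1e-10 and are tested; the simulator is deterministic and bit-stable.

## Priors

Truncated lognormals for the three constituents — caps at 7 mg m⁻³
(phytoplankton), 2.5 m⁻¹ (CDOM at 440 nm), 30 g m⁻³ (minerals) — a
lognormal for wind and a uniform depth on [0.10, 20.00] m, all
independent.  The (μ, σ) pairs are medians 0.3 / 0.05 / 0.5 / 6 with
log-scale spreads 1.0 / 1.0 / 1.2 / 0.5: low typical concentrations with
a heavy right tail for episodic sediment events, and a mid-single-digit
wind climatology.  Truncation is enforced by rejection (exact; the
rejection rate is < 1e-3 at the defaults).  All values are configuration
entries and should be re-fit when local knowledge is available.

## Noise and sensors

Observation noise is additive, zero-mean, Gaussian, with one variance per
spectrum: σ² = (Σ_λ signal_λ² / N) / SNR, where N is that spectrum's band
count.  The same σ applies to every band, draws are independent across
bands, and noisy values are not clipped at zero.  Presets SNR ∈
{50, 100, 500}.  Multispectral reduction picks the nearest grid
wavelength per band center (ties toward the lower wavelength); a
spectral-response convolution is deliberately out of scope.

## Posterior estimator

A mixture density network: tanh MLP (3 hidden layers × 90 units) mapping
the spectrum to the parameters of a 6-component multivariate Gaussian
mixture over θ — softmax weights, means, and full covariance per
component via a lower-triangular Cholesky factor of the precision matrix
(log-parametrized diagonal).  Full covariances matter: the posteriors
show strong pairwise correlations that diagonal mixtures cannot express.

**Reparametrization.**  The network models transformed parameters: log
for the four lognormal-prior parameters, logit (scaled to [0.10, 20] m)
for depth, each standardized by training statistics; spectra are
standardized per band.  In natural units the near-zero, bounded
posteriors are strongly skewed and a Gaussian mixture fits them poorly —
in transformed space they are near-Gaussian.  Log-densities include the
exact change-of-variables Jacobians; samples are mapped back through the
monotone inverse, under which percentile intervals are equivariant, so
coverage statements are unaffected by the parametrization itself.

**Training.**  Mean negative log-density, Adam (lr 5e-4, batch 200),
early stopping with patience 20 on a 10% validation split, followed by up
to three learning-rate annealing steps (×0.3, restarting from the best
weights); decoupled weight decay 1e-4.  Gradients are derived
analytically and verified against finite differences in the tests.

**Noise re-sampling.**  Training draws a fresh Gaussian noise realization
for every minibatch rather than fitting one fixed noisy dataset.  The
noise law is known exactly, so this is equivalent to unlimited draws from
p(x|θ) at zero simulator cost; it removed a large train/validation gap
and the posterior overconfidence that came with it.  Validation inputs
get a single fixed realization so early stopping is stable.  The number
of simulator evaluations — the expensive resource — is unchanged.

**Support truncation.**  Posterior samples outside the prior support are
rejected (implied renormalization); `log_prob` returns −∞ outside support
without renormalizing the interior mass — a documented approximation,
adequate because the estimator places little mass outside.

## Diagnostics

* **Coverage** — fraction of held-out records whose true parameter falls
  in the marginal (5, 95) percentile interval (nominally 0.90);
  credible-interval widths are reported at (2.5, 97.5).  The two
  percentile conventions are deliberate and configurable.
* **SBC** — rank of each true parameter among L posterior samples per
  test record.  Figures show the rank ECDFs with the pointwise 95%
  binomial band; the pass/fail decision uses a
  Dvoretzky–Kiefer–Wolfowitz simultaneous band, Bonferroni-corrected
  across the five parameters, because the pointwise band rejects a
  perfectly calibrated estimator far too often when five autocorrelated
  ECDFs are inspected at once.
* **PPC** — forward-simulate (with observation noise) from posterior
  draws given a ground-truth spectrum and check it against the
  per-wavelength 5–95 envelope.  With a sharp posterior the envelope
  approaches the noise quantiles themselves, so each band has only
  ~90–94% containment probability and a handful of the 61 bands is
  expected to fall outside even for a perfectly calibrated estimator;
  all-band containment is only informative when parameter uncertainty
  dominates the predictive spread.

## Problem sizes

The desk-scale study used throughout the acceptance checks is 20,000
training / 500 test simulations at SNR 100 on the hyperspectral grid
(training ≈ 2 minutes on one CPU); the full-scale design is 30,000
simulations split 29,000/1,000.  Unit and property tests use smaller
pipelines (4,000–6,000 simulations, shortened epochs) that exercise the
identical code paths.

## What the synthetic data do and do not show

The generator emulates: smooth reef reflectance spectra driven by five
physical parameters, realistic parameter ranges, SNR-scaled sensor noise
and band reduction.  It does not emulate: benthic heterogeneity (a single
albedo is assumed), spectrally correlated or wavelength-dependent noise,
atmospheric or sun-glint structure, bio-optical model error, or
correlations between constituents.  Passing calibration on these data
therefore demonstrates that the inference machinery is self-consistent —
not that posteriors on field spectra are correct when the forward model
is misspecified, which is the dominant error source in practice (the
sensitivity to benthic variation is the clearest example).

## Numerical choices and degenerate inputs

Log-diagonal entries of the precision factors are clipped at ±7 to avoid
overflow; mixture weights use stable log-softmax/log-sum-exp throughout.
Standardization guards zero-variance features.  Grids must be strictly
increasing; a degenerate single-band grid is allowed.  Zero turbidity
yields the degenerate SPM range (0, 0).  Depth 0 and effectively infinite
depth are valid simulator inputs (outside the prior but useful as physical
limit checks).  Spline resampling refuses extrapolation; radiometry with
a zero mean Ed at any needed wavelength is rejected rather than patched.

## Known limitations

* The bio-optical coefficients are literature stand-ins; absolute
  posterior widths and the relative identifiability ordering across
  constituents depend on them.  Under these defaults mineral
  concentration is the best-constrained constituent relative to its
  prior; systems with different sediment optics will differ.
* The MDN log-density is un-normalized over the truncated support.
* Single benthic cover; no spectral mixing.
* CPU-only; training cost scales linearly with campaign size.
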