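# Example run configuration for the reefsbi CLI.
# Every key is optional; omitted keys use the package defaults shown here.

# simulation grid (nm); extended automatically to cover the sensor's
# red-edge band when a multispectral sensor is selected
grid_start: 400
grid_stop: 700
grid_step: 5

# campaign size and held-out test split
n_simulations: 30000
n_test: 1000

# signal-to-noise ratio of the additive Gaussian observation noise
snr: 100

# null for hyperspectral; "micasense" for the 7-band drone sensor
sensor: null

# single master seed; each pipeline stage derives its own child seed
master_seed: 0

# per-parameter priors: truncated lognormals (mu/sigma on the log scale,
# upper cap in natural units) and a uniform depth range in metres
priors:
  phytoplankton: {mu: -1.2039728043259361, sigma: 1.0, upper: 7.0}
  cdom440: {mu: -2.995732273553991, sigma: 1.0, upper: 2.5}
  minerals: {mu: -0.6931471805599453, sigma: 1.2, upper: 30.0}
  wind: {mu: 1.791759469228055, sigma: 0.5}
  depth: {low: 0.10, high: 20.00}

# bio-optical coefficients of the forward simulator (see docs/methods.md)
bio_optics:
  aph440: 0.05        # chlorophyll-specific absorption at 440 nm, m^2 mg^-1
  s_cdom: 0.015       # CDOM spectral slope, nm^-1
  am440: 0.03         # mineral-specific absorption at 440 nm, m^2 g^-1
  s_mineral: 0.011    # mineral absorption slope, nm^-1
  k_glint: 2.0e-5     # flat wind surface term, sr^-1 per m s^-1
  sun_zenith_deg: 30.0

# mixture-density-network architecture and optimization
mdn:
  hidden_layers: 3
  units_per_layer: 90
  n_components: 6
  max_epochs: 400
  batch_size: 200
  learning_rate: 5.0e-4
  weight_decay: 1.0e-4
  early_stop_patience: 20
  validation_fraction: 0.1
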