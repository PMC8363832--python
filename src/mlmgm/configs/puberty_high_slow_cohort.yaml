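schema_version: 1
scenario_name: puberty
design:
  kind: PubertyDesign
  sampling: slow
  frame: cohort
  n_subjects: 188
  n_waves: 4
  accel_spread: 1.0
  jitter_sd: 0.1
fixed:
  gamma00: 0.0
  terms:
    age_c: 0.0
    puberty_c: 2.0
    age_c_x_puberty_c: -0.5
random:
  intercept_sd: 0.5
  slope_sd: 0.0
  residual_sd: 0.5
mcar_rate: 0.0
n_replicants: 1000
master_seed: 0
puberty_dist:
  location_sd: 1.5
  truncation: 3.0
  shape_gamma_shape: 10.0
  shape_gamma_rate: 3.0
  zk_correlation: 0.5
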