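schema_version: 1
scenario_name: tvc_stress
design:
  kind: DesignSpec
  design_label: school_cohort
  n_subjects: 150
  n_waves: 5
  baseline_age_low: 10.0
  baseline_age_high: 11.0
  spacing: 1.0
  jitter_sd: 0.1
fixed:
  gamma00: 0.0
  terms:
    age_c: 0.3
    stress_c: 0.3
    age_c_x_stress_c: -0.1
random:
  intercept_sd: 1.0
  slope_sd: 0.15
  residual_sd: 0.5
mcar_rate: 0.0
n_replicants: 1000
master_seed: 0
tvc:
  signal_slope: 0.2197
  latent_sd: 0.5
  error_sd: 0.5
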