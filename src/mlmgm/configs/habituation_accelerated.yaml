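schema_version: 1
scenario_name: habituation
design:
  kind: DesignSpec
  design_label: accelerated
  n_subjects: 250
  n_waves: 3
  baseline_age_low: 8.0
  baseline_age_high: 14.0
  spacing: 1.0
  jitter_sd: 0.1
fixed:
  gamma00: 0.0
  terms:
    age_c: 0.3
    exposure_c: -0.3
random:
  intercept_sd: 0.5
  slope_sd: 0.0
  residual_sd: 1.0
mcar_rate: 0.0
n_replicants: 1000
master_seed: 0
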