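schema_version: 1
scenario_name: practice_only
design:
  kind: DesignSpec
  design_label: cohort
  n_subjects: 150
  n_waves: 5
  baseline_age_low: 10.0
  baseline_age_high: 10.0
  spacing: 1.0
  jitter_sd: 0.1
fixed:
  gamma00: 0.0
  terms:
    age_c: 0.0
    exposure_c: 0.3
random:
  intercept_sd: 0.5
  slope_sd: 0.0
  residual_sd: 1.0
mcar_rate: 0.0
n_replicants: 1000
master_seed: 0
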