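# mlmgm

A Monte-Carlo simulation laboratory for **multi-level multi-growth models
(MLMGMs)** — mixed-effects growth models in which two or more monotone
growth processes (age, practice/exposure, intervention, pubertal
maturation) jointly drive a longitudinal outcome:

```
y_ti = γ00 + γ10·Growth1_ti + γ20·Growth2_ti (+ products, quadratics)
       + u0i + u1i·Growth1_ti + r_ti
```

with u0 ~ N(0, τ00²), u1 ~ N(0, τ11²), r ~ N(0, σ²).

The package is for quantitative developmental scientists and
methodologists who want to study how *sampling design* — not the model —
determines whether correlated growth processes can be separated. It
generates cohort, accelerated, school-based, and puberty-centred
observation designs; simulates outcomes from configurable generating
models (including sigmoid pubertal trajectories coarsened into Tanner
stages and an error-contaminated stress covariate); fits mis-specified
(age-only) and properly specified multi-growth models by REML; and
evaluates recovery with standardized bias, growth-predictor correlations
ρ_growth, variance inflation factors, and correct-sign significance rates
across replicants.

The headline phenomena it reproduces:

- In a cohort design (everyone enters at the same age), age and
  assessment count correlate at ρ ≈ .998 (VIF ≈ 200): an omitted practice
  effect aliases completely into the age estimate (standardized bias
  ≈ 11.5), and the properly specified model, while unbiased, loses nearly
  all power (≈ 13%).
- Staggered entry (an accelerated design) attenuates the confound to
  ρ ≈ .38 (VIF 1.17), restoring unbiased, stable, fully powered
  estimation.
- The same planned-missingness logic applied to a *non-age* process
  (randomly timed school interventions, pubertal timing variability)
  lets even cohort data separate the processes.
- Measurement coarseness hurts: classical error in a stress covariate,
  or coarsening continuous puberty into Tanner stages, leaks bias into
  the age term.

## Worked example

```python
from mlmgm import get_scenario, run_replications

# pure practice effect (γ_practice = .3, γ_age = 0), cohort design
bundle = get_scenario("practice_only", design="cohort")
res = run_replications(bundle, n_replicants=200, master_seed=2026)
print(res.summary[["model_label", "term", "mean_est", "sd_est", "std_bias",
                   "prop_sig_raw"]].round(3).to_string(index=False))
```

prints (abridged):

```
       model_label       term  mean_est  sd_est  std_bias  prop_sig_raw
            design        vif   200.923   9.743       NaN           NaN
            design rho_growth     0.998   0.000       NaN           NaN
     mis_specified      age_c     0.301   0.026    11.568          1.00
     mis_specified      sigma     0.997   0.031    -0.110           NaN
     mis_specified      tau00     0.492   0.050    -0.157           NaN
properly_specified      age_c     0.008   0.384     0.022          0.04
properly_specified exposure_c     0.294   0.386    -0.017          0.13
properly_specified      sigma     0.996   0.032    -0.121           NaN
properly_specified      tau00     0.492   0.050    -0.162           NaN
```

Reading: the age-only ("mis_specified") model turns a pure practice
effect into an apparent age effect of .301 — more than 11 SDs of its own
sampling distribution away from the true 0 — while the two-growth model
is centred on the truth (age ≈ 0, practice ≈ .3) but with SDs ~15× larger
(0.39 vs 0.026) because ρ_growth = .998 inflates the VIF to ~200; the
true practice effect is detected in only ~13% of replicants. Re-running
with `design="accelerated"` shows ρ ≈ .38, VIF ≈ 1.17, and full power.

The same loop is exposed on the command line:

```
mlmgm run --scenario practice_only --design accelerated --reps 200 --seed 1 --out summary.csv
mlmgm table 5 --reps 1000 --seed 1 --out tables/   # a full puberty table
mlmgm simulate --scenario puberty --seed 7 --out one_replicant.csv
```

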