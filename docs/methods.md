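# Methods

## The model

`mlmgm` is a Monte-Carlo laboratory for *multi-level multi-growth models*
(MLMGMs): linear mixed-effects growth models in which two or more monotone
growth processes jointly drive a longitudinal outcome. The generating model
for observation *t* of subject *i* is

    y_ti = γ00 + Σ_j γ_j · x_jti  +  u0i + u1i·age_c_ti + r_ti

with subject random intercepts u0 ~ N(0, τ00²), optional random age slopes
u1 ~ N(0, τ11²) and occasion residuals r ~ N(0, σ²). The growth predictors
x may be centred age, assessment count (practice/exposure), cumulative
intervention exposure, an error-contaminated stress covariate, or
continuous/ordinal pubertal status, together with centred quadratic and
product terms.

The scientific question the laboratory addresses is one of *design*, not
estimation: when two growth processes are nearly collinear (as age and
assessment count are in a cohort design, pooled r ≈ .998), the
properly-specified model is unbiased in the aggregate but its estimates are
so unstable (VIF ≈ 200, SEs ~14× larger) that single studies are
uninformative, while the conventional age-only model silently absorbs the
omitted process. Planned missingness — staggered entry with respect to
whichever process is *not* age — attenuates the collinearity and restores
both stability and power.

## Sampling designs

All stock designs share a 750-observation budget.

| design | geometry | pooled r(age, count) |
|---|---|---|
| cohort | 150 × 5 annual waves, common entry at age 10 | ≈ .998 |
| accelerated | 250 × 3 annual waves, integer entry ages uniform on 8–14 | ≈ .379 |
| school cohort | 150 × 5 (or 187 × 4), entry uniform within a 1-year band | — |
| puberty cells | 188 × 4 waves at 1.0 y (slow) or 0.5 y (fast) spacing, mean age 12 | .35–.90 |

Observed ages are the planned ages plus independent per-occasion
N(0, 0.1²) jitter; draws that would break within-subject age monotonicity
are redrawn. Per-occasion (rather than per-interval) jitter is what keeps
the cohort age/assessment correlation inside the .997–.998 band.

The seven-year accelerated entry window is chosen so the entry-age
variance (4) against the occasion variance (2/3) puts the pooled
correlation at .379 and the VIF at 1.17; anchoring ages are otherwise
arbitrary because every predictor is grand-mean centred before fitting.

Intervention onset in the school design is uniform over the n_waves + 1
possibilities including "never during the study"; the cumulative exposure
counter is 0 before onset and then 1, 2, … . The never-treated arm is what
places r(age, tx) at ≈ .554 (5 waves) / .532 (4 waves).

## Pubertal trajectories

Each subject follows a logistic curve p(x) = 1/(1 + e^{−k(x−z)}) in age
x relative to the sample mean (12 y). Timing z ~ N(0, σ²) truncated at
±3 y with σ = 1.5 (high variability) or 0.5 (low); tempo k ~ Gamma(shape
10, rate 3), so the mean steepness is 10/3 and most 2%→98% transitions
(7.78/k years) take longer than two years. The gamma is read as
shape/rate deliberately: the shape/scale reading would give mean k = 30
and quarter-year transitions, contradicting the slow-transition intent.
Timing and tempo are coupled by a Gaussian copula with correlation +0.5
(the magnitude is a free choice; only the direction — early onset with
protracted tempo — is substantively motivated), which preserves both
marginals exactly.

Ordinal Tanner stages cut p at .05/.35/.65/.95, each interval closed on
the left (p = .95 → stage 5; the half-open-up convention resolves the
boundary the cut-point list leaves unassigned). Entered into regressions,
the stage is a numeric 1–5 predictor (centred as a main effect); its
implied generating coefficient is the continuous-puberty coefficient
divided by 4, since one stage spans a quarter of the 0–1 puberty scale.
The Tanner model's age × stage product is deliberately built from the
*raw* 1–5 stage — an ordinal score is not re-centred before forming a
product in common practice — and this uncentred product is precisely what
leaks the coarsening error into the age estimate (standardized bias ~4–8
across the four variability × sampling cells), the Tanner models' central
cautionary result. Building the product from the centred stage instead
would leave the age term essentially unbiased.

## Generating parameters

Fixed effects default to ±0.3 for linear growth effects, −0.1 for
quadratic/product terms, and (0, +2, −0.5) for the age/puberty/interaction
triple. Random components: intercept SD 0.5, residual SD 1.0 by default;
the intervention and TVC scenarios use intercept SD 1.0, age-slope SD
0.15, residual SD 0.5; the puberty scenarios use intercept SD 0.5 and
residual SD 0.5. Optional MCAR deletion removes each row independently
(default rate 0.10 where used).

## The stress TVC and its measurement error

The stress covariate is generated as signal_slope·age_c plus N(0, 0.5²)
occasion-level latent variation; the observed measure adds independent
N(0, 0.5²) error. The outcome is generated from the *error-free* signal
while models are fit to the contaminated observation. The latent SD is
fixed equal to the error SD and the signal slope (0.2197) is solved in
closed form so the pooled age/stress correlation is .41 in the 5-wave
school design; both were frozen before use.

A known limitation: under this (or any classical) error-in-covariate
mechanism, the attenuation of the stress coefficient toward
reliability × truth, and the corresponding leak of the lost age-tracking
signal into the age term, are mathematically linked. The laboratory
reproduces the qualitative and quantitative inflation of the age estimate
(standardized bias ≈ 1.9) but necessarily shows the stress and
interaction coefficients attenuated at the same time; no parameterisation
of a classical error model can inflate the age term while leaving the
covariate's own coefficient untouched.

## Estimation and inference

Models are estimated by REML via `statsmodels`' `MixedLM` with a subject
random intercept (plus a random age slope where the generating model has
one). An optimizer cascade (default, then L-BFGS, Powell, CG) guards
against occasional line-search failures under extreme collinearity;
non-convergent replicants are flagged, dropped from aggregation and
counted, with a warning if more than 2% drop. A cross-check test verifies
agreement with `lme4::lmer` (REML) to ~1e−5 on fixed effects.

p-values are two-sided Wald tests on the asymptotic normal scale. At 750
observations the difference from a Satterthwaite-df t test is below half
a percent in critical values; `fit_mlm` exposes a `pvalue_fn` hook for
callers who need a small-sample df approximation. Bonferroni adjustment
multiplies each p-value by the number of growth predictors in its model
(1–3), capped at 1.

## Recovery diagnostics

For each (model, term) the replication summary reports the mean, SD, min
and max of the estimates, the standardized bias
(mean − truth)/SD(estimates) with |bias| > .25 flagged, and the
proportion of replicants significant at α = .05 *with the correct sign*
(for a zero truth, the plain false-positive rate). Per-replicant pooled
growth-predictor correlations and the age predictor's VIF
(1/(1 − R²) from the observation-level regression on the other linear
growth terms; product terms excluded) are averaged alongside. "Std. Err."
in the summaries is the SD of the sampling distribution of estimates, not
the mean model SE. Quadratic models additionally report the implied
inflection point −γ₁/(2γ₂) per replicant.

## Seeds and problem sizes

Replicant r of a run with master seed m derives every random stream from
`default_rng([m, r, stream])`, so replicants are mutually independent,
individually reproducible, and identical whatever the execution order.
Re-running a configuration reproduces its outputs bit-for-bit.

The study-scale replicant count is 1000 (the `table` CLI verb's default).
The packaged acceptance script and test-suite ensembles use 200–500
replicants — sizes at which the Monte-Carlo SE of every tracked statistic
is comfortably below the comparison tolerances — and scale checks to
3× the Monte-Carlo SE at the reduced count.

## What the generator does and does not emulate

Synthetic data are Gaussian at every level, with exactly the generating
covariance structure the models assume; there is no attrition or
non-random missingness (only MCAR), no heteroskedasticity, no
non-Gaussian random effects, no measurement error in age or assessment
counts, and no group (e.g. sex) structure in pubertal timing. Passing
recovery checks therefore demonstrates properties of the *designs and
models*, not robustness to real-data pathologies; the diagnostics here
are a lower bound on the difficulties real cohort data would present.
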