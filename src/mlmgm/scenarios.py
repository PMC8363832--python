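"""Outcome simulation for every named multi-growth scenario.

A scenario couples a sampling design with a generating mixed-effects
model.  The outcome for observation t of subject i is

    y_ti = g00 + sum_j gamma_j * x_jti + u0i + u1i * age_c_ti + r_ti

with subject-level random intercepts u0 ~ N(0, intercept_sd^2), optional
random age slopes u1 ~ N(0, slope_sd^2), and occasion residuals
r ~ N(0, residual_sd^2).  All growth predictors are grand-mean centred
before entering the model, and quadratic/product terms are built from the
centred columns, which keeps them orthogonal to the linear terms on the
symmetric sampling grids used here.

The module also provides the time-varying-covariate (TVC) stress process
with measurement error, completely-at-random row deletion, and
:func:`build_scenario`, the deterministic (config, seed, replicant) ->
dataset map used by the replication harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import designs, puberty as pub

#: Raw predictor columns that :func:`center_predictors` knows how to centre.
CENTERABLE = ["age", "exposure_count", "tx_count", "puberty", "tanner", "stress_observed"]

#: Map raw column -> centred column name.
CENTERED_NAME = {
    "age": "age_c",
    "exposure_count": "exposure_c",
    "tx_count": "tx_c",
    "puberty": "puberty_c",
    "tanner": "tanner_c",
    "stress_observed": "stress_c",
}


@dataclass(frozen=True)
class FixedEffects:
    """Generating fixed effects: intercept plus named slopes.

    ``terms`` maps centred predictor/product column names (e.g. ``age_c``,
    ``exposure_c``, ``age_c2``, ``age_c_x_tx_c``) to coefficients.
    """

    gamma00: float = 0.0
    terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("at least one growth effect must be defined")
        for name, val in self.terms.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite coefficient for {name!r}")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """SDs of the generating random components (all in outcome units,
    except ``slope_sd`` which is per year of centred age)."""

    intercept_sd: float = 0.5
    slope_sd: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.intercept_sd, self.slope_sd, self.residual_sd) < 0:
            raise ValueError("random-effect SDs must be non-negative")


@dataclass(frozen=True)
class TVCSpec:
    """Stress time-varying covariate with measurement error.

    The latent stress signal rises linearly with centred age
    (``signal_slope`` per year) around occasion-level latent variation
    (``latent_sd``); the observed measure adds independent error with SD
    ``error_sd``.  The outcome is generated from the error-free signal
    while models are fit to the contaminated observation.  The defaults
    were calibrated once (closed form, then frozen) so that the pooled
    age/observed-stress correlation in the 5-wave school design is ~.41.
    """

    signal_slope: float = 0.2197
    latent_sd: float = 0.5
    error_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.error_sd < 0 or self.latent_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Named generating model + design, the unit the harness replicates."""

    scenario_name: str
    design: designs.DesignSpec | designs.PubertyDesign
    fixed: FixedEffects
    random: RandomEffectsSpec
    puberty_dist: pub.PubertyDistribution | None = None
    tvc: TVCSpec | None = None
    mcar_rate: float = 0.0
    n_replicants: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must lie in [0, 1)")


def center_predictors(dataset: pd.DataFrame, quadratic: bool = False,
                      products: tuple = ()) -> pd.DataFrame:
    """Grand-mean centre growth predictors and build higher-order columns.

    Every column in :data:`CENTERABLE` that is present gains a centred
    companion (see :data:`CENTERED_NAME`).  ``quadratic`` adds ``age_c2``
    = age_c**2; each pair in ``products`` (centred column names) adds a
    product column ``<a>_x_<b>`` built from the centred terms.
    """
    if len(dataset) == 0:
        raise ValueError("cannot centre an empty dataset")
    out = dataset.copy()
    for raw, cent in CENTERED_NAME.items():
        if raw in out.columns:
            col = out[raw].astype(float)
            out[cent] = col - col.mean()
    if quadratic:
        out["age_c2"] = out["age_c"] ** 2
    for a, b in products:
        out[f"{a}_x_{b}"] = out[a] * out[b]
    return out


def simulate_outcome(dataset: pd.DataFrame, fixed: FixedEffects,
                     random: RandomEffectsSpec, seed=None) -> pd.DataFrame:
    """Add the simulated outcome ``y`` to a dataset with centred predictors."""
    missing = [t for t in fixed.terms if t not in dataset.columns]
    if missing:
        raise ValueError(f"unknown predictor(s) in fixed effects: {missing}")
    rng = np.random.default_rng(seed)
    subjects = dataset["subject_id"].to_numpy()
    uniq, idx = np.unique(subjects, return_inverse=True)
    u0 = rng.normal(0.0, random.intercept_sd, uniq.size)
    u1 = rng.normal(0.0, random.slope_sd, uniq.size)
    r = rng.normal(0.0, random.residual_sd, len(dataset))
    y = np.full(len(dataset), fixed.gamma00)
    for term, coef in fixed.terms.items():
        y = y + coef * dataset[term].to_numpy()
    age_c = dataset["age_c"].to_numpy() if "age_c" in dataset.columns else 0.0
    out = dataset.copy()
    out["y"] = y + u0[idx] + u1[idx] * age_c + r
    return out


def simulate_stress_tvc(grid: pd.DataFrame, tvc: TVCSpec, seed=None) -> pd.DataFrame:
    """Attach the latent and observed stress columns to a grid.

    ``stress_true`` = signal_slope * age_c + occasion latent variation;
    ``stress_observed`` = stress_true + N(0, error_sd^2).  Outcome
    generation uses the error-free ``stress_true``; fitting uses the
    contaminated ``stress_observed``.
    """
    rng = np.random.default_rng(seed)
    out = grid.copy()
    age = out["age"].astype(float)
    age_c = age - age.mean()
    true = tvc.signal_slope * age_c + rng.normal(0.0, tvc.latent_sd, len(out))
    out["stress_true"] = true
    out["stress_observed"] = true + rng.normal(0.0, tvc.error_sd, len(out))
    return out


def inject_mcar(dataset: pd.DataFrame, rate: float, seed=None) -> pd.DataFrame:
    """Delete each row independently with probability ``rate`` (MCAR)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    keep = rng.random(len(dataset)) >= rate
    return dataset.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scenario construction


def _replicant_rng(master_seed: int, replicant_index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, replicant, purpose)."""
    return np.random.default_rng([int(master_seed), int(replicant_index), int(stream)])


def _make_grid(config: ScenarioConfig, rep: int) -> pd.DataFrame:
    design = config.design
    rng = _replicant_rng(config.master_seed, rep, 0)
    if isinstance(design, designs.PubertyDesign):
        return designs.make_puberty_grid(design, rng)
    label = design.design_label
    if label == "cohort":
        return designs.make_cohort_grid(design, rng)
    if label == "accelerated":
        return designs.make_accelerated_grid(design, rng)
    if label == "school_cohort":
        grid = designs.make_school_grid(design, rng)
        if config.scenario_name == "intervention":
            grid = designs.assign_intervention(grid, _replicant_rng(config.master_seed, rep, 1))
        return grid
    raise ValueError(f"scenario {config.scenario_name!r} cannot use design {label!r}")


def build_scenario(config: ScenarioConfig, replicant_index: int) -> tuple[pd.DataFrame, dict]:
    """Simulate one replicant dataset plus its generating-truth record.

    The result is a deterministic function of (config, master_seed,
    replicant_index); replicants use independent child streams.
    """
    name = config.scenario_name
    grid = _make_grid(config, replicant_index)

    quadratic = name in ("quadratic", "puberty")
    products: list[tuple[str, str]] = []
    if name == "intervention":
        products = [("age_c", "tx_c")]
    elif name == "tvc_stress":
        grid = simulate_stress_tvc(grid, config.tvc or TVCSpec(),
                                   _replicant_rng(config.master_seed, replicant_index, 2))
        products = [("age_c", "stress_c")]
    elif name == "puberty":
        rng = _replicant_rng(config.master_seed, replicant_index, 3)
        n = grid["subject_id"].nunique()
        z, k = pub.draw_puberty_params(n, config.puberty_dist or pub.HIGH_VARIABILITY, rng)
        idx = grid["subject_id"].to_numpy()
        x = grid["age"].to_numpy() - 12.0
        grid = grid.copy()
        grid["puberty"] = pub.puberty_value(x, z[idx], k[idx])
        grid["tanner"] = pub.tanner_stage(grid["puberty"].to_numpy())
        products = [("age_c", "puberty_c")]

    data = center_predictors(grid, quadratic=quadratic, products=tuple(products))

    if name == "puberty":
        # the Tanner-model product is built from the raw 1-5 stage (an
        # ordinal score is not re-centred in practice); this uncentred
        # product is what leaks the coarsening error into the age term
        data["age_c_x_tanner"] = data["age_c"] * data["tanner"].astype(float)

    if name == "tvc_stress":
        # generation uses the error-free signal (centred), fitting the
        # contaminated observation; build the generation-side columns here
        true_c = data["stress_true"] - data["stress_true"].mean()
        data["_gen_stress_c"] = true_c
        data["_gen_age_c_x_stress_c"] = data["age_c"] * true_c
        gen_fixed = FixedEffects(
            config.fixed.gamma00,
            {
                "age_c": config.fixed.terms["age_c"],
                "_gen_stress_c": config.fixed.terms["stress_c"],
                "_gen_age_c_x_stress_c": config.fixed.terms["age_c_x_stress_c"],
            },
        )
        data = simulate_outcome(data, gen_fixed, config.random,
                                _replicant_rng(config.master_seed, replicant_index, 4))
        data = data.drop(columns=["_gen_stress_c", "_gen_age_c_x_stress_c"])
    else:
        data = simulate_outcome(data, config.fixed, config.random,
                                _replicant_rng(config.master_seed, replicant_index, 4))

    if config.mcar_rate > 0:
        data = inject_mcar(data, config.mcar_rate,
                           _replicant_rng(config.master_seed, replicant_index, 5))

    truth = dict(config.fixed.terms)
    truth["intercept"] = config.fixed.gamma00
    if name == "puberty":
        # implied truths for the coarsened Tanner predictor: one Tanner
        # stage spans a quarter of the 0-1 puberty scale
        truth["tanner_c"] = config.fixed.terms["puberty_c"] / 4.0
        truth["age_c_x_tanner"] = config.fixed.terms["age_c_x_puberty_c"] / 4.0
    truth["sigma"] = config.random.residual_sd
    truth["tau00"] = config.random.intercept_sd
    if config.random.slope_sd > 0:
        truth["tau11"] = config.random.slope_sd
    return data, truth
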