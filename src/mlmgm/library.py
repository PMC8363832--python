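"""Registry of named scenario cells and their fitted models.

Each entry couples a :class:`~mlmgm.scenarios.ScenarioConfig` (design +
generating model) with the mixed models fitted to it and the predictor
pair whose pooled correlation / VIF the study tracks.  The registry
covers every cell of the simulation study:

========================  ==========================================
scenario                  generating fixed effects
========================  ==========================================
practice_only             age 0,    assessment +0.3
age_only                  age +0.3, assessment 0
additive                  age +0.3, assessment +0.3
quadratic                 age +0.3, age^2 -0.1, assessment +0.3
habituation               age +0.3, exposure -0.3
snr_inverse               age -0.3, exposure +0.3
intervention              age +0.3, treatment +0.3, age x tx -0.1
tvc_stress                age +0.3, stress +0.3, age x stress -0.1
puberty                   age 0,    puberty +2.0, age x puberty -0.5
========================  ==========================================

Configs round-trip through plain dictionaries / YAML for the CLI.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from . import designs, puberty as pub
from .designs import DesignSpec, PubertyDesign
from .fitting import ModelSpec, age_only
from .scenarios import FixedEffects, RandomEffectsSpec, ScenarioConfig, TVCSpec

CONFIG_SCHEMA_VERSION = 1

#: default generating random effects (SDs)
_RE_DEFAULT = RandomEffectsSpec(intercept_sd=0.5, slope_sd=0.0, residual_sd=1.0)
_RE_SLOPED = RandomEffectsSpec(intercept_sd=1.0, slope_sd=0.15, residual_sd=0.5)
_RE_PUBERTY = RandomEffectsSpec(intercept_sd=0.5, slope_sd=0.0, residual_sd=0.5)

_RETEST_EFFECTS = {
    "practice_only": {"age_c": 0.0, "exposure_c": 0.3},
    "age_only": {"age_c": 0.3, "exposure_c": 0.0},
    "additive": {"age_c": 0.3, "exposure_c": 0.3},
    "habituation": {"age_c": 0.3, "exposure_c": -0.3},
    "snr_inverse": {"age_c": -0.3, "exposure_c": 0.3},
}


class ScenarioBundle:
    """A config plus everything the harness needs to evaluate it."""

    def __init__(self, config: ScenarioConfig, models: dict, rho_pair: tuple,
                 vif_regressors: tuple | None = None):
        self.config = config
        self.models = models  # {label: ModelSpec}
        self.rho_pair = rho_pair  # raw predictor columns for rho_growth
        # VIF of age on the other growth predictor(s), linear terms only
        self.vif_regressors = vif_regressors or (rho_pair[1],)

    def with_(self, **config_updates) -> "ScenarioBundle":
        return ScenarioBundle(replace(self.config, **config_updates), self.models,
                              self.rho_pair, self.vif_regressors)

    def subset(self, *labels: str) -> "ScenarioBundle":
        """Keep only the named fitted models (e.g. just the mis-specified one)."""
        return ScenarioBundle(self.config, {k: self.models[k] for k in labels},
                              self.rho_pair, self.vif_regressors)


def _design_for(name: str) -> DesignSpec:
    return {"cohort": designs.COHORT_DEFAULT, "accelerated": designs.ACCELERATED_DEFAULT}[name]


def get_scenario(name: str, design: str = "cohort", *, waves: int | None = None,
                 variability: str = "high", sampling: str = "fast",
                 mcar_rate: float = 0.0, n_replicants: int = 1000,
                 master_seed: int = 0) -> ScenarioBundle:
    """Build the bundle for one scenario cell.

    ``design`` is ``cohort`` or ``accelerated`` (for the retest/quadratic
    scenarios and the puberty frame).  ``waves`` selects the 5- or 4-wave
    school design for ``intervention``.  ``variability``/``sampling``
    select the puberty cell.
    """
    common = dict(mcar_rate=mcar_rate, n_replicants=n_replicants, master_seed=master_seed)

    if name in _RETEST_EFFECTS:
        cfg = ScenarioConfig(name, _design_for(design),
                             FixedEffects(0.0, dict(_RETEST_EFFECTS[name])), _RE_DEFAULT,
                             **common)
        models = {"mis_specified": age_only(),
                  "properly_specified": ModelSpec(("age_c", "exposure_c"))}
        return ScenarioBundle(cfg, models, ("age", "exposure_count"))

    if name == "quadratic":
        fixed = FixedEffects(0.0, {"age_c": 0.3, "age_c2": -0.1, "exposure_c": 0.3})
        cfg = ScenarioConfig(name, _design_for(design), fixed, _RE_DEFAULT, **common)
        models = {"mis_specified": age_only(quadratic=True),
                  "properly_specified": ModelSpec(("age_c", "age_c2", "exposure_c"))}
        return ScenarioBundle(cfg, models, ("age", "exposure_count"))

    if name == "intervention":
        waves = waves or 5
        if waves == 5:
            dspec = designs.SCHOOL_DEFAULT
        elif waves == 4:
            dspec = replace(designs.SCHOOL_DEFAULT, n_subjects=187, n_waves=4)
        else:
            raise ValueError("intervention design supports 4 or 5 waves")
        fixed = FixedEffects(0.0, {"age_c": 0.3, "tx_c": 0.3, "age_c_x_tx_c": -0.1})
        cfg = ScenarioConfig(name, dspec, fixed, _RE_SLOPED, **common)
        models = {"properly_specified": ModelSpec(("age_c", "tx_c", "age_c_x_tx_c"),
                                                  ("intercept", "age_c"))}
        return ScenarioBundle(cfg, models, ("age", "tx_count"))

    if name == "tvc_stress":
        fixed = FixedEffects(0.0, {"age_c": 0.3, "stress_c": 0.3, "age_c_x_stress_c": -0.1})
        cfg = ScenarioConfig(name, designs.SCHOOL_DEFAULT, fixed, _RE_SLOPED,
                             tvc=TVCSpec(), **common)
        models = {"properly_specified": ModelSpec(("age_c", "stress_c", "age_c_x_stress_c"),
                                                  ("intercept", "age_c"))}
        return ScenarioBundle(cfg, models, ("age", "stress_observed"))

    if name == "puberty":
        dist = {"high": pub.HIGH_VARIABILITY, "low": pub.LOW_VARIABILITY}[variability]
        pdesign = PubertyDesign(sampling=sampling,
                                frame="cohort" if design == "cohort" else "accelerated")
        fixed = FixedEffects(0.0, {"age_c": 0.0, "puberty_c": 2.0, "age_c_x_puberty_c": -0.5})
        cfg = ScenarioConfig(name, pdesign, fixed, _RE_PUBERTY, puberty_dist=dist, **common)
        models = {
            "mis_specified": age_only(quadratic=True),
            "puberty_model": ModelSpec(("age_c", "puberty_c", "age_c_x_puberty_c"),
                                       label="puberty_model"),
            "tanner_model": ModelSpec(("age_c", "tanner_c", "age_c_x_tanner"),
                                      label="tanner_model"),
        }
        return ScenarioBundle(cfg, models, ("age", "puberty"))

    raise KeyError(f"unknown scenario {name!r}")


SCENARIO_NAMES = (*_RETEST_EFFECTS, "quadratic", "intervention", "tvc_stress", "puberty")

#: Map study table number -> list of (scenario kwargs) cells it aggregates.
TABLE_CELLS = {
    1: [dict(name="practice_only", design=d) for d in ("cohort", "accelerated")]
       + [dict(name="age_only", design=d) for d in ("cohort", "accelerated")],
    2: [dict(name="additive", design=d) for d in ("cohort", "accelerated")]
       + [dict(name="quadratic", design=d) for d in ("cohort", "accelerated")],
    3: [dict(name="habituation", design=d) for d in ("cohort", "accelerated")]
       + [dict(name="snr_inverse", design=d) for d in ("cohort", "accelerated")],
    4: [dict(name="intervention", waves=5), dict(name="intervention", waves=4),
        dict(name="tvc_stress")],
    5: [dict(name="puberty", variability="high", sampling="fast", design=d)
        for d in ("cohort", "accelerated")],
    6: [dict(name="puberty", variability="low", sampling="fast", design=d)
        for d in ("cohort", "accelerated")],
    7: [dict(name="puberty", variability="high", sampling="slow", design=d)
        for d in ("cohort", "accelerated")],
    8: [dict(name="puberty", variability="low", sampling="slow", design=d)
        for d in ("cohort", "accelerated")],
}


# ---------------------------------------------------------------------------
# Config (de)serialization


def config_to_dict(config: ScenarioConfig) -> dict:
    d = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "scenario_name": config.scenario_name,
        "design": {"kind": type(config.design).__name__, **asdict(config.design)},
        "fixed": {"gamma00": config.fixed.gamma00, "terms": dict(config.fixed.terms)},
        "random": asdict(config.random),
        "mcar_rate": config.mcar_rate,
        "n_replicants": config.n_replicants,
        "master_seed": config.master_seed,
    }
    if config.puberty_dist is not None:
        d["puberty_dist"] = asdict(config.puberty_dist)
    if config.tvc is not None:
        d["tvc"] = asdict(config.tvc)
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    if d.get("schema_version", 1) != CONFIG_SCHEMA_VERSION:
        raise ValueError("unsupported config schema version")
    dd = dict(d["design"])
    kind = dd.pop("kind", "DesignSpec")
    design = {"DesignSpec": DesignSpec, "PubertyDesign": PubertyDesign}[kind](**dd)
    return ScenarioConfig(
        scenario_name=d["scenario_name"],
        design=design,
        fixed=FixedEffects(d["fixed"]["gamma00"], dict(d["fixed"]["terms"])),
        random=RandomEffectsSpec(**d["random"]),
        puberty_dist=pub.PubertyDistribution(**d["puberty_dist"]) if "puberty_dist" in d else None,
        tvc=TVCSpec(**d["tvc"]) if "tvc" in d else None,
        mcar_rate=d.get("mcar_rate", 0.0),
        n_replicants=d.get("n_replicants", 1000),
        master_seed=d.get("master_seed", 0),
    )


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> ScenarioConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def bundle_for_config(config: ScenarioConfig) -> ScenarioBundle:
    """Reattach the model specs / metric pair to a deserialized config."""
    name = config.scenario_name
    kwargs: dict = {}
    if isinstance(config.design, PubertyDesign):
        kwargs = dict(variability="high" if (config.puberty_dist or pub.HIGH_VARIABILITY).location_sd > 1
                      else "low",
                      sampling=config.design.sampling,
                      design="cohort" if config.design.frame == "cohort" else "accelerated")
    elif name == "intervention":
        kwargs = dict(waves=config.design.n_waves)
    elif name not in ("tvc_stress",):
        kwargs = dict(design=config.design.design_label)
    proto = get_scenario(name, **kwargs)
    return ScenarioBundle(config, proto.models, proto.rho_pair, proto.vif_regressors)
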