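"""REML estimation of single- and multi-growth mixed-effects models.

The *mis-specified* model is the conventional age-only growth model; the
*properly specified* model adds every growth process the scenario
generated.  Both are linear mixed models with a subject-level random
intercept (and optionally a random age slope), estimated by restricted
maximum likelihood through :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

p-values are two-sided Wald tests on the asymptotic normal scale.  With
750 observations the difference from a Satterthwaite-df t test is below
half a percent in the critical value, so no df approximation is applied;
``fit_mlm`` accepts a ``pvalue_fn`` hook for callers who want one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: optimizer cascade tried in order until convergence
_METHODS = (None, "lbfgs", "powell", "cg")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed and random terms to estimate.

    ``fixed_terms`` are centred predictor/product column names, intercept
    implied.  ``random_terms`` is ``("intercept",)`` or
    ``("intercept", "age_c")``.
    """

    fixed_terms: tuple
    random_terms: tuple = ("intercept",)
    label: str = "properly_specified"

    def __post_init__(self) -> None:
        if not self.fixed_terms:
            raise ValueError("fixed_terms must be non-empty")
        if self.random_terms[0] != "intercept":
            raise ValueError("the random part must include the intercept")


def age_only(quadratic: bool = False, random_terms=("intercept",)) -> ModelSpec:
    """The conventional mis-specified model (age, optionally + age^2)."""
    terms = ("age_c", "age_c2") if quadratic else ("age_c",)
    return ModelSpec(terms, tuple(random_terms), label="mis_specified")


@dataclass
class FitResult:
    """Tidy view of one fitted model on one replicant."""

    label: str
    terms: list  # ordered fixed-term names, excluding intercept
    estimates: dict
    std_errors: dict
    p_values: dict
    p_adjusted: dict = field(default_factory=dict)
    sigma: float = np.nan
    tau00: float = np.nan
    tau11: float = np.nan
    converged: bool = False

    def to_frame(self, replicant: int | None = None) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "replicant": replicant,
                    "model_label": self.label,
                    "term": t,
                    "estimate": self.estimates[t],
                    "se": self.std_errors[t],
                    "p": self.p_values[t],
                    "p_adj": self.p_adjusted.get(t, np.nan),
                    "sigma": self.sigma,
                    "tau00": self.tau00,
                    "tau11": self.tau11,
                    "converged": self.converged,
                }
            )
        return pd.DataFrame(rows)


def fit_mlm(dataset: pd.DataFrame, spec: ModelSpec, pvalue_fn=None) -> FitResult:
    """Fit one mixed model by REML and extract tidy results.

    Non-convergence after the whole optimizer cascade is reported through
    ``converged=False`` rather than an exception, so replication loops can
    drop and count such replicants.
    """
    missing = [t for t in spec.fixed_terms if t not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks fixed-term columns: {missing}")
    endog = dataset["y"].to_numpy()
    exog = np.column_stack(
        [np.ones(len(dataset))] + [dataset[t].to_numpy() for t in spec.fixed_terms]
    )
    names = ["intercept", *spec.fixed_terms]
    with_slope = "age_c" in spec.random_terms
    if with_slope:
        exog_re = np.column_stack([np.ones(len(dataset)), dataset["age_c"].to_numpy()])
    else:
        exog_re = np.ones((len(dataset), 1))
    groups = dataset["subject_id"].to_numpy()

    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    result = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _METHODS:
            try:
                kwargs = {} if method is None else {"method": method}
                candidate = model.fit(reml=True, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            result = candidate
            if candidate.converged:
                converged = True
                break

    if result is None:
        nan = {t: np.nan for t in spec.fixed_terms}
        return FitResult(spec.label, list(spec.fixed_terms), dict(nan), dict(nan), dict(nan))

    fe = dict(zip(names, np.asarray(result.fe_params)))
    se = dict(zip(names, np.asarray(result.bse_fe)))
    if pvalue_fn is None:
        pv = dict(zip(names, np.asarray(result.pvalues)[: len(names)]))
    else:
        pv = {n: pvalue_fn(fe[n], se[n], result) for n in names}
    cov_re = np.asarray(result.cov_re)
    tau00 = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    tau11 = float(np.sqrt(max(cov_re[1, 1], 0.0))) if with_slope else np.nan
    return FitResult(
        label=spec.label,
        terms=list(spec.fixed_terms),
        estimates={t: float(fe[t]) for t in spec.fixed_terms},
        std_errors={t: float(se[t]) for t in spec.fixed_terms},
        p_values={t: float(pv[t]) for t in spec.fixed_terms},
        sigma=float(np.sqrt(result.scale)),
        tau00=tau00,
        tau11=tau11,
        converged=converged,
    )


def adjust_pvalues(fit: FitResult, n_predictors: int | None = None) -> FitResult:
    """Bonferroni-adjust the growth-term p-values within one model.

    ``n_predictors`` defaults to the number of growth fixed-effect terms
    in the fit (intercept excluded), matching a within-model correction
    for 1-3 predictors.
    """
    m = len(fit.terms) if n_predictors is None else n_predictors
    if m < 1:
        raise ValueError("n_predictors must be >= 1")
    fit.p_adjusted = {t: min(1.0, m * p) for t, p in fit.p_values.items()}
    return fit


def implied_vertex(fit: FitResult | dict, linear: str = "age_c", quad: str = "age_c2",
                   center_age: float | None = None):
    """Inflection point -gamma_linear / (2 gamma_quad) of a quadratic trend.

    Returns the vertex on the centred age scale, or a ``(centred, raw)``
    pair when ``center_age`` is given.  Raises if the quadratic term is
    absent or exactly zero (the vertex is undefined, not infinite).
    """
    est = fit.estimates if isinstance(fit, FitResult) else fit
    if quad not in est or est[quad] == 0 or not np.isfinite(est[quad]):
        raise ValueError("implied vertex requires a nonzero quadratic term")
    v = -est[linear] / (2.0 * est[quad])
    if center_age is None:
        return v
    return v, v + center_age
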