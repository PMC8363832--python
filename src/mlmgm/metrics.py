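"""Parameter-recovery diagnostics over replicant ensembles.

These implement the evaluation statistics used throughout the simulation
study: the pooled correlation between growth predictors, the variance
inflation factor (VIF) and its implied standard-error inflation, the
standardized bias of an estimator relative to its own sampling spread,

    bias_std = (mean_j estimate_j - truth) / SD_j(estimate_j),

with |bias| > .25 flagged as poor recovery, and significance proportions
that only credit a rejection when the estimated sign matches the
generating sign (for a null truth they are plain false-positive rates).

:func:`summarize` aggregates an ensemble of fits into one table row per
(model, term) mirroring the layout "Mean Est / Std Err / Min / Max /
Std Bias / Prop Sig (adj)", where "Std Err" is the SD of the estimates
across replicants, not the mean model standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult

#: |standardized bias| above this is flagged as poor recovery
BIAS_FLAG = 0.25


def growth_correlation(dataset: pd.DataFrame, pred_a: str, pred_b: str) -> float:
    """Pearson correlation between two predictors pooled over all rows."""
    a = dataset[pred_a].to_numpy(dtype=float)
    b = dataset[pred_b].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("growth_correlation requires nonzero-variance predictors")
    return float(np.corrcoef(a, b)[0, 1])


def variance_inflation(dataset: pd.DataFrame, target_pred: str, other_preds) -> float:
    """VIF = 1 / (1 - R^2) of ``target_pred`` regressed on ``other_preds``."""
    other_preds = [other_preds] if isinstance(other_preds, str) else list(other_preds)
    if not other_preds:
        raise ValueError("at least one other predictor is required")
    y = dataset[target_pred].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(dataset))] + [dataset[p].to_numpy(dtype=float) for p in other_preds])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        raise ValueError("perfect collinearity: VIF undefined (degenerate design)")
    return float(1.0 / (1.0 - r2))


def se_inflation(vif: float) -> float:
    """Factor by which a coefficient's SE grows relative to orthogonal
    predictors: sqrt(VIF)."""
    if vif < 1:
        raise ValueError("VIF cannot be below 1")
    return float(np.sqrt(vif))


def standardized_bias(estimates, truth: float) -> float:
    """(mean - truth) / empirical SD across replicants, in SD units."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("standardized bias needs >= 2 estimates")
    sd = est.std(ddof=1)
    if sd == 0:
        raise ValueError("estimates have zero spread")
    return float((est.mean() - truth) / sd)


def proportion_significant(fits, term: str, truth: float, alpha: float = 0.05,
                           use_adjusted: bool = False) -> float:
    """Fraction of fits rejecting at ``alpha`` with the correct sign.

    When ``truth`` is 0 the sign filter is dropped and the result is the
    false-positive rate.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    hits = 0
    for f in fits:
        p = f.p_adjusted[term] if use_adjusted else f.p_values[term]
        if not np.isfinite(p) or p >= alpha:
            continue
        if truth == 0 or np.sign(f.estimates[term]) == np.sign(truth):
            hits += 1
    return hits / len(fits)


def _column_summary(values: np.ndarray, truth: float | None) -> dict:
    out = {
        "mean_est": float(values.mean()),
        "sd_est": float(values.std(ddof=1)),
        "min_est": float(values.min()),
        "max_est": float(values.max()),
    }
    if truth is not None and out["sd_est"] > 0:
        out["std_bias"] = (out["mean_est"] - truth) / out["sd_est"]
        out["flagged"] = abs(out["std_bias"]) > BIAS_FLAG
    else:
        out["std_bias"] = np.nan
        out["flagged"] = False
    return out


def summarize(fits_by_model: dict, truth: dict, rho: np.ndarray | None = None,
              vif: np.ndarray | None = None, n_replicants: int | None = None) -> pd.DataFrame:
    """Aggregate converged fits into the study's table layout.

    Parameters
    ----------
    fits_by_model
        ``{model_label: [FitResult, ...]}``; each list must hold >= 2
        converged fits with identical term sets.
    truth
        Generating values keyed by term name (plus ``sigma``/``tau00``/
        ``tau11``).  Terms without a truth entry get no bias column.
    rho, vif
        Optional per-replicant pooled growth correlation and VIF arrays,
        summarised into their own rows.
    """
    rows = []
    for label, fits in fits_by_model.items():
        fits = [f for f in fits if f.converged]
        if len(fits) < 2:
            raise ValueError(f"model {label!r} has fewer than 2 converged replicants")
        terms = fits[0].terms
        if any(f.terms != terms for f in fits):
            raise ValueError("mismatched term sets across replicants")
        for t in terms:
            est = np.array([f.estimates[t] for f in fits])
            row = {"model_label": label, "term": t, **_column_summary(est, truth.get(t))}
            tr = truth.get(t)
            row["prop_sig_raw"] = proportion_significant(fits, t, tr if tr is not None else 0.0)
            if fits[0].p_adjusted:
                row["prop_sig_adj"] = proportion_significant(
                    fits, t, tr if tr is not None else 0.0, use_adjusted=True
                )
            rows.append(row)
        for comp, attr in [("sigma", "sigma"), ("tau00", "tau00"), ("tau11", "tau11")]:
            vals = np.array([getattr(f, attr) for f in fits])
            if np.all(np.isfinite(vals)):
                rows.append({"model_label": label, "term": comp,
                             **_column_summary(vals, truth.get(comp))})
        rows[-1]["n_converged"] = len(fits)
    for name, arr in [("rho_growth", rho), ("vif", vif)]:
        if arr is not None:
            arr = np.asarray(arr, dtype=float)
            rows.insert(0, {"model_label": "design", "term": name, **_column_summary(arr, None)})
    frame = pd.DataFrame(rows)
    if n_replicants is not None:
        frame.attrs["n_replicants"] = n_replicants
    return frame
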