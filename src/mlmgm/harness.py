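"""Replication engine: simulate -> fit -> summarize, with seed management.

``run_replications`` executes the full Monte-Carlo loop for one scenario
cell: each replicant dataset is generated from its own child random
stream (derived from the master seed and the replicant index, so results
are independent of execution order), every registered model is fitted by
REML, Bonferroni adjustment is applied within model, and the ensemble is
aggregated into the study's summary layout.  Non-convergent replicants
are dropped from aggregation and counted; a warning is raised when more
than 2% drop.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .fitting import FitResult, adjust_pvalues, fit_mlm, implied_vertex
from .library import ScenarioBundle, TABLE_CELLS, config_to_dict, get_scenario
from .scenarios import build_scenario

#: warn when more than this fraction of replicants fails to converge
CONVERGENCE_WARN_FRACTION = 0.02


@dataclass
class RunResult:
    """Everything produced by one replicated scenario run."""

    summary: pd.DataFrame
    manifest: dict
    fits_by_model: dict
    rho: np.ndarray
    vif: np.ndarray
    truth: dict
    tidy: pd.DataFrame = field(default_factory=pd.DataFrame)


def _config_hash(config) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_replications(bundle: ScenarioBundle, n_replicants: int | None = None,
                     master_seed: int | None = None, keep_tidy: bool = False,
                     compute_vif: bool = True) -> RunResult:
    """Run the Monte-Carlo loop for one scenario bundle.

    ``n_replicants``/``master_seed`` override the config's values when
    given.  Set ``keep_tidy`` to collect the per-replicant tidy estimate
    table alongside the summary.
    """
    config = bundle.config
    if n_replicants is None:
        n_replicants = config.n_replicants
    if master_seed is None:
        master_seed = config.master_seed
    if n_replicants < 2:
        raise ValueError("n_replicants must be >= 2")
    from dataclasses import replace

    config = replace(config, n_replicants=n_replicants, master_seed=master_seed)

    fits_by_model: dict[str, list[FitResult]] = {label: [] for label in bundle.models}
    rho, vif = [], []
    tidy_frames = []
    truth: dict = {}
    n_dropped = 0

    for rep in range(n_replicants):
        data, truth = build_scenario(config, rep)
        rho.append(metrics.growth_correlation(data, *bundle.rho_pair))
        if compute_vif:
            vif.append(metrics.variance_inflation(data, bundle.rho_pair[0],
                                                  list(bundle.vif_regressors)))
        rep_ok = True
        rep_fits = {}
        for label, spec in bundle.models.items():
            fit = fit_mlm(data, spec)
            adjust_pvalues(fit)
            rep_fits[label] = fit
            rep_ok = rep_ok and fit.converged
        if not rep_ok:
            n_dropped += 1
        for label, fit in rep_fits.items():
            fits_by_model[label].append(fit)
            if keep_tidy:
                tidy_frames.append(fit.to_frame(rep))

    if n_dropped > CONVERGENCE_WARN_FRACTION * n_replicants:
        warnings.warn(
            f"{n_dropped}/{n_replicants} replicants failed to converge",
            RuntimeWarning,
        )

    summary = metrics.summarize(
        fits_by_model, truth,
        rho=np.asarray(rho), vif=np.asarray(vif) if compute_vif else None,
        n_replicants=n_replicants,
    )
    summary = _append_vertex_rows(summary, fits_by_model, truth)

    manifest = {
        "scenario": config.scenario_name,
        "config_hash": _config_hash(config),
        "master_seed": master_seed,
        "n_replicants": n_replicants,
        "child_seed_scheme": "default_rng([master_seed, replicant, stream])",
        "n_dropped": n_dropped,
        "models": {label: list(spec.fixed_terms) for label, spec in bundle.models.items()},
    }
    return RunResult(summary, manifest, fits_by_model, np.asarray(rho),
                     np.asarray(vif) if compute_vif else np.asarray([]), truth,
                     pd.concat(tidy_frames, ignore_index=True) if tidy_frames else pd.DataFrame())


def _append_vertex_rows(summary: pd.DataFrame, fits_by_model: dict, truth: dict) -> pd.DataFrame:
    """Add the implied-inflection-point row for models with a quadratic term."""
    if "age_c2" not in truth or truth.get("age_c2") in (None, 0):
        return summary
    v_truth = -truth.get("age_c", 0.0) / (2 * truth["age_c2"])
    extra = []
    for label, fits in fits_by_model.items():
        fits = [f for f in fits if f.converged and "age_c2" in f.terms]
        if len(fits) < 2:
            continue
        vals = []
        for f in fits:
            try:
                vals.append(implied_vertex(f))
            except ValueError:
                pass
        if len(vals) < 2:
            continue
        arr = np.asarray(vals)
        extra.append({"model_label": label, "term": "vertex",
                      **metrics._column_summary(arr, v_truth)})
    if extra:
        summary = pd.concat([summary, pd.DataFrame(extra)], ignore_index=True)
    return summary


def reproduce_table(table_id: int, n_replicants: int = 1000, seed: int = 0,
                    out_dir=None) -> dict:
    """Re-run every scenario cell behind one summary table of the study.

    Returns ``{cell_name: RunResult}``; when ``out_dir`` is given each
    summary is also written as ``table<k>_<cell>.csv`` plus a JSON
    manifest.
    """
    if table_id not in TABLE_CELLS:
        raise ValueError(f"unknown table id {table_id!r}; expected 1-8")
    results = {}
    for cell in TABLE_CELLS[table_id]:
        cell = dict(cell)
        name = cell.pop("name")
        bundle = get_scenario(name, n_replicants=n_replicants, master_seed=seed, **cell)
        tag = "_".join([name, *[f"{v}" for v in cell.values()]]) or name
        results[tag] = run_replications(bundle)
        if out_dir is not None:
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            results[tag].summary.to_csv(out / f"table{table_id}_{tag}.csv", index=False)
            (out / f"table{table_id}_{tag}.manifest.json").write_text(
                json.dumps(results[tag].manifest, indent=2)
            )
    return results
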