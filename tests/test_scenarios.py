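"""Outcome simulation: centering, random effects, TVC, MCAR, determinism."""

import numpy as np
import pandas as pd
import pytest

import mlmgm
from mlmgm.scenarios import (
    FixedEffects,
    RandomEffectsSpec,
    TVCSpec,
    build_scenario,
    center_predictors,
    inject_mcar,
    simulate_outcome,
    simulate_stress_tvc,
)


def _tiny_grid(ages, exposures=None):
    n = len(ages)
    return pd.DataFrame({
        "subject_id": np.zeros(n, dtype=int),
        "occasion": np.arange(n),
        "age": ages,
        "exposure_count": exposures if exposures is not None else np.arange(n),
        "tx_count": np.zeros(n, dtype=int),
        "design_label": "cohort",
    })


class TestCentering:
    def test_arithmetic_example(self):
        out = center_predictors(_tiny_grid([10.0, 12.0, 14.0]))
        assert np.allclose(out["age_c"], [-2.0, 0.0, 2.0])

    def test_constant_predictor_centres_to_zero(self):
        out = center_predictors(_tiny_grid([10, 11, 12], exposures=[3, 3, 3]))
        assert np.allclose(out["exposure_c"], 0.0)

    def test_quadratic_orthogonal_to_linear_on_symmetric_grid(self, cohort_grid):
        out = center_predictors(cohort_grid, quadratic=True)
        r = np.corrcoef(out["age_c"], out["age_c2"])[0, 1]
        assert abs(r) < 0.02  # symmetric age distribution

    def test_centred_columns_have_zero_mean(self, accelerated_grid):
        out = center_predictors(accelerated_grid, quadratic=True)
        assert abs(out["age_c"].mean()) < 1e-10 * out["age"].abs().max()
        assert abs(out["exposure_c"].mean()) < 1e-12

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            center_predictors(_tiny_grid([]).iloc[:0])


class TestSimulateOutcome:
    def test_deterministic_limit(self):
        d = center_predictors(_tiny_grid([10.0, 12.0, 14.0]))
        out = simulate_outcome(d, FixedEffects(0.0, {"age_c": 0.3}),
                               RandomEffectsSpec(0, 0, 0), seed=0)
        assert out["y"].iloc[2] == pytest.approx(0.6)

    def test_zero_noise_ols_identifiability(self, accelerated_grid):
        # with all random SDs zero, OLS on the full design matrix recovers
        # every generating coefficient to machine precision
        d = center_predictors(accelerated_grid, quadratic=True)
        fixed = FixedEffects(0.25, {"age_c": 0.3, "age_c2": -0.1, "exposure_c": -0.2})
        out = simulate_outcome(d, fixed, RandomEffectsSpec(0, 0, 0), seed=1)
        X = np.column_stack([np.ones(len(out)), out.age_c, out.age_c2, out.exposure_c])
        beta = np.linalg.lstsq(X, out.y, rcond=None)[0]
        assert np.allclose(beta, [0.25, 0.3, -0.1, -0.2], atol=1e-9)

    def test_variance_accounting(self, cohort_grid):
        d = center_predictors(cohort_grid)
        re = RandomEffectsSpec(intercept_sd=0.5, slope_sd=0.0, residual_sd=1.0)
        draws = [simulate_outcome(d, FixedEffects(0, {"age_c": 0.3}), re, seed=s)["y"]
                 - 0.3 * d["age_c"] for s in range(60)]
        total_var = np.var(np.concatenate(draws))
        assert total_var == pytest.approx(0.5**2 + 1.0**2, rel=0.05)

    def test_unknown_predictor_rejected(self):
        d = center_predictors(_tiny_grid([10, 11, 12]))
        with pytest.raises(ValueError):
            simulate_outcome(d, FixedEffects(0, {"nope": 1.0}), RandomEffectsSpec(), 0)


class TestStressTVC:
    def test_zero_error_collapses_to_signal(self, cohort_grid):
        out = simulate_stress_tvc(cohort_grid, TVCSpec(error_sd=0.0), seed=0)
        assert np.allclose(out["stress_true"], out["stress_observed"])

    def test_calibrated_age_stress_correlation(self):
        rho = []
        for s in range(60):
            g = mlmgm.make_school_grid(mlmgm.SCHOOL_DEFAULT, seed=s)
            out = simulate_stress_tvc(g, TVCSpec(), seed=s)
            rho.append(np.corrcoef(out["age"], out["stress_observed"])[0, 1])
        assert np.mean(rho) == pytest.approx(0.41, abs=0.02)

    def test_negative_error_sd_rejected(self):
        with pytest.raises(ValueError):
            TVCSpec(error_sd=-0.1)


class TestMCAR:
    def test_zero_rate_is_identity(self, cohort_grid):
        assert inject_mcar(cohort_grid, 0.0, seed=0) is cohort_grid

    def test_expected_deletion_count(self, cohort_grid):
        kept = [len(inject_mcar(cohort_grid, 0.10, seed=s)) for s in range(100)]
        deleted = 750 - np.mean(kept)
        assert deleted == pytest.approx(75, abs=3 * np.sqrt(750 * 0.1 * 0.9 / 100))

    def test_deletion_independent_of_outcome(self):
        # MCAR: the deleted rows' outcomes are a random sample of all outcomes
        b = mlmgm.get_scenario("additive")
        pvals = []
        for rep in range(40):
            data, _ = build_scenario(b.config, rep)
            kept = inject_mcar(data, 0.10, seed=rep)
            from scipy import stats
            pvals.append(stats.ks_2samp(data["y"], kept["y"]).pvalue)
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_invalid_rate_rejected(self, cohort_grid):
        for bad in (-0.1, 1.0):
            with pytest.raises(ValueError):
                inject_mcar(cohort_grid, bad, seed=0)


class TestBuildScenario:
    def test_determinism_contract(self):
        b = mlmgm.get_scenario("puberty", variability="low", sampling="slow", master_seed=9)
        d1, t1 = build_scenario(b.config, 3)
        d2, t2 = build_scenario(b.config, 3)
        pd.testing.assert_frame_equal(d1, d2)
        assert t1 == t2

    def test_replicants_differ(self):
        b = mlmgm.get_scenario("additive")
        d0, _ = build_scenario(b.config, 0)
        d1, _ = build_scenario(b.config, 1)
        assert not np.allclose(d0["y"], d1["y"])

    def test_puberty_truth_record(self):
        b = mlmgm.get_scenario("puberty")
        _, truth = build_scenario(b.config, 0)
        assert (truth["age_c"], truth["puberty_c"], truth["age_c_x_puberty_c"]) == (0.0, 2.0, -0.5)
        assert truth["tanner_c"] == pytest.approx(0.5)
        assert truth["sigma"] == 0.5 and truth["tau00"] == 0.5

    def test_intervention_truth_and_random_structure(self):
        b = mlmgm.get_scenario("intervention")
        _, truth = build_scenario(b.config, 0)
        assert truth["tau00"] == 1.0 and truth["tau11"] == 0.15 and truth["sigma"] == 0.5

    def test_config_roundtrip_through_yaml(self, tmp_path):
        import mlmgm.library as lib

        b = mlmgm.get_scenario("puberty", variability="low", sampling="fast",
                               n_replicants=17, master_seed=123)
        path = tmp_path / "cfg.yaml"
        lib.save_config(b.config, path)
        loaded = lib.load_config(path)
        assert loaded == b.config
        d1, t1 = build_scenario(b.config, 0)
        d2, t2 = build_scenario(loaded, 0)
        pd.testing.assert_frame_equal(d1, d2)
        assert t1 == t2
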