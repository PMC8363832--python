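"""Recovery diagnostics: correlations, VIF, standardized bias, significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mlmgm
from mlmgm.fitting import FitResult
from mlmgm.metrics import (
    growth_correlation,
    proportion_significant,
    se_inflation,
    standardized_bias,
    summarize,
    variance_inflation,
)


def _df(**cols):
    return pd.DataFrame(cols)


def _fit(est, p, term="g", p_adj=None):
    f = FitResult("m", [term], {term: est}, {term: np.nan}, {term: p}, converged=True)
    if p_adj is not None:
        f.p_adjusted = {term: p_adj}
    return f


class TestCorrelationAndVIF:
    def test_self_correlation_is_one(self):
        d = _df(a=[1.0, 2, 3, 5], b=[1.0, 2, 3, 5])
        assert growth_correlation(d, "a", "b") == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            growth_correlation(_df(a=[1.0, 1, 1], b=[1.0, 2, 3]), "a", "b")

    def test_orthogonal_predictors_give_unit_vif(self):
        d = _df(a=[1.0, -1, 1, -1], b=[1.0, 1, -1, -1])
        assert variance_inflation(d, "a", ["b"]) == pytest.approx(1.0)

    def test_half_correlation_gives_four_thirds(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200_000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=x.size)
        assert variance_inflation(_df(a=x, b=y), "a", ["b"]) == pytest.approx(4 / 3, rel=0.01)

    def test_vif_equals_inverse_one_minus_rho_squared(self, accelerated_grid):
        # two-predictor identity, exact to numerical precision, both ways
        rho = growth_correlation(accelerated_grid, "age", "exposure_count")
        for target, other in [("age", "exposure_count"), ("exposure_count", "age")]:
            vif = variance_inflation(accelerated_grid, target, [other])
            assert vif == pytest.approx(1.0 / (1.0 - rho**2), abs=1e-10)

    def test_perfect_collinearity_rejected(self):
        d = _df(a=[1.0, 2, 3, 4], b=[2.0, 4, 6, 8])
        with pytest.raises(ValueError):
            variance_inflation(d, "a", ["b"])

    def test_se_inflation(self):
        assert se_inflation(1.0) == pytest.approx(1.0)
        assert se_inflation(1.17) == pytest.approx(1.08, abs=0.005)
        assert se_inflation(202.0) == pytest.approx(14.2, abs=0.1)
        with pytest.raises(ValueError):
            se_inflation(0.9)


class TestStandardizedBias:
    def test_arithmetic_example(self):
        assert standardized_bias([0.4, 0.5, 0.6], 0.4) == pytest.approx(1.0)

    def test_unbiased_when_truth_is_mean(self):
        est = [0.1, 0.3, 0.2, 0.4]
        assert standardized_bias(est, np.mean(est)) == pytest.approx(0.0)

    @given(scale=st.floats(0.1, 100), shift=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_affine_rescaling(self, scale, shift):
        est = np.array([0.2, 0.35, 0.3, 0.5])
        base = standardized_bias(est, 0.25)
        moved = standardized_bias(scale * est + shift, scale * 0.25 + shift)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            standardized_bias([0.3], 0.3)
        with pytest.raises(ValueError):
            standardized_bias([0.3, 0.3, 0.3], 0.2)


class TestProportionSignificant:
    def test_all_null_pvalues_give_zero(self):
        fits = [_fit(0.5, 1.0) for _ in range(10)]
        assert proportion_significant(fits, "g", 0.3) == 0.0

    def test_sign_filter_drops_wrong_direction(self):
        fits = [_fit(+1.0, 0.001) for _ in range(5)] + [_fit(-1.0, 0.001) for _ in range(5)]
        assert proportion_significant(fits, "g", truth=+0.3) == 0.5
        # a null truth counts rejections regardless of sign
        assert proportion_significant(fits, "g", truth=0.0) == 1.0

    def test_adjusted_rate_never_exceeds_raw(self):
        rng = np.random.default_rng(1)
        fits = []
        for _ in range(200):
            p = rng.uniform(0, 0.2)
            fits.append(_fit(rng.normal(0.3, 0.1), p, p_adj=min(1.0, 2 * p)))
        raw = proportion_significant(fits, "g", 0.3)
        adj = proportion_significant(fits, "g", 0.3, use_adjusted=True)
        assert adj <= raw

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            proportion_significant([], "g", 0.3)


class TestSummarize:
    def _fits(self, rng, n=20):
        fits = []
        for _ in range(n):
            est = rng.normal(0.3, 0.05)
            p = rng.uniform(0, 1)
            f = FitResult("properly_specified", ["age_c"], {"age_c": est},
                          {"age_c": 0.05}, {"age_c": p}, sigma=1.0, tau00=0.5,
                          converged=True)
            f.p_adjusted = {"age_c": min(1.0, 2 * p)}
            fits.append(f)
        return fits

    def test_column_semantics(self, rng):
        fits = self._fits(rng)
        ests = [f.estimates["age_c"] for f in fits]
        s = summarize({"properly_specified": fits}, {"age_c": 0.3})
        row = s[s.term == "age_c"].iloc[0]
        assert row["mean_est"] == pytest.approx(np.mean(ests))
        assert row["sd_est"] == pytest.approx(np.std(ests, ddof=1))
        assert row["min_est"] <= row["mean_est"] <= row["max_est"]
        assert row["std_bias"] == pytest.approx((np.mean(ests) - 0.3) / np.std(ests, ddof=1))

    def test_permutation_invariance(self, rng):
        fits = self._fits(rng)
        s1 = summarize({"m": fits}, {"age_c": 0.3})
        s2 = summarize({"m": fits[::-1]}, {"age_c": 0.3})
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_replicant_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize({"m": self._fits(rng, n=1)}, {"age_c": 0.3})

    def test_rho_and_vif_rows(self, rng):
        s = summarize({"m": self._fits(rng)}, {"age_c": 0.3},
                      rho=np.array([0.4, 0.42]), vif=np.array([1.2, 1.21]))
        assert set(s[s.model_label == "design"]["term"]) == {"rho_growth", "vif"}
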