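"""Correlation/regression analysis, including the published Luoping
statistics recomputed from the packaged 63-patch table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canopytherm.association import (
    backward_stepwise,
    durbin_watson,
    ols_simple,
    pearson,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_published_correlations(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        r_area = pearson(patch_table["area_hm2"], y)
        r_perim = pearson(patch_table["perimeter_km"], y)
        r_shape = pearson(patch_table["shape_index"], y)
        assert r_area.r == pytest.approx(0.319, abs=0.005)
        assert r_perim.r == pytest.approx(0.313, abs=0.005)
        assert r_shape.r == pytest.approx(0.218, abs=0.005)
        # significance pattern: area and perimeter significant, shape not
        assert r_area.p < 0.05 and r_perim.p < 0.05
        assert r_shape.p > 0.05
        assert r_shape.p == pytest.approx(0.086, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_invariant_under_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert pearson(a * x + b, y).r == pytest.approx(
            pearson(x, y).r, abs=1e-9)


class TestOlsSimple:
    def test_published_regressions(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        area = ols_simple(y, patch_table["area_hm2"])
        perim = ols_simple(y, patch_table["perimeter_km"])
        assert area.slope == pytest.approx(0.118, abs=0.005)
        assert area.intercept == pytest.approx(0.148, abs=0.005)
        assert perim.slope == pytest.approx(0.275, abs=0.005)
        assert perim.intercept == pytest.approx(-0.172, abs=0.005)
        assert area.r_squared == pytest.approx(0.103, abs=0.005)
        assert perim.r_squared == pytest.approx(0.098, abs=0.005)

    def test_r_squared_equals_pearson_r_squared(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        x = patch_table["area_hm2"]
        assert ols_simple(y, x).r_squared == pytest.approx(
            pearson(x, y).r ** 2, abs=1e-12)

    def test_constant_response_convention(self):
        fit = ols_simple([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert fit.slope == 0.0 and fit.intercept == 5.0
        assert fit.r_squared == 0.0
        assert np.isnan(fit.durbin_watson)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ols_simple([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestDurbinWatson:
    def test_persistent_residuals_give_zero(self):
        assert durbin_watson([3.0] * 8) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 11, 50])
    def test_alternating_residuals_closed_form(self, n):
        """(c, -c, c, ...) gives DW = 4(n-1)/n by direct algebra."""
        e = 2.5 * (-1.0) ** np.arange(n)
        assert durbin_watson(e) == pytest.approx(4.0 * (n - 1) / n)

    def test_published_values_in_row_order(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        assert ols_simple(y, patch_table["area_hm2"]).durbin_watson == \
            pytest.approx(1.955, abs=0.01)
        assert ols_simple(y, patch_table["perimeter_km"]).durbin_watson == \
            pytest.approx(2.007, abs=0.01)

    def test_white_noise_is_near_two(self):
        rng = np.random.default_rng(21)
        assert 1.9 < durbin_watson(rng.normal(size=10_000)) < 2.1

    def test_matches_statsmodels(self, patch_table):
        from statsmodels.stats.stattools import durbin_watson as sm_dw
        resid = ols_simple(patch_table["cooling_rate_pct"],
                           patch_table["area_hm2"]).residuals
        assert durbin_watson(resid) == pytest.approx(sm_dw(resid), abs=1e-12)

    def test_all_zero_residuals_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            durbin_watson([0.0, 0.0, 0.0])


class TestBackwardStepwise:
    def test_pure_noise_predictor_removed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        noise = rng.normal(size=60)
        res = backward_stepwise(x, {"x": x, "noise": noise})
        assert res.retained == ("x",)
        assert res.removed[0][0] == "noise"

    def test_shape_index_removed_on_patch_table(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        res = backward_stepwise(y, {
            "area": patch_table["area_hm2"],
            "perimeter": patch_table["perimeter_km"],
            "shape_index": patch_table["shape_index"]}, alpha=0.05)
        assert "shape_index" in [n for n, _ in res.removed]

    def test_single_significant_predictor_kept(self):
        x = np.arange(20.0)
        res = backward_stepwise(2 * x + 0.1 * np.sin(x), {"x": x})
        assert res.retained == ("x",)
        assert res.removed == ()

    def test_removal_order_deterministic(self, patch_table):
        y = patch_table["cooling_rate_pct"]
        preds = {"area": patch_table["area_hm2"],
                 "perimeter": patch_table["perimeter_km"],
                 "shape_index": patch_table["shape_index"]}
        a = backward_stepwise(y, preds)
        b = backward_stepwise(y, preds)
        assert a.removed == b.removed and a.retained == b.retained
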