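"""Quadratic response-surface fitting, ANOVA, prediction and optimization."""

import numpy as np
import pytest

from qamskit.doe import DesignMatrix, FactorSpec, make_ccd, rsm_factors
from qamskit.exceptions import ConfigurationError, FitError
from qamskit.rsm import (
    anova_table,
    export_surface,
    fit_quadratic,
    optimize,
    predict,
    quote_floor,
    verification_deviation,
)

# actual-unit regression coefficients reported for the 13-run campaign
PRINTED_COEFFS = {
    "Intercept": 22.24149,
    "X1": -0.54921,
    "X2": 0.036763,
    "X1X2": -0.018600,
    "X1^2": 0.0071550,
    "X2^2": 0.0218553,
}


def toy_model():
    """Exactly quadratic concave surface Y = 10 - (X1-3)^2 - (X2-5)^2."""
    specs = (FactorSpec("a", "", 0.0, 10.0), FactorSpec("b", "", 0.0, 10.0))
    design = make_ccd(specs, n_center=5)
    x = design.actual
    y = 10 - (x[:, 0] - 3) ** 2 - (x[:, 1] - 5) ** 2
    return fit_quadratic(design.with_response(y), units="actual")


class TestFit:
    def test_actual_unit_coefficients_match_printed_equation(self, ccd_design):
        model = fit_quadratic(ccd_design, units="actual")
        for term, printed in PRINTED_COEFFS.items():
            assert model.coef[term] == pytest.approx(printed, rel=0.005)

    def test_r_squared_matches_printed_value(self, ccd_design):
        assert fit_quadratic(ccd_design).r_squared == pytest.approx(0.8102, abs=0.005)

    def test_exact_interpolation_of_known_quadratic(self):
        model = toy_model()
        assert model.coef["Intercept"] == pytest.approx(10 - 9 - 25, abs=1e-9)
        assert model.coef["X1"] == pytest.approx(6.0, abs=1e-9)
        assert model.coef["X1^2"] == pytest.approx(-1.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_unit_systems_predict_identically(self, ccd_design):
        actual = fit_quadratic(ccd_design, units="actual")
        coded = fit_quadratic(ccd_design, units="coded")
        pts = np.array([[60.0, 30.0], [65.0, 25.0], [70.0, 20.0], [61.3, 27.7]])
        assert np.allclose(
            predict(actual, pts, warn_extrapolation=False),
            predict(coded, pts, warn_extrapolation=False),
            atol=1e-9,
        )

    def test_unit_conversion_round_trip(self, ccd_design):
        model = fit_quadratic(ccd_design, units="actual")
        back = model.to_units("coded").to_units("actual")
        assert np.allclose(model.coefficients, back.coefficients, atol=1e-9)

    def test_rank_deficiency_names_term(self):
        specs = (FactorSpec("a", "", 0.0, 10.0), FactorSpec("b", "", 0.0, 10.0))
        # all runs on the diagonal a == b: interaction/quadratic terms collide
        actual = np.column_stack([np.linspace(0, 10, 8), np.linspace(0, 10, 8)])
        design = DesignMatrix.from_actual(specs, actual, np.arange(8.0))
        with pytest.raises(FitError):
            fit_quadratic(design)

    def test_too_few_runs(self):
        specs = rsm_factors()
        design = DesignMatrix.from_actual(
            specs, np.array([[60.0, 20.0], [70.0, 30.0]]), np.array([1.0, 2.0])
        )
        with pytest.raises(FitError):
            fit_quadratic(design)


@pytest.fixture(scope="module")
def rows(ccd_design):
    return {r.term: r for r in anova_table(fit_quadratic(ccd_design))}


class TestAnova:
    def test_printed_f_statistics(self, rows):
        assert rows["Model"].f == pytest.approx(5.97, abs=0.10)
        assert rows["X1"].f == pytest.approx(7.41, abs=0.15)
        assert rows["X2"].f == pytest.approx(6.62, abs=0.15)
        assert rows["Lack of fit"].f == pytest.approx(5.01, abs=0.10)

    def test_pure_error_from_center_replicates(self, rows, ccd_design):
        y = ccd_design.response
        center = y[[0, 1, 2, 5, 6]]  # the five (65, 25) runs
        assert rows["Pure error"].ss == pytest.approx(((center - center.mean()) ** 2).sum())
        assert rows["Pure error"].ss == pytest.approx(0.28, abs=0.005)
        assert rows["Pure error"].df == 4

    def test_total_ss(self, rows):
        assert rows["Total"].ss == pytest.approx(7.04, abs=0.01)
        assert rows["Total"].df == 12

    def test_x1_partial_ss_equals_coded_coefficient_identity(self, rows, ccd_design):
        # orthogonality: SS(X1) = b1_coded^2 * sum(x1^2)
        coded = fit_quadratic(ccd_design, units="coded")
        sum_x1_sq = (ccd_design.coded[:, 0] ** 2).sum()
        assert rows["X1"].ss == pytest.approx(coded.coef["X1"] ** 2 * sum_x1_sq, abs=1e-8)

    def test_sum_of_squares_additivity(self, rows):
        assert rows["Model"].ss + rows["Residual"].ss == pytest.approx(
            rows["Total"].ss, abs=1e-8
        )
        assert rows["Lack of fit"].ss + rows["Pure error"].ss == pytest.approx(
            rows["Residual"].ss, abs=1e-8
        )

    def test_r_squared_consistent_with_anova(self, rows, ccd_design):
        model = fit_quadratic(ccd_design)
        assert model.r_squared == pytest.approx(1 - rows["Residual"].ss / rows["Total"].ss)

    def test_anova_against_brute_force_oracle(self, ccd_design):
        """Drop-one SS recomputed with raw normal equations."""
        x = ccd_design.coded
        y = ccd_design.response
        X = np.column_stack([np.ones(13), x[:, 0], x[:, 1], x[:, 0] * x[:, 1],
                             x[:, 0] ** 2, x[:, 1] ** 2])

        def rss(M):
            beta = np.linalg.solve(M.T @ M, M.T @ y)
            r = y - M @ beta
            return r @ r

        full = rss(X)
        rows = {r.term: r for r in anova_table(fit_quadratic(ccd_design))}
        for j, term in enumerate(["X1", "X2", "X1X2", "X1^2", "X2^2"], start=1):
            oracle_ss = rss(np.delete(X, j, axis=1)) - full
            assert rows[term].ss == pytest.approx(oracle_ss, abs=1e-10)

    def test_no_replicates_warns_and_omits_split(self):
        specs = (FactorSpec("a", "", 0.0, 10.0), FactorSpec("b", "", 0.0, 10.0))
        rng = np.random.default_rng(1)
        actual = rng.uniform(0, 10, size=(10, 2))
        design = DesignMatrix.from_actual(specs, actual, rng.uniform(0, 5, 10))
        model = fit_quadratic(design)
        with pytest.warns(UserWarning, match="no replicated runs"):
            rows = {r.term for r in anova_table(model)}
        assert "Lack of fit" not in rows


class TestPredictionAndVerification:
    def test_prediction_at_selected_conditions(self, ccd_design):
        model = fit_quadratic(ccd_design)
        assert predict(model, (60.0, 30.0)) == pytest.approx(2.33, abs=0.02)

    def test_printed_equation_evaluates_to_hand_value(self):
        c = PRINTED_COEFFS
        value = (c["Intercept"] + c["X1"] * 60 + c["X2"] * 30 + c["X1X2"] * 1800
                 + c["X1^2"] * 3600 + c["X2^2"] * 900)
        assert value == pytest.approx(2.3395, abs=1e-4)

    def test_centroid_prediction_equals_ols_oracle_fit_mean(self, ccd_design):
        model = fit_quadratic(ccd_design)
        x = ccd_design.coded
        y = ccd_design.response
        X = np.column_stack([np.ones(13), x[:, 0], x[:, 1], x[:, 0] * x[:, 1],
                             x[:, 0] ** 2, x[:, 1] ** 2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert predict(model, (65.0, 25.0)) == pytest.approx(beta[0], abs=1e-9)

    def test_extrapolation_warns(self, ccd_design):
        model = fit_quadratic(ccd_design)
        with pytest.warns(UserWarning, match="outside"):
            predict(model, (80.0, 25.0))

    def test_deviation_of_quoted_prediction_from_measured_mean(self):
        result = verification_deviation(2.33, [2.30])
        assert result.deviation_percent == pytest.approx(1.30, abs=0.05)

    def test_deviation_zero_when_exact_or_mean_matches(self):
        assert verification_deviation(2.0, [2.0]).deviation_percent == 0.0
        assert verification_deviation(2.0, [1.9, 2.1]).deviation_percent == pytest.approx(0.0)

    def test_empty_measurements_rejected(self):
        with pytest.raises(ConfigurationError):
            verification_deviation(2.0, [])

    def test_quote_floor_truncates(self):
        assert quote_floor(2.3392) == 2.33
        assert quote_floor(2.3399) == 2.33
        assert quote_floor(2.34) == 2.34


class TestOptimize:
    def test_analytic_maximum_of_concave_toy_surface(self):
        point, value = optimize(toy_model(), ((0.0, 10.0), (0.0, 10.0)))
        assert point == pytest.approx((3.0, 5.0), abs=1e-9)
        assert value == pytest.approx(10.0, abs=1e-9)

    def test_grid_matches_fine_grid_oracle_on_ccd_model(self, ccd_design):
        model = fit_quadratic(ccd_design)
        region = ((60.0, 70.0), (20.0, 30.0))
        point, value = optimize(model, region, grid_step_coded=0.01)
        g1 = np.linspace(60, 70, 2001)
        g2 = np.linspace(20, 30, 2001)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        preds = predict(model, np.column_stack([G1.ravel(), G2.ravel()]),
                        warn_extrapolation=False)
        best = np.argmax(preds)
        oracle_pt = (G1.ravel()[best], G2.ravel()[best])
        assert point[0] == pytest.approx(oracle_pt[0], abs=0.06)
        assert point[1] == pytest.approx(oracle_pt[1], abs=0.06)
        assert value == pytest.approx(preds[best], abs=1e-3)

    def test_target_objective_locates_level_set(self):
        model = toy_model()
        point, value = optimize(
            model, ((0.0, 10.0), (0.0, 10.0)), objective="target", target=1.5
        )
        assert value == pytest.approx(1.5, abs=0.05)

    def test_empty_region_rejected(self):
        with pytest.raises(ConfigurationError):
            optimize(toy_model(), ((5.0, 5.0), (0.0, 10.0)))


class TestSurfaceExport:
    def test_grid_values_match_direct_evaluation(self):
        model = toy_model()
        grid = export_surface(model, ((0.0, 10.0), (0.0, 10.0)), shape=(3, 3))
        assert len(grid) == 9
        direct = predict(model, grid[["a", "b"]].to_numpy(), warn_extrapolation=False)
        assert np.allclose(grid["predicted"], direct)

    def test_grid_brackets_region_optimum(self, ccd_design):
        model = fit_quadratic(ccd_design)
        region = ((60.0, 70.0), (20.0, 30.0))
        grid = export_surface(model, region, shape=(41, 41))
        _, best = optimize(model, region)
        assert grid["predicted"].min() <= best <= grid["predicted"].max() + 1e-9
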