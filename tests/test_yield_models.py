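"""Crop response curves, model selection and the sensitivity table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from saltyield import (
    BoronToleranceParams,
    EdaphicProfile,
    MissingInputError,
    ModelChoice,
    NoInteriorMaximumError,
    QuadraticToleranceParams,
    SaltToleranceParams,
    YieldModelCoefficients,
    argmax_quadratic,
    predict_field_yield,
    predict_yield_full,
    predict_yield_quadratic,
    relative_yield_boron,
    relative_yield_salt,
    select_model,
    sensitivity_analysis,
    zero_yield_threshold,
)
from saltyield.params import CurveFamily


class TestFullModel:
    @pytest.mark.parametrize(
        "profile, expected, tol",
        [
            ((4.0, 6.8, 0.27, 0.19), 1017.3, 0.1),
            ((0.0, 0.0, 0.0, 0.0), 30.1, 1e-9),  # the intercept
            ((10.06, 6.8, 0.27, 0.19), 345.2, 0.1),
        ],
    )
    def test_known_evaluations(self, profile, expected, tol):
        p = EdaphicProfile(*profile)
        assert predict_yield_full(p) == pytest.approx(expected, abs=tol)

    def test_negative_polynomial_truncated_to_zero(self):
        # high boron and salinity drive the raw polynomial negative
        from saltyield.yield_models import full_polynomial

        assert full_polynomial(20, 25, 0.1, 0.15) < 0
        assert predict_yield_full(EdaphicProfile(20, 25, 0.1, 0.15)) == 0.0

    def test_missing_regressor_raises_named_error(self):
        with pytest.raises(MissingInputError, match="lf"):
            predict_yield_full(EdaphicProfile(boron=4, ec_e=6, theta_g=0.19))

    def test_concavity_around_boron_and_salinity_optima(self):
        c = YieldModelCoefficients()
        b_star = argmax_quadratic((c.beta1, c.beta2))
        e_star = argmax_quadratic((c.beta3, c.beta4))
        best = predict_yield_full(EdaphicProfile(b_star, e_star, 0.27, 0.19), c)
        for db, de in [(0.5, 0), (-0.5, 0), (0, 0.5), (0, -0.5), (2, 3)]:
            other = predict_yield_full(
                EdaphicProfile(b_star + db, e_star + de, 0.27, 0.19), c
            )
            assert other < best


class TestToleranceCurves:
    @pytest.mark.parametrize(
        "ec, expected", [(5.0, 100.0), (9.3, 83.0), (20.0, 0.0)]
    )
    def test_two_piece_salt(self, ec, expected):
        assert relative_yield_salt(ec) == pytest.approx(expected)

    @pytest.mark.parametrize("b, expected", [(6.0, 100.0), (9.0, 72.0)])
    def test_three_piece_boron(self, b, expected):
        assert relative_yield_boron(b) == pytest.approx(expected)

    def test_boron_yield_vanishes_above_toxic_limit(self):
        assert relative_yield_boron(11.6) == pytest.approx(0.0, abs=1.0)
        assert relative_yield_boron(12.0) == 0.0

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_relative_yields_bounded(self, ec, b):
        assert 0.0 <= relative_yield_salt(ec) <= 100.0
        assert 0.0 <= relative_yield_boron(b) <= 100.0

    @pytest.mark.parametrize(
        "params, x, expected, tol",
        [
            (QuadraticToleranceParams.salt_default(), 0.0, 74.0, 1e-9),
            (QuadraticToleranceParams.salt_default(), 6.7713, 936.0, 0.5),
            (QuadraticToleranceParams.boron_default(), 0.0, 0.0, 1e-9),
            (QuadraticToleranceParams.boron_default(), 6.5472, 1399.5, 0.5),
        ],
    )
    def test_quadratic_curves(self, params, x, expected, tol):
        assert predict_yield_quadratic(x, params) == pytest.approx(expected, abs=tol)


class TestLandmarks:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            ((83.0, -6.1), 6.80),
            ((146.4, -18.3), 4.00),
            ((254.6, -18.8), 6.77),
            ((555.2, -42.4), 6.55),
        ],
    )
    def test_argmax_quadratic(self, pair, expected):
        assert argmax_quadratic(pair) == pytest.approx(expected, abs=0.005)

    def test_argmax_requires_concavity(self):
        with pytest.raises(NoInteriorMaximumError):
            argmax_quadratic((10.0, 0.5))

    def test_argmax_matches_numerical_maximiser_of_full_model(self):
        c = YieldModelCoefficients()
        analytic = argmax_quadratic((c.beta3, c.beta4))
        res = minimize_scalar(
            lambda e: -predict_yield_full(EdaphicProfile(4.0, e, 0.27, 0.19), c),
            bounds=(0, 30), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(analytic, abs=1e-6)

    @pytest.mark.parametrize(
        "params, expected",
        [
            (SaltToleranceParams(8.3, 17.0), 14.18),
            (BoronToleranceParams(), 11.57),
            (SaltToleranceParams(8.3, 100.0), 9.3),
        ],
    )
    def test_zero_yield_threshold(self, params, expected):
        assert zero_yield_threshold(params) == pytest.approx(expected, abs=0.005)

    def test_zero_yield_threshold_matches_grid_scan(self):
        p = SaltToleranceParams()
        grid = np.arange(0, 30, 1e-4)
        rel = relative_yield_salt(grid, p)
        first_zero = grid[np.argmax(rel == 0.0)]
        assert first_zero == pytest.approx(zero_yield_threshold(p), abs=1e-3)


class TestModelSelection:
    def test_complete_in_range_fine_texture_uses_full_model(self):
        p = EdaphicProfile(4.0, 6.8, 0.27, 0.19)
        assert select_model(p) is ModelChoice.FULL_MODEL

    def test_out_of_range_salinity_falls_back_to_tolerance(self):
        p = EdaphicProfile(4.0, 35.0, 0.27, 0.19)
        assert select_model(p) is ModelChoice.TOLERANCE_MOST_LIMITING

    def test_salinity_only_uses_salt_tolerance(self):
        assert (
            select_model(EdaphicProfile(ec_e=10.0))
            is ModelChoice.SALT_TOLERANCE_ONLY
        )

    def test_coarse_texture_never_uses_full_model(self):
        p = EdaphicProfile(4.0, 6.8, 0.27, 0.19)
        assert select_model(p, texture="coarse") is ModelChoice.TOLERANCE_MOST_LIMITING

    def test_no_stressor_data_assumes_optimal(self):
        assert select_model(EdaphicProfile(lf=0.3)) is ModelChoice.OPTIMAL

    @given(
        st.booleans(), st.booleans(), st.booleans(), st.booleans(),
        st.sampled_from(["fine", "coarse"]),
    )
    @settings(max_examples=64, deadline=None)
    def test_selection_is_total(self, has_b, has_e, has_lf, has_th, texture):
        p = EdaphicProfile(
            boron=5.0 if has_b else None,
            ec_e=6.0 if has_e else None,
            lf=0.3 if has_lf else None,
            theta_g=0.2 if has_th else None,
        )
        assert select_model(p, texture=texture) in ModelChoice


class TestFieldYield:
    def test_optimal_returns_plateau_yield(self):
        assert predict_field_yield(EdaphicProfile(), ModelChoice.OPTIMAL, y_max=936.0) == 936.0

    def test_salt_only_scales_plateau(self):
        y = predict_field_yield(
            EdaphicProfile(ec_e=9.3), ModelChoice.SALT_TOLERANCE_ONLY, y_max=1000.0
        )
        assert y == pytest.approx(830.0)

    def test_most_limiting_takes_minimum(self):
        y = predict_field_yield(
            EdaphicProfile(boron=9.0, ec_e=5.0),
            ModelChoice.TOLERANCE_MOST_LIMITING,
            y_max=1000.0,
        )
        assert y == pytest.approx(720.0)

    def test_quadratic_family_most_limiting(self):
        y = predict_field_yield(
            EdaphicProfile(boron=6.5472, ec_e=6.7713),
            ModelChoice.TOLERANCE_MOST_LIMITING,
            curve_family=CurveFamily.QUADRATIC,
        )
        # salt vertex 936.0 is lower than boron vertex 1399.5
        assert y == pytest.approx(936.0, abs=0.5)


class TestSensitivity:
    def test_reference_rows(self):
        t = sensitivity_analysis().set_index("scenario")
        assert t.loc["Baseline", "yield_kg_ha"] == pytest.approx(1017.3, abs=0.1)
        assert t.loc["Baseline", "biofuel_L_ha"] == pytest.approx(178.3, abs=0.1)
        assert t.loc["EC_e + 1 SD", "yield_kg_ha"] == pytest.approx(776.2, abs=0.1)
        assert t.loc["EC_e + 1 SD", "pct_change"] == pytest.approx(-23.7, abs=0.1)
        assert t.loc["LF + 1 SD", "pct_change"] == pytest.approx(19.2, abs=0.1)
        assert t.loc["theta_g + 1 SD", "pct_change"] == pytest.approx(1.6, abs=0.1)

    def test_percent_changes_consistent_with_yield_column(self):
        t = sensitivity_analysis().set_index("scenario")
        base = t.loc["Baseline", "yield_kg_ha"]
        for scenario, row in t.iterrows():
            if scenario == "Baseline":
                continue
            expected = 100.0 * (row["yield_kg_ha"] - base) / base
            assert row["pct_change"] == pytest.approx(expected, rel=1e-12)
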