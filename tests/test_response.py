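"""Parameter recovery and screening behaviour of the fitting estimators."""

import numpy as np
import pandas as pd
import pytest

from saltyield import (
    NoDeclineDetectedError,
    SaltToleranceParams,
    SegmentUnderdeterminedError,
    SingularDesignError,
    TrialGeneratorConfig,
    TwoPieceSaltTolerance,
    UnderdeterminedError,
    YieldModelCoefficients,
    backward_select,
    fit_quadratic_tolerance,
    fit_three_piece_boron,
    fit_two_piece_salt,
    fit_yield_regression,
    generate_trial,
    relative_yield_boron,
    relative_yield_salt,
)

TRUE = YieldModelCoefficients()


class TestFullRegression:
    def test_noiseless_recovery_is_exact(self, noiseless_trial):
        result = fit_yield_regression(noiseless_trial)
        got = np.array(result.coefficients.as_tuple())
        want = np.array(TRUE.as_tuple())
        assert np.allclose(got, want, rtol=1e-6)
        assert result.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_three_standard_errors(self):
        """Across seeds, nearly all coefficient estimates land within 3 SE
        of the generating values.  (Zero-yield truncation removes part of
        the design space, so an occasional seed exceeds the nominal band;
        the check is on the ensemble, not one draw.)"""
        true = np.array(TRUE.as_tuple())
        within = []
        for seed in range(10):
            df = generate_trial(
                TrialGeneratorConfig(
                    n_sites=34, n_zero_yield=0, yield_noise_sd=100.0, seed=seed
                )
            )
            res = fit_yield_regression(df)
            z = np.abs((res.params.to_numpy() - true) / res.bse.to_numpy())
            within.extend(z <= 3.0)
        assert np.mean(within) >= 0.9

    def test_constant_regressor_raises_singular_design(self, noiseless_trial):
        df = noiseless_trial.copy()
        df["lf"] = 0.3
        with pytest.raises(SingularDesignError):
            fit_yield_regression(df)

    def test_adjusted_r2_not_above_r2(self):
        df = generate_trial(
            TrialGeneratorConfig(n_sites=34, n_zero_yield=0, yield_noise_sd=200.0, seed=9)
        )
        result = fit_yield_regression(df)
        assert result.r_squared_adj <= result.r_squared <= 1.0

    def test_estimator_error_shrinks_with_sample_size(self):
        """Consistency: average coefficient error at n=340 beats n=34."""

        def mean_abs_err(n, seed):
            df = generate_trial(
                TrialGeneratorConfig(
                    n_sites=n, n_zero_yield=0, yield_noise_sd=100.0, seed=seed
                )
            )
            res = fit_yield_regression(df)
            got = np.array(res.coefficients.as_tuple())
            want = np.array(TRUE.as_tuple())
            return np.mean(np.abs(got - want) / np.maximum(np.abs(want), 1.0))

        seeds = range(20)
        small = np.mean([mean_abs_err(34, s) for s in seeds])
        large = np.mean([mean_abs_err(340, s) for s in seeds])
        assert large < small

    def test_spatial_gls_refit_runs_and_stays_near_ols(self, noiseless_trial):
        res = fit_yield_regression(noiseless_trial, spatial_range=100.0)
        assert np.allclose(
            np.array(res.coefficients.as_tuple()), np.array(TRUE.as_tuple()), rtol=1e-5
        )


class TestBackwardSelection:
    @staticmethod
    def _with_nuisance(n, noise, seed):
        df = generate_trial(
            TrialGeneratorConfig(n_sites=n, n_zero_yield=0, yield_noise_sd=noise, seed=seed)
        )
        return df

    def test_null_nuisance_predictor_is_dropped(self):
        df = self._with_nuisance(200, 50.0, 11)
        retained, result = backward_select(
            df, candidates=["boron", "boron_sq", "ec_e", "ec_e_sq", "lf",
                            "theta_g", "ph_e"]
        )
        assert "ph_e" not in retained
        assert set(retained) >= {"boron", "boron_sq", "ec_e", "ec_e_sq", "lf", "theta_g"}

    def test_zero_threshold_retains_everything(self):
        df = self._with_nuisance(60, 100.0, 2)
        retained, _ = backward_select(
            df, candidates=["boron", "boron_sq", "ec_e", "ec_e_sq", "lf",
                            "theta_g", "ph_e", "sp"],
            t_threshold=0.0,
        )
        assert len(retained) == 8

    def test_pure_noise_response_collapses_to_intercept(self):
        df = self._with_nuisance(120, 0.0, 5)
        rng = np.random.default_rng(0)
        df["yield_kg_ha"] = rng.normal(1000.0, 10.0, len(df))  # unrelated response
        with pytest.warns(UserWarning, match="intercept-only"):
            retained, result = backward_select(df, t_threshold=1.8)
        assert retained == []
        assert result.terms == ()

    def test_never_drops_a_significant_predictor(self):
        df = self._with_nuisance(200, 50.0, 13)
        retained, result = backward_select(df, t_threshold=1.8)
        assert (result.tvalues.drop("const").abs() >= 1.8).all()


class TestTwoPieceSalt:
    def test_noiseless_recovery(self):
        ec = np.linspace(2, 14, 30)
        rel = relative_yield_salt(ec, SaltToleranceParams(8.3, 17.0))
        params, sse = fit_two_piece_salt(ec, rel)
        assert params.threshold_a == pytest.approx(8.3, abs=0.05)
        assert params.slope_b == pytest.approx(17.0, abs=1e-6)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery(self, rng):
        ec = rng.uniform(2, 14, 50)
        rel = relative_yield_salt(ec, SaltToleranceParams(8.3, 17.0))
        rel = np.clip(rel + rng.normal(0, 5, 50), 0, None)
        params, _ = fit_two_piece_salt(ec, rel)
        assert params.threshold_a == pytest.approx(8.3, abs=0.5)
        assert params.slope_b == pytest.approx(17.0, abs=2.0)

    def test_fit_beats_generating_parameters_on_noisy_data(self, rng):
        truth = SaltToleranceParams(8.3, 17.0)
        ec = rng.uniform(2, 14, 60)
        rel = np.clip(relative_yield_salt(ec, truth) + rng.normal(0, 5, 60), 0, None)
        est = TwoPieceSaltTolerance().fit(ec, rel)
        sse_truth = float(np.sum((rel - relative_yield_salt(ec, truth)) ** 2))
        assert est.sse_ <= sse_truth + 1e-9

    def test_all_plateau_raises(self):
        ec = np.linspace(1, 6, 10)
        with pytest.raises(NoDeclineDetectedError):
            fit_two_piece_salt(ec, np.full(10, 100.0))

    def test_positive_trend_raises(self):
        ec = np.linspace(1, 12, 10)
        rel = 100.0 + 2.0 * ec  # yield rising with salinity: no decline
        with pytest.raises(NoDeclineDetectedError):
            fit_two_piece_salt(ec, rel)


class TestThreePieceBoron:
    TRUTH = dict(deficiency_threshold=4.2, toxicity_threshold=8.0,
                 toxicity_slope=28.0, deficiency_slope=100 / 4.2)

    def test_noiseless_recovery(self):
        from saltyield import BoronToleranceParams

        b = np.linspace(0.5, 11.5, 45)
        rel = relative_yield_boron(b, BoronToleranceParams(**self.TRUTH))
        params, sse = fit_three_piece_boron(b, rel)
        assert params.deficiency_threshold == pytest.approx(4.2, abs=0.05)
        assert params.toxicity_threshold == pytest.approx(8.0, abs=0.05)
        assert params.toxicity_slope == pytest.approx(28.0, abs=0.5)
        assert sse == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery(self, rng):
        from saltyield import BoronToleranceParams

        b = rng.uniform(0.5, 11.5, 60)
        rel = relative_yield_boron(b, BoronToleranceParams(**self.TRUTH))
        rel = np.clip(rel + rng.normal(0, 5, 60), 0, None)
        params, _ = fit_three_piece_boron(b, rel)
        assert params.deficiency_threshold == pytest.approx(4.2, abs=0.5)
        assert params.toxicity_threshold == pytest.approx(8.0, abs=0.5)

    def test_all_points_on_plateau_raises(self):
        b = np.linspace(4.5, 7.5, 20)
        with pytest.raises(SegmentUnderdeterminedError):
            fit_three_piece_boron(b, np.full(20, 100.0))


class TestQuadraticTolerance:
    def test_three_exact_points_interpolate(self):
        x = np.array([1.0, 5.0, 10.0])
        y = 74.0 + 254.6 * x - 18.8 * x**2
        params, r2, vertex = fit_quadratic_tolerance(x, y)
        assert params.c0 == pytest.approx(74.0, abs=1e-6)
        assert params.c1 == pytest.approx(254.6, abs=1e-6)
        assert params.c2 == pytest.approx(-18.8, abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_vertex_of_boron_curve(self):
        x = np.linspace(1, 12, 10)
        y = 555.2 * x - 42.4 * x**2 - 418.0
        _, _, vertex = fit_quadratic_tolerance(x, y)
        assert vertex == pytest.approx(6.55, abs=0.005)

    def test_two_distinct_points_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            fit_quadratic_tolerance([1.0, 1.0, 2.0], [5.0, 5.0, 7.0])
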