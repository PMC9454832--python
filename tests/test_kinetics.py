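import numpy as np
import pytest

from ivgp.errors import FitError, SelectionError
from ivgp.kinetics import (
    EXPONENTIAL,
    GROOT,
    aic_least_squares,
    derive_kinetics,
    exponential_curve,
    fit_exponential,
    fit_groot,
    groot_curve,
    groot_rate,
    select_model,
)
from ivgp.synthetic_data import TrueKinetics, simulate_gas_curve


class TestModelFunctions:
    def test_half_asymptote_at_half_time(self):
        assert groot_curve(10.0, 100.0, 10.0, 2.0) == pytest.approx(50.0)

    def test_hand_evaluated_point(self):
        # 100 / (1 + (10/5)^2) = 100 / 5
        assert groot_curve(5.0, 100.0, 10.0, 2.0) == pytest.approx(20.0)

    def test_sigmoid_starts_at_zero(self):
        assert groot_curve(0.0, 100.0, 10.0, 2.0) == 0.0

    def test_exponential_starts_at_zero_and_saturates(self):
        assert exponential_curve(0.0, 100.0, 0.1) == 0.0
        assert exponential_curve(500.0, 100.0, 0.1) == pytest.approx(100.0)


class TestFitting:
    def test_noiseless_sigmoid_recovery(self, grid_10min):
        truth = (194.89, 16.92, 2.6)
        y = groot_curve(grid_10min, *truth)
        fit = fit_groot(grid_10min, y)
        assert fit.converged
        np.testing.assert_allclose(fit.params, truth, rtol=1e-4)
        assert fit.rss < 1e-10

    def test_exact_data_gives_zero_rss(self, grid_10min):
        y = groot_curve(grid_10min, 100.0, 10.0, 2.0)
        assert fit_groot(grid_10min, y).rss == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_exponential_recovery(self, grid_10min):
        y = exponential_curve(grid_10min, 180.0, 0.08)
        fit = fit_exponential(grid_10min, y)
        assert fit.converged
        np.testing.assert_allclose(fit.params, (180.0, 0.08), rtol=1e-4)

    def test_noisy_asymptote_unbiased(self, grid_10min):
        estimates = [
            fit_groot(
                grid_10min,
                simulate_gas_curve(
                    TrueKinetics(GROOT, 194.89, 16.92, 2.6), grid_10min, 5.0, seed=s
                ).values,
            ).params[0]
            for s in range(30)
        ]
        assert np.mean(estimates) == pytest.approx(194.89, rel=0.02)

    def test_all_zero_response_is_fit_error(self, grid_10min):
        with pytest.raises(FitError, match="degenerate"):
            fit_groot(grid_10min, np.zeros_like(grid_10min))

    def test_constant_response_flagged_not_raised(self, grid_10min):
        fit = fit_exponential(grid_10min, np.full_like(grid_10min, 50.0))
        assert not fit.converged
        assert fit.message

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_groot([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSelection:
    @pytest.mark.parametrize("generator,expected", [
        (TrueKinetics(GROOT, 180.0, 15.0, 2.5), GROOT),
        (TrueKinetics(EXPONENTIAL, b_ml_per_g=180.0, c_per_h=0.08), EXPONENTIAL),
    ])
    def test_least_aic_identifies_generating_family(self, grid_10min, generator,
                                                    expected):
        hits = 0
        for s in range(20):
            curve = simulate_gas_curve(generator, grid_10min, 3.0, seed=s)
            fits = [fit_groot(grid_10min, curve.values),
                    fit_exponential(grid_10min, curve.values)]
            hits += select_model(fits).family == expected
        assert hits >= 19

    def test_single_fit_returned_unchanged(self, grid_10min):
        fit = fit_groot(grid_10min, groot_curve(grid_10min, 100.0, 10.0, 2.0))
        assert select_model([fit]) is fit

    def test_no_converged_fit_is_selection_error(self, grid_10min):
        bad = fit_exponential(grid_10min, np.full_like(grid_10min, 3.0))
        with pytest.raises(SelectionError):
            select_model([bad])

    def test_aic_ordering_stable_under_duplicated_points(self, grid_10min):
        # appending the same block of observations to both candidates
        # shifts both AICs but cannot flip their order
        curve = simulate_gas_curve(
            TrueKinetics(GROOT, 180.0, 15.0, 2.5), grid_10min, 3.0, seed=0
        )
        f1 = [fit_groot(grid_10min, curve.values),
              fit_exponential(grid_10min, curve.values)]
        t2 = np.concatenate([grid_10min, grid_10min + 48.0 + 1 / 6])
        y2 = np.concatenate([curve.values, curve.values])
        f2 = [fit_groot(t2, y2), fit_exponential(t2, y2)]
        order1 = f1[0].aic < f1[1].aic
        order2 = f2[0].aic < f2[1].aic
        assert order1 == order2

    def test_aic_formula(self):
        # n·ln(rss/n) + 2k with k = params + variance
        assert aic_least_squares(10.0, 100, 3) == pytest.approx(
            100 * np.log(0.1) + 8
        )


class TestDerivedKinetics:
    def test_sigmoid_closed_forms(self):
        fit = fit_groot(np.linspace(0.1, 48, 200),
                        groot_curve(np.linspace(0.1, 48, 200), 100.0, 10.0, 2.0))
        d = derive_kinetics(fit)
        assert d.Tmax_min == pytest.approx(10.0 * np.sqrt(1 / 3) * 60.0, rel=1e-6)
        assert d.Tmax_min == pytest.approx(346.41, abs=0.01)
        assert d.Vmax_ml_per_g_h == pytest.approx(6.495, abs=0.001)

    def test_tmax_vmax_match_numerical_derivative_on_1min_grid(self):
        A, B, C = 194.89, 16.92, 2.6
        d = derive_kinetics(
            fit_groot(np.linspace(0.1, 48, 300),
                      groot_curve(np.linspace(0.1, 48, 300), A, B, C))
        )
        t = np.arange(0.0, 48.0, 1.0 / 60.0)  # 1-min grid, hours
        y = groot_curve(t, A, B, C)
        rate = np.gradient(y, t)
        t_argmax_min = t[np.argmax(rate)] * 60.0
        assert abs(d.Tmax_min - t_argmax_min) <= 1.0
        assert d.Vmax_ml_per_g_h == pytest.approx(rate.max(), rel=1e-3)

    def test_curve_at_h1_is_half_of_a1_both_families(self, grid_10min):
        gfit = fit_groot(grid_10min, groot_curve(grid_10min, 150.0, 12.0, 2.2))
        gd = derive_kinetics(gfit)
        assert gfit.predict(gd.H1_h) == pytest.approx(gd.A1_ml_per_g / 2, abs=1e-9)
        efit = fit_exponential(grid_10min,
                               exponential_curve(grid_10min, 100.0, 0.1))
        ed = derive_kinetics(efit)
        assert efit.predict(ed.H1_h) == pytest.approx(ed.A1_ml_per_g / 2, abs=1e-9)

    def test_exponential_closed_forms(self, grid_10min):
        fit = fit_exponential(grid_10min,
                              exponential_curve(grid_10min, 100.0, 0.1))
        d = derive_kinetics(fit)
        assert d.H1_h == pytest.approx(np.log(2) / 0.1, rel=1e-6)
        assert d.H1_h == pytest.approx(6.9315, abs=1e-3)
        assert d.Vmax_ml_per_g_h == pytest.approx(10.0, rel=1e-6)
        assert d.Tmax_min == 0.0

    def test_shallow_sigmoid_reports_initial_rate(self, grid_10min):
        # C <= 1: monotone decreasing rate, Tmax pinned to 0
        y = groot_curve(grid_10min, 80.0, 5.0, 0.9)
        fit = fit_groot(grid_10min, y)
        d = derive_kinetics(fit, first_time_h=1 / 6)
        assert d.Tmax_min == 0.0
        assert d.Vmax_ml_per_g_h == pytest.approx(
            groot_rate(1 / 6, *fit.params), rel=1e-9
        )

    def test_per_minute_display_unit(self):
        fit = fit_groot(np.linspace(0.1, 48, 100),
                        groot_curve(np.linspace(0.1, 48, 100), 100.0, 10.0, 2.0))
        d = derive_kinetics(fit)
        assert d.Vmax_ml_per_g_min == pytest.approx(d.Vmax_ml_per_g_h / 60.0)

    @pytest.mark.parametrize("noise_sd", [0.0, 1.0, 5.0])
    def test_recovery_bias_shrinks_with_noise(self, grid_10min, noise_sd):
        truth = TrueKinetics(GROOT, 194.89, 16.92, 2.6)
        est = np.mean([
            fit_groot(grid_10min,
                      simulate_gas_curve(truth, grid_10min, noise_sd, seed=s).values
                      ).params[0]
            for s in range(15)
        ])
        tol = 1e-6 if noise_sd == 0 else 0.02
        assert est == pytest.approx(194.89, rel=tol)
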