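"""Exchange-rate fitting: ratio construction, recovery, detailed balance."""

import itertools

import numpy as np
import pytest

from prolylnmr import (
    ExchangeParameters,
    IntensityCurve,
    TocsyMeasurement,
    build_ratio_curves,
    detailed_balance_check,
    fit_exchange,
    predict_intensities,
    predict_ratios,
    tocsy_population_ratio,
)
from prolylnmr.roesy import estimate_initial_rates, predict_ratio_model
from prolylnmr.synth import PS110_MIXING_TIMES_MS, S110E_MIXING_TIMES_MS

from conftest import PS110_RATES, S110E_RATES


class TestBuildRatioCurves:
    def test_roundtrip_matches_predict_ratios(self, ps110_params):
        t = np.array(PS110_MIXING_TIMES_MS) / 1e3
        curve = predict_intensities(ps110_params, t)
        built = build_ratio_curves(curve)
        direct = predict_ratios(ps110_params, t)
        np.testing.assert_allclose(built.r_ct, direct.r_ct, rtol=1e-12)
        np.testing.assert_allclose(built.r_tc, direct.r_tc, rtol=1e-12)

    def test_zero_cross_peaks_give_zero_ratios(self):
        t = np.array([0.0, 0.01, 0.02, 0.04])
        curve = IntensityCurve(mixing_times=t, I_cc=np.ones(4), I_tt=np.ones(4),
                               I_ct=np.zeros(4), I_tc=np.zeros(4))
        r = build_ratio_curves(curve)
        assert np.all(r.r_ct == 0) and np.all(r.r_tc == 0)

    def test_underflowing_diagonal_dropped_with_warning(self, ps110_params):
        t = np.array(PS110_MIXING_TIMES_MS) / 1e3
        curve = predict_intensities(ps110_params, t)
        curve.I_cc[5] = 1e-300
        r = build_ratio_curves(curve)
        assert r.mixing_times.size == t.size - 1
        assert any("dropped" in w for w in r.warnings)

    def test_insufficient_points_error(self):
        t = np.array([0.0, 0.01, 0.02])
        curve = IntensityCurve(mixing_times=t, I_cc=np.ones(3), I_tt=np.ones(3),
                               I_ct=np.zeros(3), I_tc=np.zeros(3))
        with pytest.raises(ValueError, match="insufficient"):
            build_ratio_curves(curve)

    def test_propagated_sigmas_positive_and_growing(self, ps110_params):
        # diagonals decay, so relative ratio noise must grow with t_m
        t = np.array(PS110_MIXING_TIMES_MS) / 1e3
        curve = predict_intensities(ps110_params, t)
        r = build_ratio_curves(curve, intensity_noise_sd=0.01)
        assert np.all(r.sigma_ct > 0) and np.all(r.sigma_tc > 0)
        assert r.sigma_ct[-1] > r.sigma_ct[1]


class TestInitialRates:
    def test_short_time_slope_near_true_rate(self, ps110_params):
        r = predict_ratios(ps110_params, np.array(PS110_MIXING_TIMES_MS) / 1e3)
        k_ct0, k_tc0, dR0, _ = estimate_initial_rates(r)
        assert abs(k_ct0 - 26.5) / 26.5 < 0.30
        assert dR0 == 0.0

    def test_flat_ratios_fall_back_with_warning(self):
        from prolylnmr.exchange import RatioCurve
        r = RatioCurve(mixing_times=np.array([0.0, 0.01, 0.02, 0.04]),
                       r_ct=np.zeros(4), r_tc=np.zeros(4))
        k_ct0, k_tc0, _, warnings = estimate_initial_rates(r)
        assert k_ct0 == 1.0 and k_tc0 == 1.0
        assert len(warnings) == 2

    def test_time_scaling_halves_slopes(self, ps110_params):
        t = np.array(PS110_MIXING_TIMES_MS) / 1e3
        r = predict_ratios(ps110_params, t)
        from prolylnmr.exchange import RatioCurve
        r2 = RatioCurve(mixing_times=2 * t, r_ct=r.r_ct, r_tc=r.r_tc)
        a = estimate_initial_rates(r)
        b = estimate_initial_rates(r2)
        assert b[0] == pytest.approx(a[0] / 2, rel=1e-12)
        assert b[1] == pytest.approx(a[1] / 2, rel=1e-12)


class TestFitExchange:
    @pytest.mark.parametrize("rates,grid", [
        (PS110_RATES, PS110_MIXING_TIMES_MS),
        (S110E_RATES, S110E_MIXING_TIMES_MS)])
    def test_noiseless_roundtrip_recovery(self, roesy_curve_factory, rates, grid):
        curve, _ = roesy_curve_factory(rates["k_ct"], rates["k_tc"], grid=grid)
        fit = fit_exchange(build_ratio_curves(curve), seed=0)
        assert fit.converged
        assert fit.k_ct == pytest.approx(rates["k_ct"], rel=1e-6)
        assert fit.k_tc == pytest.approx(rates["k_tc"], rel=1e-6)
        assert abs(fit.delta_R2) < 1e-6
        assert fit.k_ex == fit.k_ct + fit.k_tc  # exact by construction

    def test_noiseless_grid_recovery(self, roesy_curve_factory):
        for k_ct, k_tc, dR2 in itertools.product([0.5, 5, 25], [0.1, 1, 5], [-5, 0, 5]):
            curve, _ = roesy_curve_factory(k_ct, k_tc, R2_c=max(dR2, 0) + 2,
                                           R2_t=max(-dR2, 0) + 2)
            fit = fit_exchange(build_ratio_curves(curve), seed=0)
            assert fit.k_ct == pytest.approx(k_ct, rel=1e-5)
            assert fit.k_tc == pytest.approx(k_tc, rel=1e-5)
            assert fit.delta_R2 == pytest.approx(dR2, rel=1e-5, abs=1e-5)

    def test_objective_no_worse_than_truth(self, roesy_curve_factory):
        curve, _ = roesy_curve_factory(26.5, 2.48)
        ratios = build_ratio_curves(curve)
        fit = fit_exchange(ratios, seed=0)
        r_ct, r_tc = predict_ratio_model(26.5, 2.48, 0.0, ratios.mixing_times)
        rss_truth = float(np.sum((r_ct - ratios.r_ct) ** 2) + np.sum((r_tc - ratios.r_tc) ** 2))
        assert fit.rss <= rss_truth + 1e-9

    def test_noise_error_decreases_with_noise_level(self, roesy_curve_factory):
        medians = []
        for sd in (0.05, 0.02, 0.005):
            errs = []
            for seed in range(20):
                curve, _ = roesy_curve_factory(26.5, 2.48, noise=sd, seed=seed)
                fit = fit_exchange(build_ratio_curves(curve, intensity_noise_sd=sd),
                                   seed=seed)
                errs.append(abs(fit.k_ex - 28.98) / 28.98)
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_constrained_fit_matches_unconstrained_when_consistent(self, roesy_curve_factory):
        curve, _ = roesy_curve_factory(26.5, 2.48)
        ratios = build_ratio_curves(curve)
        tocsy = TocsyMeasurement(I_trans=26.5 / 2.48, I_cis=1.0)
        free = fit_exchange(ratios, seed=0)
        con = fit_exchange(ratios, tocsy=tocsy, use_constraint=True, seed=0)
        assert con.constrained
        assert con.k_ct == pytest.approx(free.k_ct, rel=1e-6)
        assert con.k_tc == pytest.approx(free.k_tc, rel=1e-6)
        assert con.K_isom_rates == pytest.approx(26.5 / 2.48, rel=1e-12)

    def test_constraint_requires_tocsy(self, roesy_curve_factory):
        curve, _ = roesy_curve_factory(26.5, 2.48)
        with pytest.raises(ValueError):
            fit_exchange(build_ratio_curves(curve), use_constraint=True)

    def test_standard_errors_reported(self, roesy_curve_factory):
        curve, _ = roesy_curve_factory(26.5, 2.48, noise=0.01, seed=3)
        fit = fit_exchange(build_ratio_curves(curve, intensity_noise_sd=0.01), seed=3)
        assert set(fit.standard_errors) == {"k_ct", "k_tc", "delta_R2"}
        assert all(v is None or v > 0 for v in fit.standard_errors.values())


class TestTocsyAndDetailedBalance:
    @pytest.mark.parametrize("I_trans,I_cis,expected", [
        (10.7, 1.0, 10.7), (5.0, 5.0, 1.0), (74.9, 7.0, 10.7)])
    def test_population_ratio(self, I_trans, I_cis, expected):
        assert tocsy_population_ratio(TocsyMeasurement(I_trans, I_cis)) == pytest.approx(expected)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            TocsyMeasurement(I_trans=0.0, I_cis=1.0)

    @pytest.mark.parametrize("ratio,tocsy,disc,ok", [
        (10.685, 10.7, 0.0014, True),
        (6.64, 6.87, 0.034, True),
        (5.0, 10.0, 0.5, False)])
    def test_discrepancy_report(self, ratio, tocsy, disc, ok, roesy_curve_factory):
        curve, _ = roesy_curve_factory(ratio, 1.0)
        fit = fit_exchange(build_ratio_curves(curve), seed=0)
        rep = detailed_balance_check(fit, TocsyMeasurement(I_trans=tocsy, I_cis=1.0))
        assert rep["relative_discrepancy"] == pytest.approx(disc, abs=2e-3)
        assert rep["pass"] is ok

    def test_equal_values_pass_exactly(self, roesy_curve_factory):
        curve, _ = roesy_curve_factory(8.0, 1.0)
        fit = fit_exchange(build_ratio_curves(curve), seed=0)
        rep = detailed_balance_check(fit, TocsyMeasurement(I_trans=fit.K_isom_rates, I_cis=1.0))
        assert rep["relative_discrepancy"] == pytest.approx(0.0, abs=1e-12)
        assert rep["pass"]
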