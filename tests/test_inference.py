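"""Estimators: inversion of the forward models and error paths."""

import math
import warnings

import numpy as np
import pytest

import radioswitch as rs
from radioswitch.errors import (
    DataError,
    DataOrderingError,
    DomainError,
    InsufficientDataError,
)
from radioswitch.synthetic import AssayNoiseModel, ZERO_NOISE


def make_fraction_series(doses, trans_irr, trans_ctrl=None, trans0=0.10):
    doses = np.asarray(doses, dtype=float)
    return rs.DoseResponseSeries(
        doses_Gy=doses,
        irradiated_values=np.asarray(trans_irr, dtype=float),
        control_values=None if trans_ctrl is None else np.asarray(trans_ctrl, float),
        timestamps_h=np.arange(doses.size) * 0.25,
        readout="trans_fraction",
        trans0=trans0,
    )


class TestFitActivationConstant:
    def test_noiseless_recovery_is_exact(self, params, gr):
        series = rs.gen_dose_response(
            params, gr, doses_Gy=[0, 0.5, 1.0, 1.5, 2.0], noise=ZERO_NOISE
        )
        fit = rs.fit_activation_constant(series)
        assert fit.k_per_Gy == pytest.approx(0.21, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.thermal_corrected

    def test_noiseless_without_control_and_without_lag(self, params, gr):
        # with no dark time at all, the uncorrected fit is also exact
        series = rs.gen_dose_response(
            params,
            gr,
            doses_Gy=[0, 0.5, 1.0, 1.5, 2.0],
            noise=ZERO_NOISE,
            lag_h=0.0,
            interval_h=0.0,
        )
        fit = rs.fit_activation_constant(series, thermal_correction=False)
        assert fit.k_per_Gy == pytest.approx(0.21, rel=1e-9)

    def test_correction_removes_thermal_drift_for_any_schedule(self, params, gr):
        # long inter-measurement gaps inflate the uncorrected slope; the
        # paired log-space correction undoes them exactly
        series = rs.gen_dose_response(
            params,
            gr,
            doses_Gy=[0, 0.5, 1.0, 1.5, 2.0],
            noise=ZERO_NOISE,
            lag_h=2.0,
            interval_h=1.0,
        )
        uncorrected = rs.fit_activation_constant(series, thermal_correction=False)
        corrected = rs.fit_activation_constant(series, thermal_correction=True)
        assert uncorrected.k_per_Gy > 0.25
        assert corrected.k_per_Gy == pytest.approx(0.21, rel=1e-9)

    def test_seeded_noisy_series_lands_in_printed_band(self, params, gr):
        noise = AssayNoiseModel(fraction_sigma=0.018, seed=11)
        series = rs.gen_dose_response(
            params, gr, doses_Gy=[0, 0.5, 1.0, 1.5, 2.0], noise=noise
        )
        fit = rs.fit_activation_constant(series)
        assert fit.k_per_Gy == pytest.approx(0.21, abs=0.02)
        assert fit.k_stderr > 0

    def test_absorbance_readout_equivalent_to_fractions(self, params, gr):
        series = rs.gen_dose_response(
            params,
            gr,
            doses_Gy=[0, 0.5, 1.0, 1.5, 2.0],
            readout="absorbance_367nm",
            noise=ZERO_NOISE,
        )
        fit = rs.fit_activation_constant(series)
        assert fit.k_per_Gy == pytest.approx(0.21, rel=1e-6)

    def test_single_dose_point_insufficient(self):
        series = make_fraction_series([0.0, 1.0], [0.10, 0.27], [0.10, 0.11])
        with pytest.raises(InsufficientDataError):
            rs.fit_activation_constant(series)

    def test_out_of_interval_readout_names_the_dose(self):
        series = make_fraction_series(
            [0.0, 0.5, 1.0, 2.0], [0.10, 0.19, 0.05, 0.41]
        )
        with pytest.raises(DataOrderingError, match="1.0"):
            rs.fit_activation_constant(series, thermal_correction=False)


class TestFitGValue:
    def test_hand_constructed_anchor(self):
        # irradiated Δtrans = 18 µM, control Δtrans = 1.2 µM on a 50 µM pool
        # at 2 Gy → (18 − 1.2)/2 = 8.4 µmol/J ≡ G ≈ 81
        series = make_fraction_series(
            [0.0, 2.0],
            [0.10, 0.10 + 18.0 / 50.0],
            [0.10, 0.10 + 1.2 / 50.0],
        )
        res = rs.fit_g_value(series, initial_cis_uM=45.0, dose_Gy=2.0)
        assert res.g.value_umol_per_J == pytest.approx(8.4, rel=1e-9)
        assert res.g.value_per_100eV == pytest.approx(81.05, abs=0.1)
        assert res.corrected_for_thermal

    def test_zero_increment_gives_zero(self):
        series = make_fraction_series([0.0, 2.0], [0.10, 0.10], [0.10, 0.10])
        res = rs.fit_g_value(series, 45.0, 2.0)
        assert res.g.value_umol_per_J == 0.0

    def test_pure_thermal_drift_is_cancelled(self):
        series = make_fraction_series([0.0, 2.0], [0.10, 0.22], [0.10, 0.22])
        res = rs.fit_g_value(series, 45.0, 2.0)
        assert res.g.value_umol_per_J == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("drift", [0.0, 0.03, 0.08])
    def test_invariant_to_common_drift_on_both_plates(self, drift):
        series = make_fraction_series(
            [0.0, 2.0],
            [0.10, 0.46 + drift],
            [0.10, 0.10 + drift],
        )
        res = rs.fit_g_value(series, 45.0, 2.0)
        assert res.g.value_umol_per_J == pytest.approx(9.0, rel=1e-9)

    def test_model_based_fallback_is_flagged(self, params):
        series = make_fraction_series([0.0, 2.0], [0.10, 0.46])
        res = rs.fit_g_value(series, 45.0, 2.0, params=params)
        assert res.correction_method == "model-based"

    def test_negative_corrected_increment_warns(self):
        series = make_fraction_series([0.0, 2.0], [0.10, 0.12], [0.10, 0.20])
        with pytest.warns(UserWarning, match="negative"):
            res = rs.fit_g_value(series, 45.0, 2.0)
        assert res.g.value_umol_per_J == 0.0


class TestFitGHO:
    def test_noiseless_slope_recovers_water_yield(self):
        # G(7-OH-Coum) = 0.031 × 0.280 = 8.68e-3 µM/Gy
        doses = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 40.0])
        conc = 8.68e-3 * doses
        assay = rs.CoumarinAssayData(
            doses_Gy=doses,
            fluorescence_au=1500.0 * conc + 30.0,
            standard_curve=(1500.0, 30.0),
        )
        g = rs.fit_g_ho(assay)
        assert g.value_umol_per_J == pytest.approx(0.280, rel=1e-3)

    def test_blank_fluorescence_gives_zero_with_warning(self):
        doses = np.array([0.0, 5.0, 10.0, 20.0])
        assay = rs.CoumarinAssayData(
            doses_Gy=doses,
            fluorescence_au=np.full(4, 30.0),
            standard_curve=(1500.0, 30.0),
        )
        with pytest.warns(UserWarning, match="non-positive"):
            assert rs.fit_g_ho(assay).value_umol_per_J == 0.0

    def test_doubling_assumed_conversion_yield_halves_g(self, gr):
        # same fluorescence data, reinterpreted with a doubled probe yield
        a1 = rs.gen_coumarin_assay(gr, conversion_yield=0.031)
        a2 = rs.CoumarinAssayData(
            doses_Gy=a1.doses_Gy,
            fluorescence_au=a1.fluorescence_au,
            standard_curve=a1.standard_curve,
            conversion_yield=0.062,
        )
        assert rs.fit_g_ho(a2).value_umol_per_J == pytest.approx(
            rs.fit_g_ho(a1).value_umol_per_J / 2.0, rel=1e-9
        )

    def test_too_few_points_rejected(self):
        assay = rs.CoumarinAssayData(
            doses_Gy=np.array([0.0, 5.0]),
            fluorescence_au=np.array([30.0, 95.0]),
            standard_curve=(1500.0, 30.0),
        )
        with pytest.raises(InsufficientDataError):
            rs.fit_g_ho(assay)


class TestEnhancementProfile:
    def test_flat_table_has_zero_enhancement(self):
        table = {0.0: 0.28, 100.0: 0.28, 500.0: 0.28}
        profile, (_, e_max) = rs.enhancement_profile(table)
        assert all(v == pytest.approx(0.0) for v in profile.values())
        assert e_max == pytest.approx(0.0)

    def test_gr_printed_maximum(self):
        profile, (c_max, e_max) = rs.enhancement_profile({0.0: 0.280, 500.0: 0.336})
        assert c_max == 500.0
        assert e_max == pytest.approx(0.20, rel=1e-9)

    def test_xr_printed_maximum(self):
        _, (c_max, e_max) = rs.enhancement_profile({0.0: 0.200, 200.0: 0.266})
        assert c_max == 200.0
        assert e_max == pytest.approx(0.33, rel=1e-9)

    def test_missing_baseline_rejected(self):
        with pytest.raises(DataError, match="baseline"):
            rs.enhancement_profile({100.0: 0.3, 500.0: 0.33})


class TestFitThermalHalfLife:
    def test_noiseless_recovery_is_exact(self, params):
        course = rs.gen_relaxation_course(params, noise=ZERO_NOISE)
        fit = rs.fit_thermal_half_life(course)
        assert fit.half_life_h == pytest.approx(2.3, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_seeded_noisy_course_within_ten_percent(self, params):
        course = rs.gen_relaxation_course(
            params, noise=AssayNoiseModel(fraction_sigma=0.01, seed=3)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rs.fit_thermal_half_life(course)
        assert fit.half_life_h == pytest.approx(2.3, rel=0.10)

    def test_saturated_points_filtered_with_warning(self, params):
        times = np.linspace(0, 30, 10)
        trans = 1.0 - 0.9 * np.exp(-params.thermal_rate_per_h * times)
        trans[-2:] = 1.0  # detector saturation
        with pytest.warns(UserWarning, match="saturated"):
            fit = rs.fit_thermal_half_life(times, trans)
        assert fit.half_life_h == pytest.approx(2.3, rel=1e-6)

    def test_constant_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            rs.fit_thermal_half_life(np.arange(6.0), np.full(6, 0.4))


class TestFitEfficiencyModel:
    def test_noiseless_exact_recovery(self):
        Y = {d: -0.036 * math.log(d) + 0.1304 for d in (2.0, 5.0, 10.0, 20.0)}
        fit = rs.fit_efficiency_model(Y)
        assert fit.a == pytest.approx(-0.036, rel=1e-12)
        assert fit.b == pytest.approx(0.1304, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_seeded_noisy_intercept_within_five_percent(self, rng):
        doses = (2.0, 5.0, 10.0, 20.0)
        Y = {
            d: -0.036 * math.log(d) + 0.1304 + 0.002 * rng.standard_normal()
            for d in doses
        }
        fit = rs.fit_efficiency_model(Y)
        assert fit.b == pytest.approx(0.1304, rel=0.05)

    def test_two_doses_insufficient(self):
        with pytest.raises(InsufficientDataError):
            rs.fit_efficiency_model({2.0: 0.1, 5.0: 0.07})

    def test_non_positive_dose_rejected(self):
        with pytest.raises(DomainError):
            rs.fit_efficiency_model({0.0: 0.13, 2.0: 0.1, 5.0: 0.07})


class TestEstimatorBias:
    """Bias of each estimator on fixed-seed noisy ensembles is within 2 MC SE."""

    def test_activation_constant_bias(self, params, gr):
        ks = []
        for seed in range(200):
            series = rs.gen_dose_response(
                params,
                gr,
                doses_Gy=[0, 0.5, 1.0, 1.5, 2.0],
                noise=AssayNoiseModel(fraction_sigma=0.018, seed=seed),
            )
            ks.append(rs.fit_activation_constant(series).k_per_Gy)
        ks = np.array(ks)
        se = ks.std(ddof=1) / np.sqrt(ks.size)
        assert abs(ks.mean() - 0.21) < 2 * se

    def test_half_life_bias(self, params):
        estimates = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(200):
                course = rs.gen_relaxation_course(
                    params, noise=AssayNoiseModel(fraction_sigma=0.01, seed=seed)
                )
                estimates.append(rs.fit_thermal_half_life(course).half_life_h)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - 2.3) < 2 * se
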