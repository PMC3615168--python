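import math

import numpy as np
import pytest

from gutsurv import (ExposureProfile, ITParams, SDParams, constant_profile,
                     predict, rectangular_pulse, scaled_internal_concentration,
                     survival_it, survival_sd)

from _oracles import (brute_force_internal, brute_force_survival,
                      random_it_params, random_sd_params, random_step_profile)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(ke=0.0, kk=1.0, z=1.0), dict(ke=-1.0, kk=1.0, z=1.0),
        dict(ke=1.0, kk=-0.1, z=1.0), dict(ke=1.0, kk=1.0, z=-0.1),
        dict(ke=1.0, kk=1.0, z=1.0, h_controls=-0.01),
        dict(ke=np.nan, kk=1.0, z=1.0),
    ])
    def test_sd_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SDParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        dict(ke=1.0, alpha=0.0, beta=1.0), dict(ke=1.0, alpha=1.0, beta=0.0),
        dict(ke=0.0, alpha=1.0, beta=1.0),
    ])
    def test_it_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ITParams(**kwargs)

    def test_model_param_type_mismatch(self):
        pulse = rectangular_pulse(1.0)
        grid = np.array([0.0, 1.0])
        with pytest.raises(TypeError):
            survival_sd(pulse, ITParams(ke=1.0, alpha=1.0, beta=2.0), grid)
        with pytest.raises(TypeError):
            survival_it(pulse, SDParams(ke=1.0, kk=1.0, z=1.0), grid)


class TestInternalConcentration:
    def test_constant_exposure_closed_form(self):
        grid = np.linspace(0.0, 6.0, 25)
        ci = scaled_internal_concentration(constant_profile(2.5, 6.0), 0.8, grid)
        np.testing.assert_allclose(ci, 2.5 * (1.0 - np.exp(-0.8 * grid)),
                                   atol=1e-12)

    def test_depuration_after_pulse(self):
        # 1-d unit pulse, ke = 1: Ci(1) = 1 - e^-1, then pure decay
        pulse = rectangular_pulse(1.0, duration=1.0)
        grid = np.array([0.0, 1.0, 2.5, 4.0])
        ci = scaled_internal_concentration(pulse, 1.0, grid)
        peak = 1.0 - math.exp(-1.0)
        assert ci[1] == pytest.approx(peak, abs=1e-12)
        np.testing.assert_allclose(ci[2:], peak * np.exp(-(grid[2:] - 1.0)),
                                   atol=1e-12)

    def test_pulse_against_fine_step_euler(self):
        pulse = rectangular_pulse(1.0, duration=1.0)
        grid_bf, ci_bf = brute_force_internal(pulse, 1.0, 4.0, dt=1e-4)
        ci = scaled_internal_concentration(pulse, 1.0, grid_bf[::4000])
        np.testing.assert_allclose(ci[1:], ci_bf[::4000][1:], rtol=1e-3)

    def test_dose_metric_linear_in_factor(self, rng):
        p = random_step_profile(rng)
        grid = np.linspace(0.0, 14.0, 57)
        base = scaled_internal_concentration(p, 0.7, grid)
        scaled = scaled_internal_concentration(p.scaled(3.3), 0.7, grid)
        np.testing.assert_allclose(scaled, 3.3 * base, rtol=1e-12, atol=1e-15)

    def test_bounded_by_max_concentration(self, rng):
        p = random_step_profile(rng, cmax=2.0)
        ci = scaled_internal_concentration(p, 1.2, np.linspace(0, 15, 100))
        assert np.all(ci >= 0.0)
        assert np.all(ci <= 2.0 + 1e-12)

    def test_invalid_inputs(self):
        p = constant_profile(1.0, 2.0)
        with pytest.raises(ValueError):
            scaled_internal_concentration(p, -1.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            scaled_internal_concentration(p, 1.0, np.array([1.0, 0.5]))


class TestStochasticDeath:
    def test_no_mortality_below_threshold(self):
        params = SDParams(ke=1.0, kk=2.0, z=5.0)
        res = survival_sd(constant_profile(3.0, 10.0), params,
                          np.linspace(0, 10, 11))
        np.testing.assert_array_equal(res.survival, 1.0)

    def test_constant_exceedance_hazard(self):
        # Ci pinned at z + 1 for 1 d (ke huge -> instant equilibration)
        params = SDParams(ke=5e3, kk=0.5, z=2.0)
        res = survival_sd(constant_profile(3.0, 1.0), params,
                          np.array([0.0, 1.0]))
        assert res.survival[-1] == pytest.approx(math.exp(-0.5), rel=1e-3)

    def test_survival_one_at_start_and_monotone(self, rng):
        for _ in range(5):
            p = random_step_profile(rng)
            res = survival_sd(p, random_sd_params(rng), np.linspace(0, 14, 30))
            assert res.survival[0] == 1.0
            assert np.all(np.diff(res.survival) <= 1e-12)
            assert np.all((0.0 <= res.survival) & (res.survival <= 1.0))
            assert np.all(np.diff(res.cumulative_hazard) >= -1e-12)

    def test_crossing_times_in_output(self):
        # 2-d pulse crossing z on the way up and after the pulse
        params = SDParams(ke=1.0, kk=0.3, z=0.5)
        res = survival_sd(rectangular_pulse(1.0, duration=2.0), params,
                          np.array([0.0, 2.0, 8.0]))
        at_z = np.isclose(res.internal, params.z, atol=1e-9)
        assert at_z.sum() >= 2  # up- and down-crossing both recorded


class TestIndividualTolerance:
    def test_median_threshold_gives_half(self):
        params = ITParams(ke=1.0, alpha=1.0 - math.exp(-1.0), beta=3.0)
        res = survival_it(rectangular_pulse(1.0, duration=1.0), params,
                          np.array([0.0, 1.0, 5.0]))
        assert res.threshold_cdf[-1] == pytest.approx(0.5, abs=1e-12)
        assert res.survival[-1] == pytest.approx(0.5, abs=1e-12)

    def test_repeat_pulse_kills_nobody(self):
        # separation long enough for elimination to complete to machine precision
        params = ITParams(ke=1.0, alpha=0.4, beta=4.0)
        times = np.array([0.0, 1.0, 45.0, 46.0])
        conc = np.array([1.0, 0.0, 1.0, 0.0])
        profile = ExposureProfile(times, conc)
        res = survival_it(profile, params, np.linspace(0, 90, 181))
        s_after_first = res.at(44.0)
        assert res.survival[-1] == pytest.approx(s_after_first, abs=1e-12)

    def test_large_beta_step_limit(self):
        low = ITParams(ke=1e3, alpha=1.0, beta=500.0)
        grid = np.array([0.0, 5.0])
        s_below = survival_it(constant_profile(0.9, 5.0), low, grid).survival[-1]
        s_above = survival_it(constant_profile(1.1, 5.0), low, grid).survival[-1]
        assert s_below == pytest.approx(1.0, abs=1e-6)
        assert s_above == pytest.approx(0.0, abs=1e-6)

    def test_zero_running_max_is_not_an_error(self):
        params = ITParams(ke=1.0, alpha=1.0, beta=2.0)
        zero = ExposureProfile(np.array([0.0, 5.0]), np.array([0.0, 0.0]))
        res = survival_it(zero, params, np.array([0.0, 5.0]))
        np.testing.assert_array_equal(res.threshold_cdf, 0.0)
        np.testing.assert_array_equal(res.survival, 1.0)

    def test_peak_not_missed_by_coarse_grid(self):
        # pulse lives entirely between two grid points
        params = ITParams(ke=2.0, alpha=0.1, beta=8.0)
        profile = ExposureProfile(np.array([0.4, 0.6, 0.61]),
                                  np.array([5.0, 0.0, 0.0]))
        res = survival_it(profile, params, np.array([0.0, 10.0]))
        assert res.survival[-1] < 0.01


class TestPredictDispatcher:
    def test_background_only_closed_form(self):
        zero = ExposureProfile(np.array([0.0, 96.0]), np.array([0.0, 0.0]))
        params = SDParams(ke=1.0, kk=1.0, z=1.0, h_controls=0.018)
        res = predict(zero, params, horizon=96.0)
        assert res.survival[-1] == pytest.approx(math.exp(-0.018 * 96.0),
                                                 rel=1e-12)

    def test_zero_profile_zero_background(self):
        zero = ExposureProfile(np.array([0.0, 50.0]), np.array([0.0, 0.0]))
        for params in (SDParams(ke=1.0, kk=1.0, z=1.0),
                       ITParams(ke=1.0, alpha=1.0, beta=2.0)):
            res = predict(zero, params, horizon=50.0)
            np.testing.assert_array_equal(res.survival, 1.0)

    def test_long_profile_far_below_threshold_full_survival(self):
        rng = np.random.default_rng(5)
        times = np.arange(0.0, 486.0, 1.0)
        conc = rng.uniform(0.0, 0.2, times.size)  # far below z and alpha
        profile = ExposureProfile(times, conc)
        sd = predict(profile, SDParams(ke=1.0, kk=1.42, z=4.06), horizon=485.0)
        it = predict(profile, ITParams(ke=0.47, alpha=3.63, beta=10.52),
                     horizon=485.0)
        assert sd.survival[-1] == 1.0
        assert it.survival[-1] > 0.999999

    def test_output_contains_profile_breakpoints(self):
        profile = ExposureProfile(np.array([0.0, 0.35, 0.7, 3.1]),
                                  np.array([1.0, 0.0, 2.0, 0.0]))
        res = predict(profile, SDParams(ke=1.0, kk=0.1, z=0.5), horizon=5.0)
        for t in profile.times:
            assert np.any(np.isclose(res.times, t))

    def test_step_refinement_does_not_change_survival(self):
        profile = ExposureProfile(np.array([0.0, 0.35, 0.7, 3.1]),
                                  np.array([1.0, 0.0, 2.0, 0.0]))
        params = SDParams(ke=0.9, kk=0.4, z=0.3, h_controls=0.01)
        coarse = predict(profile, params, horizon=6.0, step=1.0)
        fine = predict(profile, params, horizon=6.0, step=0.01)
        assert fine.survival[-1] == pytest.approx(coarse.survival[-1],
                                                  abs=1e-6)


class TestOracleEquivalence:
    """Piecewise-analytic survival vs dense fixed-step explicit integration."""

    @pytest.mark.parametrize("model", ["SD", "IT"])
    def test_random_profiles_match_brute_force(self, model):
        rng = np.random.default_rng(42 if model == "SD" else 43)
        worst = 0.0
        for _ in range(8):
            profile = random_step_profile(rng)
            params = (random_sd_params(rng) if model == "SD"
                      else random_it_params(rng))
            grid_bf, s_bf = brute_force_survival(profile, params, 14.0)
            check = grid_bf[::10_000]  # every 1 d
            fn = survival_sd if model == "SD" else survival_it
            res = fn(profile, params, check)
            idx = np.searchsorted(res.times, check)
            worst = max(worst, float(np.max(np.abs(res.survival[idx]
                                                   - s_bf[::10_000]))))
        assert worst < 1e-4

    def test_linear_interpolation_matches_brute_force(self, rng):
        times = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 9.0])
        conc = np.array([0.0, 2.0, 0.5, 3.0, 0.0, 0.0])
        profile = ExposureProfile(times, conc, interpolation="linear")
        for params in (SDParams(ke=0.8, kk=0.5, z=0.8, h_controls=0.01),
                       ITParams(ke=0.8, alpha=1.2, beta=4.0)):
            grid_bf, s_bf = brute_force_survival(profile, params, 12.0)
            check = grid_bf[::10_000]
            res = predict(profile, params, grid=check)
            idx = np.searchsorted(res.times, check)
            np.testing.assert_allclose(res.survival[idx], s_bf[::10_000],
                                       atol=1e-4)
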