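import math

import numpy as np
import pytest

from gutsurv import (ControlGroup, ITParams, SDParams, SurvivalDataset,
                     Treatment, fit_background_hazard,
                     hazard_from_survival_fraction, neg_log_likelihood)
from gutsurv.likelihood import survival_at_constant

from _oracles import (brute_force_survival, random_it_params, random_sd_params)
from gutsurv import constant_profile


def make_dataset(records, controls=()):
    treatments = tuple(Treatment(c, np.asarray(t, float), np.asarray(y, float))
                       for c, t, y in records)
    ctrl = tuple(ControlGroup(np.asarray(t, float), np.asarray(y, float))
                 for t, y in controls)
    return SurvivalDataset(treatments, ctrl)


class TestDatasetValidation:
    def test_requires_time_zero_with_initial_count(self):
        with pytest.raises(ValueError):
            Treatment(1.0, np.array([1.0, 2.0]), np.array([10.0, 8.0]))

    def test_rejects_increasing_survivors(self):
        with pytest.raises(ValueError):
            Treatment(1.0, np.array([0.0, 1.0, 2.0]), np.array([10.0, 8.0, 9.0]))


class TestConstantExposureSurvival:
    """The closed-form fast path must agree with the general engine."""

    @pytest.mark.parametrize("model", ["SD", "IT"])
    def test_matches_general_engine(self, model, rng):
        times = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        for _ in range(20):
            params = (random_sd_params(rng) if model == "SD"
                      else random_it_params(rng))
            c = float(rng.uniform(0.0, 3.0))
            fast = survival_at_constant(c, params, times)
            from gutsurv import predict
            res = predict(constant_profile(c, 4.0), params, grid=times)
            idx = np.searchsorted(res.times, times)
            np.testing.assert_allclose(fast, res.survival[idx], atol=1e-12)


class TestNegLogLikelihood:
    def test_zero_when_all_survive_and_model_agrees(self):
        data = make_dataset([(0.5, [0, 1, 2, 3, 4], [10, 10, 10, 10, 10])])
        params = SDParams(ke=1.0, kk=1.0, z=2.0)  # Ci stays below z
        assert neg_log_likelihood(data, params) == pytest.approx(0.0, abs=1e-12)

    def test_half_deaths_at_half_survival(self):
        # model S(1) = 0.5: IT with alpha at Ci(1), any beta
        alpha = 2.0 * (1.0 - math.exp(-1.0))
        params = ITParams(ke=1.0, alpha=alpha, beta=3.0)
        data = make_dataset([(2.0, [0.0, 1.0], [10, 5])])
        assert neg_log_likelihood(data, params) == pytest.approx(10 * math.log(2),
                                                                 rel=1e-9)

    def test_matches_brute_force_interval_probabilities(self, rng):
        """Independent oracle: death probabilities from the dense-grid
        integrator, multinomial log-mass assembled by explicit loops."""
        times = np.array([0.0, 1.0, 2.0, 4.0])
        for model in ("SD", "IT"):
            params = (random_sd_params(rng) if model == "SD"
                      else random_it_params(rng))
            records, expected = [], 0.0
            for c, counts in [(1.2, [8, 6, 5, 2]), (0.4, [10, 10, 9, 9]),
                              (2.5, [6, 1, 0, 0])]:
                records.append((c, times, counts))
                grid, s_dense = brute_force_survival(
                    constant_profile(c, 4.0), params, 4.0, dt=1e-5)
                s_obs = s_dense[np.searchsorted(grid, times)]
                for i in range(1, len(times)):
                    deaths = counts[i - 1] - counts[i]
                    p = max(s_obs[i - 1] - s_obs[i], 1e-12)
                    expected -= deaths * math.log(p)
                expected -= counts[-1] * math.log(max(s_obs[-1], 1e-12))
            got = neg_log_likelihood(make_dataset(records), params)
            assert got == pytest.approx(expected, abs=5e-3)

    def test_invariant_under_treatment_permutation(self, rng):
        params = random_sd_params(rng)
        recs = [(1.0, [0, 1, 2], [10, 9, 7]), (2.0, [0, 1, 2], [10, 5, 2]),
                (0.3, [0, 1, 2], [10, 10, 10])]
        a = neg_log_likelihood(make_dataset(recs), params)
        b = neg_log_likelihood(make_dataset(recs[::-1]), params)
        assert a == pytest.approx(b, rel=1e-14)

    def test_zero_fish_treatment_contributes_nothing(self, rng):
        params = random_sd_params(rng)
        base = [(1.0, [0, 1, 2], [10, 9, 7])]
        withzero = base + [(5.0, [0, 1, 2], [0, 0, 0])]
        assert (neg_log_likelihood(make_dataset(base), params)
                == neg_log_likelihood(make_dataset(withzero), params))

    def test_floor_keeps_objective_finite(self):
        # deaths in an interval the model calls impossible
        params = SDParams(ke=1.0, kk=1.0, z=50.0)  # no predicted mortality
        data = make_dataset([(1.0, [0.0, 1.0], [10, 4])])
        val = neg_log_likelihood(data, params)
        assert math.isfinite(val)

    def test_model_name_mismatch_raises(self):
        data = make_dataset([(1.0, [0.0, 1.0], [10, 9])])
        with pytest.raises(TypeError):
            neg_log_likelihood(data, SDParams(ke=1.0, kk=1.0, z=1.0), model="IT")


class TestBackgroundHazard:
    def test_single_interval_closed_form(self):
        # 50 of 100 fish alive at day 4: MLE is ln(2)/4
        res = fit_background_hazard([ControlGroup(np.array([0.0, 4.0]),
                                                  np.array([100.0, 50.0]))])
        assert res.h_controls == pytest.approx(math.log(2) / 4.0, rel=1e-6)
        lo, hi = res.ci
        assert lo < res.h_controls < hi

    def test_no_deaths_returns_zero_with_warning(self):
        grp = ControlGroup(np.array([0.0, 4.0]), np.array([10.0, 10.0]))
        with pytest.warns(UserWarning):
            res = fit_background_hazard([grp])
        assert res.h_controls == 0.0
        assert res.ci[0] == 0.0 and res.ci[1] > 0.0

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            fit_background_hazard([])

    def test_pooling_controls_uses_all_groups(self):
        one = [ControlGroup(np.array([0.0, 4.0]), np.array([100.0, 50.0]))]
        both = one + [ControlGroup(np.array([0.0, 4.0]), np.array([100.0, 100.0]))]
        h_one = fit_background_hazard(one).h_controls
        h_both = fit_background_hazard(both).h_controls
        assert h_both < h_one  # extra death-free fish pull the rate down


class TestLifespanHazard:
    def test_ten_percent_over_two_years(self):
        h = hazard_from_survival_fraction(0.10, 730.0)
        assert h == pytest.approx(0.00315, abs=5e-6)

    def test_agrees_with_interval_mle(self):
        # a control record with exactly 10% survivors at 730 d
        grp = ControlGroup(np.array([0.0, 730.0]), np.array([1000.0, 100.0]))
        mle = fit_background_hazard([grp]).h_controls
        assert mle == pytest.approx(hazard_from_survival_fraction(0.10, 730.0),
                                    rel=1e-4)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            hazard_from_survival_fraction(0.0, 730.0)
        with pytest.raises(ValueError):
            hazard_from_survival_fraction(0.5, 0.0)
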