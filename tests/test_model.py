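"""Unit tests for the right-hand-side evaluators and domain types."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caloradapt import IntakeHistory, ModelState
from caloradapt.model import (energy_balance, energy_expenditure,
                              food_intake_rate, moving_average_intake,
                              partition_ffm, rhs_body_composition, rhs_food,
                              rhs_ghrelin, rhs_glucose, rhs_hunger,
                              rhs_lambda, rhs_leptin)
from caloradapt.params import ModelParameters


class TestIntakeRule:
    def test_no_hunger_no_intake(self, params):
        assert food_intake_rate(0.0, 100.0, params) == 0.0

    def test_no_food_no_intake(self, params):
        assert food_intake_rate(100.0, 0.0, params) == 0.0

    def test_depends_on_minimum_only(self, params):
        assert food_intake_rate(50.0, 200.0, params) == \
            food_intake_rate(50.0, 50.0, params)
        assert food_intake_rate(0.3, 7.0, params) == \
            food_intake_rate(7.0, 0.3, params)

    def test_monotone_and_capped(self, params):
        qs = [food_intake_rate(h, 1e6, params)
              for h in (0.0, 0.1, 0.5, 1.0, 5.0, 50.0)]
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        assert qs[-1] == pytest.approx(1.0 / params.intake_rate_coeff)

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            food_intake_rate(-1.0, 10.0, params)


class TestEnergyExpenditure:
    def test_zero_rate_spends_nothing(self, params):
        assert energy_expenditure(50.0, 350.0, 0.0, params) == 0.0

    def test_affine_caloric_content(self, params):
        # lam * (rho_F*F + rho_FFM*FFM + K) with the default densities
        expected = 1e-5 * (39.3 * 50 + 7.5 * 350 + 1964.4)
        assert energy_expenditure(50.0, 350.0, 1e-5, params) == \
            pytest.approx(expected)

    def test_linear_in_rate(self, params):
        assert energy_expenditure(50, 350, 2e-5, params) == \
            pytest.approx(2 * energy_expenditure(50, 350, 1e-5, params))

    def test_strictly_increasing_in_masses(self, params):
        base = energy_expenditure(50, 350, 1e-5, params)
        assert energy_expenditure(51, 350, 1e-5, params) > base
        assert energy_expenditure(50, 351, 1e-5, params) > base

    def test_negative_mass_rejected(self, params):
        with pytest.raises(ValueError):
            energy_expenditure(-1.0, 350, 1e-5, params)


def test_energy_balance_arithmetic():
    assert energy_balance(1.0, 1.0) == 0.0
    assert energy_balance(0.5, 0.2) == pytest.approx(0.3)
    assert energy_balance(0.2, 0.5) == -energy_balance(0.5, 0.2)


class TestBodyComposition:
    @pytest.mark.parametrize("F,FFM,E", [(48, 352, 0.0), (10, 300, 0.15),
                                         (120, 420, -0.2), (0.5, 200, 0.07)])
    def test_energy_partition_identity(self, params, F, FFM, E):
        st_ = ModelState(F, FFM, 0, 0, 0, 0, 0, params.lambda0)
        dF, dFFM = rhs_body_composition(st_, E, params)
        assert params.rho_F * dF + params.rho_FFM * dFFM == \
            pytest.approx(E, abs=1e-12)

    def test_partition_in_unit_interval_and_monotone(self, params):
        fs = np.linspace(0.0, 200.0, 400)
        ps = np.array([partition_ffm(f, params) for f in fs])
        assert np.all((ps > 0) & (ps < 1))
        # fatter animals store mostly fat: monotone split, strict until
        # the exponential term underflows to the floor
        assert np.all(np.diff(ps) <= 1e-15)
        strict = ps[fs < 60.0]
        assert np.all(np.diff(strict) < 0)

    def test_nonfinite_balance_rejected(self, params):
        st_ = ModelState(48, 352, 0, 0, 0, 0, 0, params.lambda0)
        with pytest.raises(ValueError):
            rhs_body_composition(st_, math.nan, params)


def test_rhs_food_is_delivery_minus_consumption():
    assert rhs_food(10.0, 0.0, 0.0) == 0.0
    assert rhs_food(10.0, 0.2, 0.05) == pytest.approx(0.15)


class TestHormoneKinetics:
    def test_leptin_steady_state(self, params):
        # production 0.126 ng/g/min at F=100 g against clearance 0.074/min
        L_star = 0.126 * 100 / 0.074
        assert rhs_leptin(L_star, 100.0, params) == pytest.approx(0.0, abs=1e-12)
        assert rhs_leptin(L_star + 1, 100.0, params) < 0
        assert rhs_leptin(0.0, 0.0, params) == 0.0

    def test_glucose_steady_state(self, params):
        q = 0.2
        G_star = params.glucose_yield * q / params.glucose_clear
        assert rhs_glucose(G_star, q, params) == pytest.approx(0.0, abs=1e-12)
        assert rhs_glucose(G_star + 1, q, params) < 0
        assert rhs_glucose(0.0, 0.0, params) == 0.0

    def test_ghrelin_fasted_production(self, params):
        assert rhs_ghrelin(0.0, 0.0, params) == pytest.approx(params.ghrelin_prod)
        fasted_star = params.ghrelin_prod / params.ghrelin_clear
        assert rhs_ghrelin(fasted_star, 0.0, params) == pytest.approx(0.0)

    def test_ghrelin_inhibited_by_eating(self, params):
        qs = np.linspace(0.0, 1.0 / params.intake_rate_coeff, 20)
        prods = [rhs_ghrelin(0.0, q, params) for q in qs]
        assert all(b <= a for a, b in zip(prods, prods[1:]))
        assert prods[-1] == pytest.approx(0.0, abs=1e-12)


class TestHunger:
    def test_partial_derivative_signs(self, params):
        """Hunger rises with ghrelin and falls with leptin and glucose."""
        H, L, G, Ghr = 0.3, 80.0, 1.2, 40.0
        eps = 1e-6
        base = rhs_hunger(H, L, G, Ghr, params)
        assert rhs_hunger(H, L, G, Ghr + eps, params) > base
        assert rhs_hunger(H, L + eps, G, Ghr, params) < base
        assert rhs_hunger(H, L, G + eps, Ghr, params) < base

    def test_satiated_state_decays(self, params):
        assert rhs_hunger(1.0, 1e4, 1e3, 0.0, params) <= 0.0

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1e3])
    def test_finite_over_wide_hormone_range(self, params, scale):
        v = rhs_hunger(0.3, 80 * scale, 1.2 * scale, 40 * scale, params)
        assert math.isfinite(v)


class TestMemory:
    def _hist(self, fill=0.0):
        return IntakeHistory(dt=60.0, tau1_day=1.0, tau2_day=8.0,
                             fill_rate=fill)

    def test_constant_intake_returns_constant(self):
        h = self._hist(fill=315.0 / 1440.0)
        assert moving_average_intake(h, 1.0) == pytest.approx(315.0)
        assert moving_average_intake(h, 8.0) == pytest.approx(315.0)

    def test_zero_intake(self):
        h = self._hist(0.0)
        assert moving_average_intake(h, 8.0) == 0.0

    def test_square_wave_matches_brute_force(self):
        h = self._hist(0.0)
        rng = np.random.default_rng(0)
        pushed = []
        for day in range(12):
            amount = 300.0 if day % 2 else 0.0
            for _ in range(24):  # dt = 60 min
                e = amount / 24.0 * rng.uniform(0.5, 1.5)
                h.push(e)
                pushed.append(e)
        arr = np.array(pushed)
        for window in (1.0, 8.0):
            w = int(window * 24)
            expected = arr[-w:].sum() / window
            assert moving_average_intake(h, window) == pytest.approx(expected)

    def test_untracked_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average_intake(self._hist(), 3.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=600))
    def test_running_sums_match_numpy(self, values):
        """The O(1) ring-buffer sums agree with direct trailing sums."""
        h = IntakeHistory(dt=30.0, tau1_day=0.5, tau2_day=2.0, fill_rate=0.1)
        full = [0.1 * 30.0] * h.w2
        for v in values:
            h.push(v)
            full.append(v)
        m1, m2 = h.means()
        assert m1 == pytest.approx(sum(full[-h.w1:]) / (h.w1 * 30.0))
        assert m2 == pytest.approx(sum(full[-h.w2:]) / (h.w2 * 30.0))


class TestLambdaAdaptation:
    def test_balanced_memory_is_fixed_point(self, params):
        assert rhs_lambda(params.lambda0, 0.2, 0.2, params) == 0.0

    def test_restriction_lowers_expenditure_rate(self, params):
        assert rhs_lambda(params.lambda0, 0.1, 0.2, params) < 0
        assert rhs_lambda(params.lambda0, 0.3, 0.2, params) > 0

    def test_zero_gain_freezes_rate(self, params):
        p0 = params.with_(mem_gain=0.0)
        assert rhs_lambda(p0.lambda0, 0.1, 0.3, p0) == 0.0

    def test_nonpositive_rate_rejected(self, params):
        with pytest.raises(ValueError):
            rhs_lambda(0.0, 0.1, 0.2, params)


class TestDomainTypes:
    def test_state_rejects_negative_variables(self):
        with pytest.raises(ValueError):
            ModelState(-1, 352, 0, 0, 0, 0, 0, 1e-5)

    def test_state_requires_positive_body_weight(self):
        with pytest.raises(ValueError):
            ModelState(0, 0, 10, 0, 0, 0, 0, 1e-5)

    def test_parameters_require_window_ordering(self):
        with pytest.raises(ValueError):
            ModelParameters(tau1=8.0, tau2=1.0)

    def test_parameters_require_positivity(self):
        with pytest.raises(ValueError):
            ModelParameters(leptin_clear=0.0)

    def test_density_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(rho_F=5.0, rho_FFM=7.5)

    def test_history_requires_window_ordering(self):
        with pytest.raises(ValueError):
            IntakeHistory(dt=1.0, tau1_day=8.0, tau2_day=1.0)
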