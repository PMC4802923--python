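"""Transition-matrix assembly and cohort iteration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfscreen.markov import (
    TransitionMatrixCache,
    annual_to_cycle_prob,
    build_transition_matrix,
    nyha_cycle_matrix,
    run_cohort,
    treated_mortality,
    treatment_hazard_multiplier,
)
from hfscreen.states import DETECTED_STATES, UNDETECTED_STATES, HealthState

from conftest import toy_params


class TestAnnualToCycle:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    @pytest.mark.parametrize("cycle", [0.25, 1.0, 2.0])
    def test_boundaries_preserved(self, p, cycle):
        assert annual_to_cycle_prob(p, cycle) == p

    def test_closed_form(self):
        # constant-hazard split of an annual 0.042 into quarters
        expected = 1.0 - math.exp(0.25 * math.log(1.0 - 0.042))
        assert annual_to_cycle_prob(0.042, 0.25) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.01067, abs=5e-6)

    @given(st.floats(0.0, 1.0 - 1e-12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_four_cycles_compose_to_annual(self, p):
        q = annual_to_cycle_prob(p, 0.25)
        assert 1.0 - (1.0 - q) ** 4 == pytest.approx(p, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            annual_to_cycle_prob(1.2, 0.25)
        with pytest.raises(ValueError):
            annual_to_cycle_prob(0.5, 0.0)


class TestNyhaCycleMatrix:
    def test_identity_fixed_point(self, men):
        out = nyha_cycle_matrix(np.eye(4), 85.0, men, detected=True)
        np.testing.assert_allclose(out, np.eye(4), atol=1e-12)

    def test_reference_age_is_plain_cube(self, men):
        m = men.nyha_monthly_transition
        out = nyha_cycle_matrix(m, 65.0, men, detected=False)
        np.testing.assert_allclose(out, np.linalg.matrix_power(m, 3), atol=1e-14)

    def test_scaling_against_brute_force(self):
        """Worsening x ratio, improvement / ratio, diagonal re-closes each row."""
        params = toy_params(mortality_age_scale={60: 1.0, 80: 1.5})
        m = np.full((4, 4), 0.1 / 3)
        np.fill_diagonal(m, 0.9)
        m[0, 0] = m[3, 3] = 1 - 0.1  # keep rows stochastic
        m = m / m.sum(axis=1, keepdims=True)
        out = nyha_cycle_matrix(m, 80.0, params, detected=False)
        cube = np.linalg.matrix_power(m, 3)
        ratio = 1.5
        for i in range(4):
            expected = cube[i].copy()
            for j in range(4):
                if j > i:
                    expected[j] *= ratio
                elif j < i:
                    expected[j] /= ratio
            expected[i] = 1.0 - (expected.sum() - expected[i])
            np.testing.assert_allclose(out[i], expected, atol=1e-12)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_excess_mass_renormalized_with_warning(self):
        params = toy_params(mortality_age_scale={60: 1.0, 80: 50.0})
        m = np.array(
            [
                [0.9, 0.1, 0.0, 0.0],
                [0.05, 0.9, 0.05, 0.0],
                [0.0, 0.05, 0.9, 0.05],
                [0.0, 0.0, 0.05, 0.95],
            ]
        )
        with pytest.warns(UserWarning, match="renormalized"):
            out = nyha_cycle_matrix(m, 80.0, params, detected=False)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()


class TestTreatedMortality:
    def test_full_effect_limit(self, men):
        assert treatment_hazard_multiplier(men, rho=1.0) == pytest.approx(
            men.hfref_treatment_hr
        )

    def test_null_treatment_limit(self):
        params = toy_params(hfref_treatment_hr=1.0, hfpef_fraction=0.826)
        for rho in (0.0, 0.5, 1.0):
            assert treatment_hazard_multiplier(params, rho=rho) == 1.0
        assert treated_mortality(0.103, params) == pytest.approx(0.103, abs=1e-12)

    def test_base_case_multiplier_closed_form(self, men):
        # untreated -> treated mix at rho=0: (1-f)h + f
        f, h = 0.826, 0.90
        assert treatment_hazard_multiplier(men, rho=0.0) == pytest.approx(
            (1 - f) * h + f
        )
        assert treatment_hazard_multiplier(men, rho=0.0) == pytest.approx(0.9826)

    def test_hazard_scale_application(self, men):
        m = treatment_hazard_multiplier(men)
        assert treated_mortality(0.103, men) == pytest.approx(
            1.0 - (1.0 - 0.103) ** m, abs=1e-15
        )


class TestBuildTransitionMatrix:
    def test_null_dynamics_is_identity(self):
        params = toy_params()
        P = build_transition_matrix(params, 60.0).entries
        np.testing.assert_allclose(P, np.eye(11), atol=1e-12)

    def test_recorded_hf_mortality_enters_per_cycle(self, men):
        """At the base case the detected NYHA III mortality is used verbatim."""
        P = build_transition_matrix(men, 60.0).entries
        expected = annual_to_cycle_prob(0.103, 0.25)
        assert P[HealthState.NYHA3_D, HealthState.DEATH_HF] == pytest.approx(
            expected, abs=1e-12
        )

    def test_death_rows_are_absorbing(self, men):
        P = build_transition_matrix(men, 72.0).entries
        for s in (HealthState.DEATH_HF, HealthState.DEATH_OTHER):
            expected = np.zeros(11)
            expected[s] = 1.0
            np.testing.assert_array_equal(P[s], expected)

    def test_rows_sum_to_one_across_ages(self, men, women):
        for params in (men, women):
            for age in (60, 65, 75, 90, 105):
                P = build_transition_matrix(params, age).entries
                np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
                assert (P >= -1e-12).all() and (P <= 1 + 1e-12).all()

    def test_no_entry_into_undetected_except_incidence_and_movement(self, men):
        """Undetected states are reachable only from DIAB (NYHA II) and the
        undetected stratum; detected states never fall back to undetected."""
        P = build_transition_matrix(men, 70.0).entries
        undetected = set(UNDETECTED_STATES.values())
        for src in HealthState:
            for dst in undetected:
                if P[src, dst] <= 0:
                    continue
                if src == HealthState.DIAB_NO_HF:
                    assert dst == HealthState.NYHA2_U
                else:
                    assert src in undetected

    def test_impossible_death_mass_raises(self):
        params = toy_params(cycle_death=0.9)
        params.hf_mortality_annual = {(k, d): 1.0 - 1e-9 for k in (1, 2, 3, 4) for d in (True, False)}
        params.baseline_hf_distribution[(2, False)] = 0.3
        with pytest.raises(ValueError, match="death mass|exceeds"):
            build_transition_matrix(params, 60.0)


class TestRunCohort:
    def test_absorbed_start_has_no_dynamics(self, strategies):
        params = toy_params(cycle_death=0.5)
        dist = np.zeros(11)
        dist[HealthState.DEATH_OTHER] = 1.0
        trace = run_cohort(strategies[0], params, initial=dist)
        assert trace.n_cycles == 0
        assert trace.alive_mass().sum() == 0.0

    @pytest.mark.parametrize("q", [0.5, 0.1, 0.01])
    def test_geometric_life_expectancy_oracle(self, q, strategies):
        """Two-state cohort with constant per-cycle death q lives 1/q cycles."""
        params = toy_params(cycle_death=q, max_age=float("inf"))
        trace = run_cohort(strategies[0], params)
        cycles_alive = trace.alive_mass().sum()
        assert cycles_alive == pytest.approx(1.0 / q, abs=1e-6)

    def test_matrix_power_oracle_equivalence(self, strategies):
        """With an age-constant matrix, occupancy at cycle n equals d0 @ P^n."""
        m = np.array(
            [
                [0.95, 0.03, 0.015, 0.005],
                [0.02, 0.93, 0.04, 0.01],
                [0.005, 0.03, 0.925, 0.04],
                [0.001, 0.004, 0.03, 0.965],
            ]
        )
        params = toy_params(cycle_death=0.02, nyha_monthly=m)
        params.hf_mortality_annual = {
            (k, d): 0.02 * k for k in (1, 2, 3, 4) for d in (True, False)
        }
        params.baseline_hf_distribution = {(2, False): 0.2, (3, False): 0.1}
        params = params.validate()
        P = build_transition_matrix(params, 60.0).entries
        trace = run_cohort(strategies[0], params, horizon=10.0)
        d0 = trace.occupancy[0]
        for n in (1, 5, 20, trace.n_cycles - 1):
            expected = d0 @ np.linalg.matrix_power(P, n)
            np.testing.assert_allclose(trace.occupancy[n], expected, atol=1e-10)

    def test_mass_conservation_and_monotone_death(self, men, women, strategies):
        for params in (men, women):
            for s in (strategies[0], strategies[1], strategies[5]):
                trace = run_cohort(s, params)
                np.testing.assert_allclose(
                    trace.occupancy.sum(axis=1), 1.0, atol=1e-9
                )
                dead = trace.occupancy[:, [HealthState.DEATH_HF, HealthState.DEATH_OTHER]].sum(axis=1)
                assert (np.diff(dead) >= -1e-12).all()

    def test_perfect_detection_dominates_no_screening(self, men, strategies):
        t0 = run_cohort(strategies[0], men)
        t5 = run_cohort(strategies[5], men)
        det = [DETECTED_STATES[k] for k in (1, 2, 3, 4)]
        n = min(t0.n_cycles, t5.n_cycles)
        d0 = t0.occupancy[1:n, det].sum(axis=1)
        d5 = t5.occupancy[1:n, det].sum(axis=1)
        assert (d5 > d0).all()

    def test_raising_mortality_lowers_life_expectancy(self, men, strategies):
        worse = men.copy()
        worse.hf_mortality_annual = {
            k: min(1.0, v * 1.5) for k, v in men.hf_mortality_annual.items()
        }
        ly = lambda p: run_cohort(strategies[0], p).alive_mass().sum() * 0.25
        assert ly(worse) < ly(men)

    def test_raising_sensitivity_raises_detected_occupancy(self, men, strategies):
        from dataclasses import replace

        lo = replace(strategies[1], sensitivity_by_nyha={1: 0.1, 2: 0.4, 3: 0.4, 4: 0.5})
        hi = replace(strategies[1], sensitivity_by_nyha={1: 0.3, 2: 0.9, 3: 0.95, 4: 1.0})
        det = [DETECTED_STATES[k] for k in (1, 2, 3, 4)]
        cum = lambda s: run_cohort(s, men).occupancy[:, det].sum()
        assert cum(hi) > cum(lo)

    def test_nonconvergent_horizon_raises(self, strategies):
        params = toy_params(cycle_death=0.0, max_age=float("inf"))
        with pytest.raises(RuntimeError, match="not decreasing"):
            run_cohort(strategies[0], params)

    def test_trace_export_shape(self, men, strategies):
        df = run_cohort(strategies[1], men).to_frame()
        assert list(df.columns[:2]) == ["age", "DIAB_NO_HF"]
        assert "event_cost" in df.columns
        assert len(df) > 150  # lifetime horizon at 3-month cycles


def test_matrix_cache_matches_direct_build(men):
    cache = TransitionMatrixCache(men)
    np.testing.assert_array_equal(cache.at(73.6), build_transition_matrix(men, 73.0).entries)
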