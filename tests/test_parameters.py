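"""Parameter records, fixtures, config round trip, distribution specs."""

import numpy as np
import pytest

from hfscreen.parameters import (
    ConfigurationError,
    ValidationError,
    beta_spec_from_counts,
    beta_spec_from_moments,
    default_strategies,
    export_parameter_table,
    fixture,
    gamma_spec_from_mean,
    gompertz_mortality_table,
    load_parameters,
    write_config,
)
from hfscreen.states import HealthState
from hfscreen.uncertainty import default_psa_specs


class TestFixtures:
    """The built-in Dutch fixtures reproduce every recorded input cell."""

    def test_men_point_values(self, men):
        assert men.echo_cost == 169.38
        assert men.ecg_stress_cost == 94.75
        assert men.utilities[HealthState.DIAB_NO_HF] == 0.868
        assert men.hf_incidence_per_100k == 658
        assert men.background_mortality_at(60) == 0.010
        assert men.discount_rate_costs == 0.04
        assert men.discount_rate_effects == 0.015
        assert men.hfpef_fraction == 0.826

    @pytest.mark.parametrize(
        "nyha,detected,men_v,women_v",
        [
            (1, True, 0.042, 0.035), (1, False, 0.043, 0.036),
            (2, True, 0.066, 0.056), (2, False, 0.067, 0.057),
            (3, True, 0.103, 0.087), (3, False, 0.105, 0.089),
            (4, True, 0.159, 0.137), (4, False, 0.163, 0.139),
        ],
    )
    def test_hf_mortality_cells(self, men, women, nyha, detected, men_v, women_v):
        assert men.hf_mortality_annual[(nyha, detected)] == men_v
        assert women.hf_mortality_annual[(nyha, detected)] == women_v

    @pytest.mark.parametrize(
        "nyha,detected,men_v,women_v",
        [
            (1, True, 1777, 1172), (1, False, 1786, 1100),
            (2, True, 2099, 1370), (2, False, 2114, 1302),
            (3, True, 3235, 2070), (3, False, 3275, 2018),
            (4, True, 8752, 5470), (4, False, 8912, 5490),
        ],
    )
    def test_annual_hf_cost_cells(self, men, women, nyha, detected, men_v, women_v):
        assert men.annual_hf_cost[(nyha, detected)] == men_v
        assert women.annual_hf_cost[(nyha, detected)] == women_v

    @pytest.mark.parametrize(
        "state,value",
        [
            (HealthState.NYHA1_D, 0.855), (HealthState.NYHA1_U, 0.817),
            (HealthState.NYHA2_D, 0.790), (HealthState.NYHA2_U, 0.739),
            (HealthState.NYHA3_D, 0.734), (HealthState.NYHA3_U, 0.685),
            (HealthState.NYHA4_D, 0.665), (HealthState.NYHA4_U, 0.683),
        ],
    )
    def test_utilities_shared_across_genders(self, men, women, state, value):
        assert men.utilities[state] == value
        assert women.utilities[state] == value

    def test_baseline_prevalence_block(self, men):
        assert men.baseline_hf_distribution[(2, True)] == 0.148
        assert men.baseline_hf_distribution[(2, False)] == 0.142
        assert men.baseline_hf_distribution[(4, True)] == 0.0
        assert sum(men.baseline_hf_distribution.values()) == pytest.approx(0.375)

    def test_women_incidence_and_mortality(self, women):
        assert women.hf_incidence_per_100k == 666
        assert women.background_mortality_at(60) == 0.007

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ConfigurationError):
            fixture("elbonia_men")


class TestStrategies:
    def test_recorded_sensitivities(self, strategies):
        s = {st.id: st for st in strategies}
        assert s[1].sensitivity_by_nyha == {1: 0.250, 2: 0.853, 3: 0.923, 4: 1.000}
        assert s[4].sensitivity_by_nyha[1] == 0.500
        assert s[3].specificity == 0.652
        assert [st.gp_screen_cost for st in strategies] == [0.0, 6.39, 15.17, 36.67, 61.77, 0.0]

    def test_boundary_strategies(self, strategies):
        s0, s5 = strategies[0], strategies[5]
        assert all(v == 0.0 for v in s0.sensitivity_by_nyha.values())
        assert s0.specificity == 1.0 and s0.gp_screen_cost == 0.0
        assert all(v == 1.0 for v in s5.sensitivity_by_nyha.values())
        assert s5.direct_echo and s5.gp_screen_cost == 0.0


class TestConfigRoundTrip:
    def test_yaml_round_trip_field_by_field(self, men, tmp_path):
        path = tmp_path / "men.yaml"
        write_config(men, str(path))
        back = load_parameters(str(path))
        assert back.to_config_dict() == men.to_config_dict()
        np.testing.assert_array_equal(back.nyha_monthly_transition, men.nyha_monthly_transition)
        assert back.utilities == men.utilities
        assert back.hf_mortality_annual == men.hf_mortality_annual

    def test_override_passthrough(self, men):
        cfg = men.to_config_dict()
        cfg["discount_rate_costs"] = 0.0
        assert load_parameters(cfg).discount_rate_costs == 0.0

    def test_bad_transition_row_names_field(self, men):
        cfg = men.to_config_dict()
        cfg["nyha_monthly_transition"][0][0] -= 0.1  # row now sums to 0.9
        with pytest.raises(ValidationError, match="nyha_monthly_transition"):
            load_parameters(cfg)

    def test_missing_required_field_is_config_error(self, men):
        cfg = men.to_config_dict()
        del cfg["utilities"]
        with pytest.raises(ConfigurationError, match="utilities"):
            load_parameters(cfg)

    def test_invalid_probability_names_field(self, men):
        cfg = men.to_config_dict()
        cfg["hf_mortality_annual"]["NYHA2"]["detected"] = 1.5
        with pytest.raises(ValidationError, match="hf_mortality_annual"):
            load_parameters(cfg)


class TestDistributionSpecs:
    def test_gamma_variance_equals_mean(self):
        spec = gamma_spec_from_mean(169.38)
        shape, scale = spec.parameters
        assert shape * scale == pytest.approx(169.38)  # mean
        assert shape * scale**2 == pytest.approx(169.38)  # variance

    def test_gamma_shape_one_is_exponential(self):
        spec = gamma_spec_from_mean(1.0)
        assert spec.parameters == (1.0, 1.0)

    def test_gamma_monte_carlo_moment(self):
        spec = gamma_spec_from_mean(94.75)
        rng = np.random.default_rng(0)
        draws = rng.gamma(spec.parameters[0], spec.parameters[1], size=10**6)
        se = np.sqrt(94.75 / 10**6)  # MC standard error of the mean
        assert abs(draws.mean() - 94.75) < 3 * se

    def test_gamma_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            gamma_spec_from_mean(0.0)

    @pytest.mark.parametrize("tp,fn,mean", [(29, 5, 29 / 34), (1, 3, 0.25)])
    def test_beta_counts_mean(self, tp, fn, mean):
        assert beta_spec_from_counts(tp, fn).mean() == pytest.approx(mean)

    def test_beta_degenerate_counts_are_fixed(self):
        assert beta_spec_from_counts(1, 0).family == "fixed"
        assert beta_spec_from_counts(0, 7).family == "fixed"
        with pytest.raises(ValueError):
            beta_spec_from_counts(0, 0)

    def test_beta_moments_mean_preserved(self):
        spec = beta_spec_from_moments(0.79, 0.02)
        assert spec.mean() == pytest.approx(0.79, abs=1e-12)

    def test_psa_specs_are_mean_centred(self, men, strategies):
        """Every sampling distribution's analytic mean equals the base value."""
        by_id = {s.id: s for s in strategies}
        for spec in default_psa_specs(men, strategies):
            path = spec.target.split(".")
            if path[0] == "strategies":
                s = by_id[int(path[1])]
                base = (
                    s.sensitivity_by_nyha[int(path[3])]
                    if path[2] == "sensitivity"
                    else getattr(s, path[2])
                )
            elif path[0] == "utilities":
                base = men.utilities[HealthState[path[1]]]
            elif path[0] == "annual_hf_cost":
                base = men.annual_hf_cost[(int(path[1][4:]), path[2] == "detected")]
            elif path[0] == "baseline_hf_distribution":
                cells = sorted(c for c, p in men.baseline_hf_distribution.items() if p > 0)
                total = sum(men.baseline_hf_distribution[c] for c in cells)
                base = np.array([men.baseline_hf_distribution[c] / total for c in cells])
            else:
                base = getattr(men, path[0])
            np.testing.assert_allclose(spec.mean(), base, atol=1e-9)


class TestGompertz:
    def test_table_is_increasing_and_anchored(self):
        table = gompertz_mortality_table(0.010)
        ages = sorted(table)
        assert table[60] == 0.010
        assert all(table[a + 1] > table[a] for a in ages[:-1] if table[a] < 0.99)

    def test_rejects_nonpositive_anchor(self):
        with pytest.raises(ValueError):
            gompertz_mortality_table(0.0)


def test_parameter_export_table(men, strategies):
    df = export_parameter_table(men, strategies)
    assert {"parameter", "value", "distribution"} <= set(df.columns)
    row = df[df.parameter == "echo_cost"].iloc[0]
    assert row.value == 169.38 and row.distribution == "gamma"
    assert (df[df.parameter.str.startswith("hf_mortality")].distribution == "fixed").all()
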