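import numpy as np
import pytest

from hfscreen.parameters import ParameterSet, default_strategies, fixture
from hfscreen.states import HealthState


@pytest.fixture(scope="session")
def men() -> ParameterSet:
    return fixture("dutch_men")


@pytest.fixture(scope="session")
def women() -> ParameterSet:
    return fixture("dutch_women")


@pytest.fixture(scope="session")
def strategies():
    return default_strategies()


def toy_params(
    *,
    cycle_death: float = 0.0,
    incidence: float = 0.0,
    nyha_monthly: np.ndarray | None = None,
    max_age: float = 110.0,
    **overrides,
) -> ParameterSet:
    """A minimal, analytically tractable parameter set.

    Zero HF mortality and incidence by default; ``cycle_death`` sets the
    per-cycle background death probability exactly (converted to the
    equivalent annual probability).
    """
    annual = 1.0 - (1.0 - cycle_death) ** 4
    kwargs = dict(
        gender="male",
        hf_incidence_per_100k=incidence,
        background_mortality_annual=annual,
        hf_mortality_annual={(k, d): 0.0 for k in (1, 2, 3, 4) for d in (True, False)},
        baseline_hf_distribution={(k, d): 0.0 for k in (1, 2, 3, 4) for d in (True, False)},
        annual_hf_cost={(k, d): 0.0 for k in (1, 2, 3, 4) for d in (True, False)},
        medication_prescription={},
        utilities={
            s: 1.0
            for s in HealthState
            if s not in (HealthState.DEATH_HF, HealthState.DEATH_OTHER)
        },
        nyha_monthly_transition=np.eye(4) if nyha_monthly is None else nyha_monthly,
        max_age=max_age,
        discount_rate_costs=0.0,
        discount_rate_effects=0.0,
    )
    kwargs.update(overrides)
    return ParameterSet(**kwargs).validate()
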