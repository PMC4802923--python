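"""Cohort state-transition engine.

Builds 11x11 per-cycle (3-month) transition matrices from a
:class:`~hfscreen.parameters.ParameterSet` and iterates the cohort over a
lifetime horizon.  Within a cycle the event order is: death (background and,
for HF states, HF-specific), then HF incidence, then NYHA movement
conditional on survival.  Death probabilities are additive competing risks;
NYHA movement redistributes the surviving mass within a detection stratum.
Detection status changes only through screening events, which the runner
applies to the state distribution at cycle start (initial screen at cycle 0,
annual EMR/symptoms reassessment every fourth cycle for screening
strategies).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ScreeningStrategy, emr_symptoms_profile
from .states import (
    DETECTED_STATES,
    HealthState,
    N_STATES,
    NYHA_CLASSES,
    UNDETECTED_STATES,
)

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "TransitionMatrixCache",
    "annual_to_cycle_prob",
    "nyha_cycle_matrix",
    "treated_mortality",
    "treatment_hazard_multiplier",
    "build_transition_matrix",
    "initial_distribution",
    "run_cohort",
]

_ALIVE = np.array([s not in (HealthState.DEATH_HF, HealthState.DEATH_OTHER) for s in HealthState])


def annual_to_cycle_prob(p_annual: float, cycle_years: float) -> float:
    """Convert an annual probability to a per-cycle one under constant hazard.

    ``1 - (1 - p)**t`` for a cycle of ``t`` years; p=0 and p=1 are preserved
    for any cycle length.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0,1], got {p_annual}")
    if cycle_years <= 0:
        raise ValueError(f"cycle_years must be > 0, got {cycle_years}")
    return 1.0 - (1.0 - p_annual) ** cycle_years


def treatment_hazard_multiplier(params: ParameterSet, rho: float | None = None) -> float:
    """Mortality hazard multiplier for a *detected* (treated) HF population.

    The detected population is a mix of an HFrEF share ``1 - f`` whose
    guideline treatment carries hazard ratio ``h``, and an HFpEF share ``f``
    that receives a fraction ``rho`` of that effect:

        m = (1 - f) * h + f * (1 - rho * (1 - h))

    ``rho = 0`` leaves HFpEF untreated (base case); ``rho = 1`` gives every
    detected patient the full HFrEF effect (m = h).
    """
    f = params.hfpef_fraction
    h = params.hfref_treatment_hr
    r = params.hfpef_relative_effectiveness if rho is None else rho
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"rho must be in [0,1], got {r}")
    return (1.0 - f) * h + f * (1.0 - r * (1.0 - h))


def treated_mortality(base_annual: float, params: ParameterSet) -> float:
    """Annual death probability of an untreated HF population after treatment.

    Applies :func:`treatment_hazard_multiplier` on the hazard scale:
    ``1 - (1 - p)**m``.
    """
    if not 0.0 <= base_annual <= 1.0:
        raise ValueError(f"base_annual must be in [0,1], got {base_annual}")
    m = treatment_hazard_multiplier(params)
    return 1.0 - (1.0 - base_annual) ** m


def _relative_treatment_factor(params: ParameterSet) -> float:
    """Hazard factor on the *recorded* detected-state mortalities.

    The point-estimate detected mortalities already embed the base-case
    treatment mix (HFrEF treated, HFpEF not), so scenario effectiveness
    ``rho`` enters relative to that base: ``m(rho) / m(0)`` (= 1 at rho=0).
    """
    return treatment_hazard_multiplier(params) / treatment_hazard_multiplier(params, rho=0.0)


def nyha_cycle_matrix(
    monthly: np.ndarray, age: float, params: ParameterSet, detected: bool
) -> np.ndarray:
    """3-month NYHA-to-NYHA matrix at a given age.

    The monthly matrix is cubed; above the reference age (65) worsening
    (above-diagonal) probabilities are multiplied by the age-band mortality
    ratio relative to 65 and improvement (below-diagonal) probabilities are
    divided by it, with the diagonal absorbing the difference.  If scaling
    pushes a row's off-diagonal mass above 1 the row is renormalized and a
    warning recorded.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape != (4, 4):
        raise ValueError(f"monthly matrix must be 4x4, got {monthly.shape}")
    if not np.allclose(monthly.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("monthly matrix rows must sum to 1")
    m3 = np.linalg.matrix_power(monthly, 3)
    ratio = params.age_scale(age) / params.age_scale(65.0)
    if ratio == 1.0:
        return m3
    out = m3.copy()
    upper = np.triu(np.ones((4, 4), dtype=bool), k=1)
    lower = np.tril(np.ones((4, 4), dtype=bool), k=-1)
    out[upper] *= ratio
    out[lower] /= ratio
    np.fill_diagonal(out, 0.0)
    off = out.sum(axis=1)
    for i in range(4):
        if off[i] > 1.0:
            warnings.warn(
                f"NYHA row {i + 1}: age-scaled off-diagonal mass {off[i]:.4f} > 1; renormalized",
                stacklevel=2,
            )
            out[i] /= off[i]
            off[i] = 1.0
        out[i, i] = 1.0 - off[i]
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle transition probabilities at a given cohort age."""

    entries: np.ndarray
    age: float

    def __post_init__(self) -> None:
        e = self.entries
        if e.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}, got {e.shape}")


def build_transition_matrix(params: ParameterSet, age: float) -> TransitionMatrix:
    """Assemble the full 11-state per-cycle matrix at ``age``.

    Raises an assembly error naming the state when composed probabilities
    leave [0,1] (e.g. background + HF death mass exceeding 1).
    """
    cl = params.cycle_length
    P = np.zeros((N_STATES, N_STATES))
    q_bg = annual_to_cycle_prob(min(1.0, params.background_mortality_at(age)), cl)

    # Diabetes without HF: background death, then incidence into NYHA II undetected.
    inc_annual = min(
        1.0, params.hf_incidence_per_100k / 1e5 * params.diabetes_incidence_multiplier
    )
    p_inc = annual_to_cycle_prob(inc_annual, cl)
    i0 = HealthState.DIAB_NO_HF
    P[i0, HealthState.DEATH_OTHER] = q_bg
    P[i0, HealthState.NYHA2_U] = (1.0 - q_bg) * p_inc
    P[i0, i0] = (1.0 - q_bg) * (1.0 - p_inc)

    age_ratio = params.age_scale(age) / params.age_scale(params.start_age)
    rel_treat = _relative_treatment_factor(params)
    for detected, stratum in ((False, UNDETECTED_STATES), (True, DETECTED_STATES)):
        nyha_m = nyha_cycle_matrix(params.nyha_monthly_transition, age, params, detected)
        for k in NYHA_CLASSES:
            s = stratum[k]
            p_hf_annual = params.hf_mortality_annual[(k, detected)]
            # age-band scaling on the hazard scale keeps the probability in [0,1]
            hazard_power = age_ratio * (rel_treat if detected else 1.0)
            p_hf_annual = 1.0 - (1.0 - p_hf_annual) ** hazard_power
            q_hf = annual_to_cycle_prob(p_hf_annual, cl)
            survive = 1.0 - q_bg - q_hf
            if survive < 0:
                raise ValueError(
                    f"state {s.name} at age {age}: death mass {q_bg + q_hf:.4f} exceeds 1"
                )
            P[s, HealthState.DEATH_HF] = q_hf
            P[s, HealthState.DEATH_OTHER] = q_bg
            for j in NYHA_CLASSES:
                P[s, stratum[j]] = survive * nyha_m[k - 1, j - 1]

    for s in (HealthState.DEATH_HF, HealthState.DEATH_OTHER):
        P[s, s] = 1.0

    if (P < -1e-12).any() or (P > 1 + 1e-12).any():
        bad = int(np.argwhere((P < -1e-12) | (P > 1 + 1e-12))[0][0])
        raise ValueError(f"assembled probability outside [0,1] in row {HealthState(bad).name}")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        bad = int(np.argmin(np.isclose(P.sum(axis=1), 1.0, atol=1e-9)))
        raise ValueError(f"row {HealthState(bad).name} does not sum to 1")
    return TransitionMatrix(P, age)


class TransitionMatrixCache:
    """Per-integer-age cache of transition matrices for one parameter set.

    All inputs that vary over the horizon (life table, age-band scaling)
    change only at whole ages, so matrices are shared across the four cycles
    of a year — and across strategies, which differ only in screening.
    """

    def __init__(self, params: ParameterSet):
        self.params = params
        self._cache: dict[int, np.ndarray] = {}

    def at(self, age: float) -> np.ndarray:
        key = int(math.floor(age))
        if key not in self._cache:
            self._cache[key] = build_transition_matrix(self.params, float(key)).entries
        return self._cache[key]


@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort history.

    ``occupancy[i]`` is the state distribution at the start of cycle ``i``
    (after any screening event); cost arrays hold per-cycle screening (GP)
    and diagnosis (echo + ECG stress test) event costs per cohort member.
    """

    occupancy: np.ndarray
    ages: np.ndarray
    screening_costs: np.ndarray
    diagnosis_costs: np.ndarray
    cycle_length: float
    strategy_id: int | None = None
    new_detections: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def event_costs(self) -> np.ndarray:
        return self.screening_costs + self.diagnosis_costs

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def alive_mass(self) -> np.ndarray:
        return self.occupancy[:, _ALIVE].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: age, 11 occupancy columns, event cost."""
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "age", self.ages)
        df["event_cost"] = self.event_costs
        return df


def initial_distribution(params: ParameterSet) -> np.ndarray:
    """Baseline state distribution before the initial screening event.

    Under the default ``all_undetected`` policy every prevalent HF case
    starts undetected (the cohort excluded known HF; the recorded
    detected-column proportions are folded into the undetected states).
    ``as_recorded`` starts from the recorded detected/undetected split.
    """
    dist = np.zeros(N_STATES)
    for (k, detected), p in params.baseline_hf_distribution.items():
        if params.baseline_detection == "all_undetected":
            dist[UNDETECTED_STATES[k]] += p
        else:
            dist[(DETECTED_STATES if detected else UNDETECTED_STATES)[k]] += p
    dist[HealthState.DIAB_NO_HF] = 1.0 - dist.sum()
    if dist[HealthState.DIAB_NO_HF] < -1e-9:
        raise ValueError("baseline_hf_distribution sums to more than 1")
    dist[HealthState.DIAB_NO_HF] = max(0.0, dist[HealthState.DIAB_NO_HF])
    return dist


def run_cohort(
    strategy: ScreeningStrategy,
    params: ParameterSet,
    horizon: float | str = "lifetime",
    matrix_cache: TransitionMatrixCache | None = None,
    strategies_annual: ScreeningStrategy | None = None,
    initial: np.ndarray | None = None,
) -> CohortTrace:
    """Simulate the cohort under one screening strategy.

    The initial screen (the strategy itself) is applied at cycle 0; for
    screening strategies (id != 0) the annual EMR/symptoms reassessment is
    applied every fourth cycle thereafter.  The simulation stops when the
    alive mass drops below 1e-8, the cohort age exceeds ``params.max_age``,
    or a numeric ``horizon`` (years) is reached.
    """
    from .screening import apply_screening  # local import to avoid a cycle

    cache = matrix_cache or TransitionMatrixCache(params)
    annual = strategies_annual or emr_symptoms_profile(params.annual_screen_gp_cost)
    dist = initial_distribution(params) if initial is None else np.asarray(initial, dtype=float)

    occupancy: list[np.ndarray] = []
    ages: list[float] = []
    screen_costs: list[float] = []
    dx_costs: list[float] = []
    detections: list[float] = []

    cl = params.cycle_length
    max_years = float("inf") if horizon == "lifetime" else float(horizon)
    i = 0
    prev_alive = float("inf")
    while True:
        age = params.start_age + i * cl
        alive = dist[_ALIVE].sum()
        if alive < 1e-8 or age > params.max_age or i * cl >= max_years:
            break
        if alive >= prev_alive and not math.isfinite(params.max_age):
            raise RuntimeError("non-convergent horizon: alive mass is not decreasing")

        gp_cost = dx_cost = 0.0
        new_det = 0.0
        if i == 0:
            outcome = apply_screening(dist, strategy, params, is_initial=True)
            dist = outcome.post_distribution
            gp_cost, dx_cost = outcome.gp_cost, outcome.diagnosis_cost
            new_det = sum(outcome.new_detections_by_nyha.values())
        elif strategy.id != 0 and i % 4 == 0:
            outcome = apply_screening(dist, annual, params, is_initial=False)
            dist = outcome.post_distribution
            gp_cost, dx_cost = outcome.gp_cost, outcome.diagnosis_cost
            new_det = sum(outcome.new_detections_by_nyha.values())

        occupancy.append(dist.copy())
        ages.append(age)
        screen_costs.append(gp_cost)
        dx_costs.append(dx_cost)
        detections.append(new_det)

        prev_alive = alive
        dist = dist @ cache.at(age)
        i += 1

    return CohortTrace(
        occupancy=np.array(occupancy).reshape(-1, N_STATES),
        ages=np.array(ages),
        screening_costs=np.array(screen_costs),
        diagnosis_costs=np.array(dx_costs),
        cycle_length=cl,
        strategy_id=strategy.id,
        new_detections=np.array(detections),
    )
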