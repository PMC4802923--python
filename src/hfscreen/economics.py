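"""Valuation of a cohort trace: discounted life-years, QALYs and costs.

Health effects are discounted at the effects rate (default 1.5%/year), costs
at the costs rate (default 4%/year), both at cycle start.  State costs model
only the *increase* over routine diabetes care, so the diabetes-without-HF
state and the death states carry zero cost.  Reported life expectancy is
undiscounted; a discounted variant is also returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace
from .parameters import ParameterSet
from .states import DEATH_STATES, HealthState, NYHA_CLASSES, hf_state

__all__ = ["EconResult", "discount_factor", "state_cost_per_cycle", "derived_annual_hf_costs", "accrue"]


def discount_factor(rate: float, time: float) -> float:
    """Present-value factor ``(1 + rate) ** -time`` (time in years)."""
    if rate < 0 or time < 0:
        raise ValueError("rate and time must be non-negative")
    return (1.0 + rate) ** (-time)


def derived_annual_hf_costs(params: ParameterSet) -> dict[tuple[int, bool], float]:
    """Annual HF cost per (NYHA, detection) derived from config components.

    Base hospitalization/nursing cost weighted by the per-NYHA
    hospitalization hazard ratio, adjusted for detection status by the
    detected/undetected mortality ratio, plus — for detected patients only —
    the prescribed-medication cost (prescription proportion x annual drug
    cost per drug class).
    """
    if (
        params.hosp_hazard_ratio_by_nyha is None
        or params.drug_annual_cost is None
        or params.base_hosp_nursing_annual_cost is None
    ):
        raise ValueError(
            "derived HF costs need hosp_hazard_ratio_by_nyha, drug_annual_cost "
            "and base_hosp_nursing_annual_cost in the configuration"
        )
    med_detected = sum(
        p * params.drug_annual_cost.get(drug, 0.0)
        for (drug, det), p in params.medication_prescription.items()
        if det
    )
    out: dict[tuple[int, bool], float] = {}
    for k in NYHA_CLASSES:
        hr = params.hosp_hazard_ratio_by_nyha[k]
        base = params.base_hosp_nursing_annual_cost * hr
        mort_ratio = params.hf_mortality_annual[(k, True)] / max(
            params.hf_mortality_annual[(k, False)], 1e-12
        )
        out[(k, False)] = base
        out[(k, True)] = base * mort_ratio + med_detected
    return out


def state_cost_per_cycle(
    state: HealthState, params: ParameterSet, derived: bool = False
) -> float:
    """Per-cycle cost of occupying ``state``.

    The default path reads the recorded annual HF costs; ``derived=True``
    rebuilds them from hazard-ratio components (:func:`derived_annual_hf_costs`).
    Diabetes-without-HF and death states cost nothing (incremental-cost
    convention).
    """
    if state is HealthState.DIAB_NO_HF or state in DEATH_STATES:
        return 0.0
    costs = derived_annual_hf_costs(params) if derived else params.annual_hf_cost
    for k in NYHA_CLASSES:
        for det in (True, False):
            if hf_state(k, det) is state:
                return costs[(k, det)] * params.cycle_length
    raise ValueError(f"unknown state {state!r}")  # pragma: no cover


@dataclass(frozen=True)
class EconResult:
    """Discounted totals per cohort member for one strategy."""

    strategy_id: int | None
    life_years: float
    life_years_discounted: float
    qalys: float
    qalys_undiscounted: float
    total_cost: float
    breakdown: dict[str, float]

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.qalys - self.total_cost


def accrue(trace: CohortTrace, params: ParameterSet, derived_costs: bool = False) -> EconResult:
    """Sum a trace into life-years, QALYs and discounted costs.

    Per cycle the occupancy-weighted utility accrues ``cycle_length`` years
    of quality-adjusted time at the effects discount rate; state and event
    costs accrue at the costs rate.  With ``half_cycle_correction`` both are
    discounted to mid-cycle.
    """
    n = trace.n_cycles
    if n == 0:
        return EconResult(trace.strategy_id, 0.0, 0.0, 0.0, 0.0, 0.0, _breakdown(0, 0, 0, 0))
    occ = trace.occupancy
    if occ.shape[1] != len(HealthState):
        raise ValueError("trace occupancy has the wrong number of states")
    cl = trace.cycle_length
    t = np.arange(n) * cl + (0.5 * cl if params.half_cycle_correction else 0.0)
    df_eff = (1.0 + params.discount_rate_effects) ** (-t)
    df_cost = (1.0 + params.discount_rate_costs) ** (-t)

    u = np.array([params.utility_of(s) for s in HealthState])
    sc = np.array([state_cost_per_cycle(s, params, derived=derived_costs) for s in HealthState])
    alive = np.array([s not in DEATH_STATES for s in HealthState], dtype=float)

    ly = float((occ @ alive).sum() * cl)
    ly_disc = float(((occ @ alive) * df_eff).sum() * cl)
    qalys = float(((occ @ u) * df_eff).sum() * cl)
    qalys_undisc = float((occ @ u).sum() * cl)

    hf_state_cost = float(((occ @ sc) * df_cost).sum())
    screening = float((trace.screening_costs * df_cost).sum())
    diagnosis = float((trace.diagnosis_costs * df_cost).sum())
    breakdown = _breakdown(screening, diagnosis, hf_state_cost, 0.0)
    total = sum(breakdown.values())
    return EconResult(trace.strategy_id, ly, ly_disc, qalys, qalys_undisc, total, breakdown)


def _breakdown(screening: float, diagnosis: float, hf_state: float, medication: float) -> dict[str, float]:
    # medication is reported separately only on the derived-cost path; the
    # recorded annual HF costs already include it for detected states.
    return {
        "screening": screening,
        "diagnosis": diagnosis,
        "hf_state": hf_state,
        "medication": medication,
    }
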