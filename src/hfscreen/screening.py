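"""Screening events on a cohort state distribution.

A screen examines the alive, not-yet-detected population (diabetes without
HF plus the undetected NYHA states).  Per NYHA class, a fraction equal to
the strategy's sensitivity moves from undetected to detected; screen-positive
non-HF members (1 - specificity of the diabetes-without-HF mass) are referred
for echocardiography, which is a perfect arbiter — no false HF diagnoses
arise.  Costs: the GP-level screen is charged for every screened person, the
echo for every referral, and an ECG stress test for every new diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, ScreeningStrategy, emr_symptoms_profile
from .states import DETECTED_STATES, HealthState, NYHA_CLASSES, UNDETECTED_STATES

__all__ = ["ScreeningOutcome", "apply_screening", "diagnosis_cost"]


@dataclass(frozen=True)
class ScreeningOutcome:
    """Result of one screening event (all quantities per cohort member)."""

    post_distribution: np.ndarray
    screened_fraction: float
    echo_referrals: float
    new_detections_by_nyha: dict[int, float]
    gp_cost: float
    diagnosis_cost: float

    @property
    def event_cost(self) -> float:
        return self.gp_cost + self.diagnosis_cost


def diagnosis_cost(new_detections: float, params: ParameterSet) -> float:
    """ECG-stress-test cost booked per newly diagnosed member.

    The echocardiography cost is booked with the referral, not here.
    """
    if not 0.0 <= new_detections <= 1.0:
        raise ValueError(f"new_detections must be in [0,1], got {new_detections}")
    return new_detections * params.ecg_stress_cost


def apply_screening(
    dist: np.ndarray,
    strategy: ScreeningStrategy,
    params: ParameterSet,
    is_initial: bool,
) -> ScreeningOutcome:
    """Apply one screening event and account its costs.

    Detected and dead states are never screened.  When ``is_initial`` is
    false the event is the annual follow-up and the strategy is forced to
    the EMR/symptoms profile (with the configured annual GP cost).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(HealthState),) or (dist < -1e-12).any():
        raise ValueError("dist must be a valid 11-state distribution")
    if not is_initial:
        strategy = emr_symptoms_profile(params.annual_screen_gp_cost)

    post = dist.copy()
    no_hf = dist[HealthState.DIAB_NO_HF]
    screened = no_hf + sum(dist[UNDETECTED_STATES[k]] for k in NYHA_CLASSES)

    new_det: dict[int, float] = {}
    for k in NYHA_CLASSES:
        moved = strategy.sensitivity_by_nyha[k] * dist[UNDETECTED_STATES[k]]
        new_det[k] = moved
        post[UNDETECTED_STATES[k]] -= moved
        post[DETECTED_STATES[k]] += moved
    total_det = sum(new_det.values())

    if strategy.direct_echo:
        # everyone screened is sent straight to echocardiography
        echo_referrals = screened
    else:
        echo_referrals = total_det + (1.0 - strategy.specificity) * no_hf

    gp = strategy.gp_screen_cost * screened
    dx = params.echo_cost * echo_referrals + diagnosis_cost(total_det, params)
    return ScreeningOutcome(
        post_distribution=post,
        screened_fraction=screened,
        echo_referrals=echo_referrals,
        new_detections_by_nyha=new_det,
        gp_cost=gp,
        diagnosis_cost=dx,
    )
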