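"""Health states of the heart-failure progression model.

The cohort model distinguishes diabetes without heart failure, the four NYHA
symptom classes each split into *detected* and *undetected* HF, and two
absorbing death states (death from HF, death from other causes) — eleven
states in total.
"""

from __future__ import annotations

from enum import IntEnum

NYHA_CLASSES: tuple[int, ...] = (1, 2, 3, 4)

DETECTED = True
UNDETECTED = False


class HealthState(IntEnum):
    """Model states; the integer value is the row/column index in matrices."""

    DIAB_NO_HF = 0
    NYHA1_U = 1
    NYHA1_D = 2
    NYHA2_U = 3
    NYHA2_D = 4
    NYHA3_U = 5
    NYHA3_D = 6
    NYHA4_U = 7
    NYHA4_D = 8
    DEATH_HF = 9
    DEATH_OTHER = 10


N_STATES = len(HealthState)

ABSORBING_STATES = (HealthState.DEATH_HF, HealthState.DEATH_OTHER)
DEATH_STATES = ABSORBING_STATES

#: Alive states in index order.
ALIVE_STATES = tuple(s for s in HealthState if s not in ABSORBING_STATES)

#: Undetected / detected HF states indexed by NYHA class.
UNDETECTED_STATES = {
    1: HealthState.NYHA1_U,
    2: HealthState.NYHA2_U,
    3: HealthState.NYHA3_U,
    4: HealthState.NYHA4_U,
}
DETECTED_STATES = {
    1: HealthState.NYHA1_D,
    2: HealthState.NYHA2_D,
    3: HealthState.NYHA3_D,
    4: HealthState.NYHA4_D,
}


def hf_state(nyha: int, detected: bool) -> HealthState:
    """Return the model state for a NYHA class and detection status."""
    if nyha not in NYHA_CLASSES:
        raise ValueError(f"NYHA class must be 1-4, got {nyha!r}")
    return DETECTED_STATES[nyha] if detected else UNDETECTED_STATES[nyha]


def is_hf_state(state: HealthState) -> bool:
    return state not in (HealthState.DIAB_NO_HF, *ABSORBING_STATES)
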