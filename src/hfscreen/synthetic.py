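"""Synthetic generators for the inputs no publication prints.

The cohort model needs a 1-month NYHA transition matrix, an age-indexed
background-mortality life table, hospitalization hazard ratios, drug costs
and — for validation exercises — a patient-level table whose group summaries
match the recorded cohort means.  These generators produce plausible,
seed-deterministic versions of each so the full pipeline runs and is
testable offline.  A derivative-free calibration helper searches the NYHA
generator's configuration space for a matrix reproducing given life/QALY
expectancy targets; with only four scalar targets the problem is
under-determined and the result is a best fit, not a unique answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .economics import accrue
from .markov import TransitionMatrixCache, run_cohort
from .parameters import (
    ParameterSet,
    default_strategies,
    gompertz_mortality_table,
)
from .states import NYHA_CLASSES

__all__ = [
    "SyntheticConfig",
    "GenerationError",
    "generate_nyha_matrix",
    "generate_life_table",
    "generate_patient_table",
    "calibrate_nyha_matrix",
    "CalibrationResult",
]


class GenerationError(ValueError):
    """Requested intensities cannot yield a row-stochastic matrix."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generators.

    ``progression_intensity`` / ``improvement_intensity`` are per-month
    probabilities of moving one NYHA class up (worse) / down (better);
    transitions across ``d`` classes are damped by ``step_decay**(d-1)``.
    ``jitter`` adds seeded lognormal noise to the off-diagonal entries
    (coefficient of variation; 0 = deterministic).  ``nyha_mix`` is the NYHA
    distribution of prevalent HF, defaulting to the recorded cohort mix.
    """

    seed: int = 0
    n_patients: int = 581
    hf_prevalence: float = 0.277
    hfpef_share: float = 0.826
    nyha_mix: tuple[float, float, float, float] = (0.0187, 0.7733, 0.2080, 0.0)
    detected_share_by_nyha: tuple[float, float, float, float] = (1.0, 0.5103, 0.6026, 0.5)
    progression_intensity: float = 0.04
    improvement_intensity: float = 0.02
    step_decay: float = 0.18
    jitter: float = 0.0
    gompertz_anchor_male: float = 0.010
    gompertz_anchor_female: float = 0.007
    gompertz_rate: float = 0.092

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("hf_prevalence", "hfpef_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: {v} not in [0,1]")
        if abs(sum(self.nyha_mix) - 1.0) > 1e-9:
            raise ValueError(f"nyha_mix must sum to 1, got {sum(self.nyha_mix)}")
        for name in ("progression_intensity", "improvement_intensity", "step_decay", "jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_nyha_matrix(config: SyntheticConfig) -> np.ndarray:
    """Seeded, row-stochastic 1-month NYHA I-IV transition matrix.

    Worsening mass sits above the diagonal and improvement mass below it
    (including NYHA IV -> I: even severe patients have a small chance of a
    better class within a month); the diagonal takes the remainder.
    """
    rng = np.random.default_rng(config.seed)
    m = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            d = abs(j - i)
            base = (
                config.progression_intensity if j > i else config.improvement_intensity
            ) * config.step_decay ** (d - 1)
            noise = rng.lognormal(0.0, config.jitter) if config.jitter > 0 else 1.0
            m[i, j] = base * noise
        off = m[i].sum()
        if off > 1.0:
            raise GenerationError(
                f"row {i + 1}: off-diagonal mass {off:.3f} > 1; lower the intensities"
            )
        m[i, i] = 1.0 - off
    return m


def generate_life_table(config: SyntheticConfig, gender: str) -> dict[int, float]:
    """Gompertz-shaped annual mortality by age (60-110), anchored at age 60.

    The anchors default to the recorded annual non-HF death probabilities at
    the cohort's start age (0.010 men, 0.007 women); mortality rises
    strictly with age at log-slope ``gompertz_rate``.
    """
    if gender not in ("male", "female"):
        raise ValueError(f"gender must be male/female, got {gender!r}")
    anchor = config.gompertz_anchor_male if gender == "male" else config.gompertz_anchor_female
    return gompertz_mortality_table(anchor, config.gompertz_rate)


def generate_patient_table(config: SyntheticConfig) -> pd.DataFrame:
    """Patient-level synthetic cohort emulating the recorded summary statistics.

    One row per patient: gender, age, HF status, HF type (HFpEF/HFrEF), NYHA
    class, detected flag, an EQ5D utility draw (beta, moment-matched to the
    recorded group means with SE 0.02) and an annual HF cost draw
    (variance-equals-mean gamma around the recorded group means).  Group
    means converge to the recorded fixtures as ``n_patients`` grows.
    """
    from .parameters import fixture  # deferred: fixtures carry the group means

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    genders = np.where(rng.random(n) < 0.5, "male", "female")
    ages = rng.uniform(60.0, 80.0, n)
    has_hf = rng.random(n) < config.hf_prevalence
    hfpef = has_hf & (rng.random(n) < config.hfpef_share)
    nyha = np.where(has_hf, rng.choice([1, 2, 3, 4], size=n, p=config.nyha_mix), 0)
    det_share = dict(zip(NYHA_CLASSES, config.detected_share_by_nyha))
    detected = np.array(
        [bool(k) and rng.random() < det_share[k] for k in nyha], dtype=bool
    )

    params = {"male": fixture("dutch_men"), "female": fixture("dutch_women")}
    util = np.empty(n)
    cost = np.zeros(n)
    for i in range(n):
        p = params[genders[i]]
        if not has_hf[i]:
            mean_u = p.utilities[_state(0, False)]
            util[i] = _beta_draw(rng, mean_u, 0.02)
            continue
        mean_u = p.utilities[_state(int(nyha[i]), bool(detected[i]))]
        util[i] = _beta_draw(rng, mean_u, 0.02)
        mean_c = p.annual_hf_cost[(int(nyha[i]), bool(detected[i]))]
        cost[i] = rng.gamma(mean_c, 1.0)  # shape=mean, scale=1: variance = mean
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "gender": genders,
            "age": ages,
            "has_hf": has_hf,
            "hf_type": np.where(has_hf, np.where(hfpef, "HFpEF", "HFrEF"), ""),
            "nyha": nyha,
            "detected": detected,
            "eq5d_utility": util,
            "annual_hf_cost": cost,
        }
    )


def _state(nyha: int, detected: bool):
    from .states import HealthState, hf_state

    return HealthState.DIAB_NO_HF if nyha == 0 else hf_state(nyha, detected)


def _beta_draw(rng: np.random.Generator, mean: float, se: float) -> float:
    var = se * se
    if mean in (0.0, 1.0) or var >= mean * (1 - mean):
        return mean
    nu = mean * (1 - mean) / var - 1
    return float(rng.beta(mean * nu, (1 - mean) * nu))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Best NYHA matrix found, the generator config producing it, and the loss."""

    matrix: np.ndarray
    config: SyntheticConfig
    loss: float
    achieved: dict[str, float]
    evaluations: int = 0


def _pipeline_summary(matrix: np.ndarray, base: ParameterSet) -> dict[str, float]:
    """Life-years and QALYs for no-screening and EMR/symptoms under ``matrix``."""
    params = base.copy()
    params.nyha_monthly_transition = np.asarray(matrix, dtype=float)
    cache = TransitionMatrixCache(params)
    s0, s1 = default_strategies()[0], default_strategies()[1]
    out: dict[str, float] = {}
    for s, tag in ((s0, "s0"), (s1, "s1")):
        res = accrue(run_cohort(s, params, matrix_cache=cache), params)
        out[f"ly_{tag}"] = res.life_years
        # the published expectancy block is undiscounted (its QALY/LY ratio
        # exceeds what discounted QALYs could reach given the utilities)
        out[f"qaly_{tag}"] = res.qalys_undiscounted
    return out


_TARGET_KEYS = ("ly_s0", "qaly_s0", "ly_s1", "qaly_s1")


def calibrate_nyha_matrix(
    targets: Mapping[str, float] | Sequence[float],
    base: ParameterSet,
    search_budget: int = 250,
    seed: int = 0,
) -> CalibrationResult:
    """Search the NYHA-generator configuration for given expectancy targets.

    ``targets`` holds life-years and QALYs for no screening and the
    EMR/symptoms strategy (keys ``ly_s0, qaly_s0, ly_s1, qaly_s1`` or a
    4-sequence in that order).  A seeded random scan over (progression,
    improvement, step-decay) intensities is followed by a Nelder-Mead polish
    in log space; ``search_budget`` caps the total number of model
    evaluations.  The loss is the summed squared deviation from the targets;
    many matrices can achieve similar loss — no uniqueness is claimed.
    """
    if not isinstance(targets, Mapping):
        targets = dict(zip(_TARGET_KEYS, targets))
    missing = [k for k in _TARGET_KEYS if k not in targets]
    if missing:
        raise ValueError(f"targets missing keys: {missing}")
    if search_budget < 0:
        raise ValueError("search_budget must be >= 0")

    evaluations = 0

    def loss_of(x: np.ndarray) -> tuple[float, SyntheticConfig, np.ndarray, dict[str, float]]:
        nonlocal evaluations
        evaluations += 1
        cfg = SyntheticConfig(
            seed=seed,
            progression_intensity=float(np.exp(x[0])),
            improvement_intensity=float(np.exp(x[1])),
            step_decay=float(1.0 / (1.0 + np.exp(-x[2]))),
            jitter=0.0,
        )
        try:
            m = generate_nyha_matrix(cfg)
            achieved = _pipeline_summary(m, base)
        except (GenerationError, ValueError):
            return float("inf"), cfg, np.eye(4), {}
        loss = sum((achieved[k] - float(targets[k])) ** 2 for k in _TARGET_KEYS)
        return loss, cfg, m, achieved

    default_cfg = SyntheticConfig(seed=seed, jitter=0.0)
    x0 = np.array(
        [
            np.log(default_cfg.progression_intensity),
            np.log(default_cfg.improvement_intensity),
            np.log(default_cfg.step_decay / (1.0 - default_cfg.step_decay)),
        ]
    )
    if search_budget == 0:
        loss, cfg, m, achieved = loss_of(x0)
        return CalibrationResult(m, cfg, loss, achieved, evaluations=0)
    best = loss_of(x0)

    rng = np.random.default_rng(seed)
    n_scan = min(max(search_budget // 5, 0), max(search_budget - 1, 0))
    for _ in range(n_scan):
        if evaluations >= search_budget:
            break
        cand = loss_of(x0 + rng.normal(0.0, 1.0, size=3))
        if cand[0] < best[0]:
            best = cand

    if evaluations < search_budget:
        start = (
            x0
            if best[0] == float("inf")
            else np.array(
                [
                    np.log(best[1].progression_intensity),
                    np.log(best[1].improvement_intensity),
                    np.log(best[1].step_decay / (1.0 - best[1].step_decay)),
                ]
            )
        )
        res = optimize.minimize(
            lambda x: loss_of(x)[0],
            start,
            method="Nelder-Mead",
            options={
                "maxfev": max(search_budget - evaluations, 1),
                "xatol": 1e-8,
                "fatol": 1e-14,
            },
        )
        cand = loss_of(res.x)
        if cand[0] < best[0]:
            best = cand

    loss, cfg, m, achieved = best
    return CalibrationResult(m, cfg, loss, achieved, evaluations=evaluations)
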