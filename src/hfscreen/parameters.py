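"""Model inputs: typed, validated, gender-stratified parameter records.

Everything the cohort model consumes lives in a :class:`ParameterSet` — HF
incidence and mortality, the baseline NYHA distribution, monthly NYHA
transition probabilities, state costs and utilities, discount rates and the
treatment-effect knobs — together with the six :class:`ScreeningStrategy`
definitions (per-NYHA sensitivity, specificity and per-screen cost).

Built-in fixtures ``dutch_men`` and ``dutch_women`` carry the published Dutch
point estimates for a type-2-diabetes cohort screened at age 60.  Inputs that
no publication prints (the 1-month NYHA transition matrix, the life table,
hospitalization hazard ratios, drug unit costs) default to hand-tuned
synthetic values and can be overridden from a YAML config file.

:class:`DistributionSpec` describes, per parameter, the sampling distribution
used by the probabilistic sensitivity analysis: beta for probabilities and
utilities, variance-equals-mean gamma for costs, Dirichlet for the baseline
prevalence block, or fixed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import yaml

from .states import (
    DEATH_STATES,
    HealthState,
    NYHA_CLASSES,
    hf_state,
)

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ScreeningStrategy",
    "ParameterSet",
    "DistributionSpec",
    "default_strategies",
    "emr_symptoms_profile",
    "fixture",
    "load_parameters",
    "write_config",
    "gamma_spec_from_mean",
    "beta_spec_from_counts",
    "beta_spec_from_moments",
    "gompertz_mortality_table",
    "export_parameter_table",
    "DEFAULT_NYHA_MONTHLY",
]


class ConfigurationError(Exception):
    """A config source is missing a required field or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant; message names the field."""


# ---------------------------------------------------------------------------
# Screening strategies (published sensitivities/specificities/costs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningStrategy:
    """One screening strategy: NYHA-specific sensitivity, specificity, cost.

    Strategy 0 is "no screening" (detects nothing, costs nothing); strategy 5
    refers every screened person directly for echocardiography
    (``direct_echo``), so its GP-level screen is free but every screen incurs
    an echo.
    """

    id: int
    name: str
    sensitivity_by_nyha: Mapping[int, float]
    specificity: float
    gp_screen_cost: float
    direct_echo: bool = False

    def __post_init__(self) -> None:
        for k in NYHA_CLASSES:
            s = self.sensitivity_by_nyha[k]
            if not 0.0 <= s <= 1.0:
                raise ValidationError(f"strategy {self.id} sensitivity NYHA {k}: {s} not in [0,1]")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValidationError(f"strategy {self.id} specificity: {self.specificity} not in [0,1]")
        if self.gp_screen_cost < 0:
            raise ValidationError(f"strategy {self.id} gp_screen_cost: {self.gp_screen_cost} < 0")


def default_strategies() -> list[ScreeningStrategy]:
    """The six strategies of the Dutch evaluation, 0 = usual care."""
    return [
        ScreeningStrategy(0, "No screening", {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}, 1.0, 0.0),
        ScreeningStrategy(1, "EMR/symptoms", {1: 0.250, 2: 0.853, 3: 0.923, 4: 1.000}, 0.610, 6.39),
        ScreeningStrategy(
            2, "EMR/symptoms/PhysicalExam", {1: 0.250, 2: 0.853, 3: 0.949, 4: 1.000}, 0.617, 15.17
        ),
        ScreeningStrategy(
            3,
            "EMR/symptoms/PhysicalExam/NTproBNP",
            {1: 0.250, 2: 0.879, 3: 0.897, 4: 1.000},
            0.652,
            36.67,
        ),
        ScreeningStrategy(
            4,
            "EMR/symptoms/PhysicalExam/NTproBNP/ECG",
            {1: 0.500, 2: 0.862, 3: 0.897, 4: 1.000},
            0.676,
            61.77,
        ),
        ScreeningStrategy(
            5, "Echocardiography", {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}, 1.0, 0.0, direct_echo=True
        ),
    ]


def emr_symptoms_profile(annual_gp_cost: float | None = None) -> ScreeningStrategy:
    """The EMR/symptoms profile used for the annual follow-up assessment.

    By default the full per-screen GP cost of strategy 1 is charged every
    year; ``annual_gp_cost`` overrides it (e.g. for a reduced
    within-consultation tariff).
    """
    s1 = default_strategies()[1]
    if annual_gp_cost is None:
        return s1
    return replace(s1, gp_screen_cost=float(annual_gp_cost))


# ---------------------------------------------------------------------------
# Unprinted inputs: hand-tuned synthetic defaults
# ---------------------------------------------------------------------------

#: Hand-tuned 1-month NYHA transition matrix (rows/cols = NYHA I..IV) for
#: ~65-year-old HF patients on therapy.  Worsening mass sits above the
#: diagonal, a small improvement mass (including IV -> I) below it.  Tuned so
#: the full model's life/QALY expectancies land in the published range;
#: version-frozen — regenerate only via the calibration helper.
DEFAULT_NYHA_MONTHLY: np.ndarray = np.array(
    [
        [0.951504, 0.040000, 0.007200, 0.001296],
        [0.020000, 0.932800, 0.040000, 0.007200],
        [0.003600, 0.020000, 0.936400, 0.040000],
        [0.000648, 0.003600, 0.020000, 0.975752],
    ]
)

#: Hospitalization hazard ratios per NYHA class relative to NYHA I, used by
#: the derived (non-fixture) HF-cost path.
DEFAULT_HOSP_HAZARD_RATIOS: dict[int, float] = {1: 1.0, 2: 1.2, 3: 1.8, 4: 5.0}

#: Annual drug-class unit costs (EUR), Dutch generic price level.
DEFAULT_DRUG_ANNUAL_COST: dict[str, float] = {"ace_inhibitor": 45.0, "beta_blocker": 60.0}

#: Age-band multipliers for HF mortality and NYHA worsening (band lower
#: bound -> multiplier), emulating the age stratification of an HF survival
#: model (bands 60-70 / 70-80 / 80+, reference band 60-70).
DEFAULT_MORTALITY_AGE_SCALE: dict[int, float] = {60: 1.0, 70: 1.4, 80: 2.0}

#: Gompertz log-slope of the synthetic background-mortality life table
#: (mortality doubles roughly every 7.5 years, typical of ages 60+).
DEFAULT_GOMPERTZ_RATE = 0.092


def gompertz_mortality_table(
    anchor: float, rate: float = DEFAULT_GOMPERTZ_RATE, ages: range = range(60, 111)
) -> dict[int, float]:
    """Annual death probability by age, ``anchor * exp(rate*(age-60))`` capped at 0.99.

    ``anchor`` is the annual probability at age 60.
    """
    if anchor <= 0 or not math.isfinite(anchor):
        raise ValueError(f"anchor must be positive, got {anchor}")
    return {a: min(0.99, anchor * math.exp(rate * (a - ages.start))) for a in ages}


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Every input of the cohort model for one gender.

    Maps over HF states are keyed by ``(nyha_class, detected)`` with
    ``detected`` a bool; utilities are keyed by :class:`HealthState` (death
    states carry utility 0 implicitly).
    """

    gender: str
    hf_incidence_per_100k: float
    background_mortality_annual: float | Mapping[int, float]
    hf_mortality_annual: dict[tuple[int, bool], float]
    baseline_hf_distribution: dict[tuple[int, bool], float]
    annual_hf_cost: dict[tuple[int, bool], float]
    medication_prescription: dict[tuple[str, bool], float]
    utilities: dict[HealthState, float]
    nyha_monthly_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_NYHA_MONTHLY.copy()
    )
    start_age: float = 60.0
    cycle_length: float = 0.25
    max_age: float = 110.0
    diabetes_incidence_multiplier: float = 1.0
    mortality_age_scale: dict[int, float] = field(default_factory=lambda: {60: 1.0})
    hosp_hazard_ratio_by_nyha: dict[int, float] | None = None
    drug_annual_cost: dict[str, float] | None = None
    base_hosp_nursing_annual_cost: float | None = None
    echo_cost: float = 169.38
    ecg_stress_cost: float = 94.75
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    hfpef_fraction: float = 0.826
    hfref_treatment_hr: float = 0.90
    hfpef_relative_effectiveness: float = 0.0
    baseline_detection: str = "all_undetected"  # or "as_recorded"
    annual_screen_gp_cost: float | None = None
    half_cycle_correction: bool = False

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check every invariant; raise :class:`ValidationError` naming the field."""
        if self.gender not in ("male", "female"):
            raise ValidationError(f"gender: {self.gender!r} not in {{male, female}}")
        if self.cycle_length <= 0:
            raise ValidationError(f"cycle_length: {self.cycle_length} must be > 0")
        if self.hf_incidence_per_100k < 0:
            raise ValidationError("hf_incidence_per_100k: negative")
        if self.diabetes_incidence_multiplier < 1.0:
            raise ValidationError(
                f"diabetes_incidence_multiplier: {self.diabetes_incidence_multiplier} must be >= 1"
            )
        for name, value in [("echo_cost", self.echo_cost), ("ecg_stress_cost", self.ecg_stress_cost)]:
            if value < 0:
                raise ValidationError(f"{name}: {value} < 0")
        for name, rate in [
            ("discount_rate_costs", self.discount_rate_costs),
            ("discount_rate_effects", self.discount_rate_effects),
        ]:
            if rate < 0:
                raise ValidationError(f"{name}: {rate} < 0")
        if not 0.0 <= self.hfpef_fraction <= 1.0:
            raise ValidationError(f"hfpef_fraction: {self.hfpef_fraction} not in [0,1]")
        if not 0.0 <= self.hfpef_relative_effectiveness <= 1.0:
            raise ValidationError(
                f"hfpef_relative_effectiveness: {self.hfpef_relative_effectiveness} not in [0,1]"
            )
        if self.hfref_treatment_hr <= 0:
            raise ValidationError(f"hfref_treatment_hr: {self.hfref_treatment_hr} must be > 0")

        for age, p in self._background_items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"background_mortality_annual[{age}]: {p} not in [0,1]")

        for (k, d), p in self.hf_mortality_annual.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"hf_mortality_annual[NYHA{k},{_dkey(d)}]: {p} not in [0,1]")
        for d in (True, False):
            probs = [self.hf_mortality_annual[(k, d)] for k in NYHA_CLASSES]
            if any(b < a for a, b in zip(probs, probs[1:])):
                raise ValidationError(
                    f"hf_mortality_annual ({_dkey(d)}): not non-decreasing in NYHA class"
                )

        total = 0.0
        for (k, d), p in self.baseline_hf_distribution.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"baseline_hf_distribution[NYHA{k},{_dkey(d)}]: {p} not in [0,1]"
                )
            total += p
        if total > 1.0 + 1e-9:
            raise ValidationError(f"baseline_hf_distribution: sums to {total} > 1")

        m = np.asarray(self.nyha_monthly_transition, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"nyha_monthly_transition: shape {m.shape} != (4, 4)")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValidationError("nyha_monthly_transition: entries outside [0,1]")
        rowsum = m.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValidationError(
                f"nyha_monthly_transition: row sums {rowsum.tolist()} deviate from 1"
            )

        for (k, d), c in self.annual_hf_cost.items():
            if c < 0:
                raise ValidationError(f"annual_hf_cost[NYHA{k},{_dkey(d)}]: {c} < 0")
        for (drug, d), p in self.medication_prescription.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"medication_prescription[{drug},{_dkey(d)}]: {p} not in [0,1]"
                )
        for state, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"utilities[{state.name}]: {u} not in [0,1]")
        for band, mult in self.mortality_age_scale.items():
            if mult <= 0:
                raise ValidationError(f"mortality_age_scale[{band}]: {mult} must be > 0")
        if self.baseline_detection not in ("all_undetected", "as_recorded"):
            raise ValidationError(
                f"baseline_detection: {self.baseline_detection!r} unknown"
            )
        return self

    # -- lookups ------------------------------------------------------------

    def _background_items(self):
        if isinstance(self.background_mortality_annual, Mapping):
            return list(self.background_mortality_annual.items())
        return [("scalar", self.background_mortality_annual)]

    def background_mortality_at(self, age: float) -> float:
        """Annual non-HF death probability at ``age`` (table lookup or scalar)."""
        bg = self.background_mortality_annual
        if isinstance(bg, Mapping):
            keys = sorted(bg)
            idx = int(age)
            if idx <= keys[0]:
                return float(bg[keys[0]])
            if idx >= keys[-1]:
                return float(bg[keys[-1]])
            return float(bg[idx]) if idx in bg else float(bg[max(k for k in keys if k <= idx)])
        return float(bg)

    def age_scale(self, age: float) -> float:
        """Age-band multiplier for HF mortality / NYHA worsening."""
        bands = sorted(self.mortality_age_scale)
        applicable = [b for b in bands if b <= age]
        band = applicable[-1] if applicable else bands[0]
        return float(self.mortality_age_scale[band])

    def utility_of(self, state: HealthState) -> float:
        if state in DEATH_STATES:
            return 0.0
        return float(self.utilities[state])

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- config round trip --------------------------------------------------

    def to_config_dict(self) -> dict[str, Any]:
        """Plain-python dict mirroring the YAML config schema."""
        bg = self.background_mortality_annual
        cfg: dict[str, Any] = {
            "gender": self.gender,
            "start_age": self.start_age,
            "cycle_length": self.cycle_length,
            "max_age": self.max_age,
            "hf_incidence_per_100k": self.hf_incidence_per_100k,
            "diabetes_incidence_multiplier": self.diabetes_incidence_multiplier,
            "background_mortality_annual": dict(bg) if isinstance(bg, Mapping) else bg,
            "hf_mortality_annual": _nested(self.hf_mortality_annual),
            "mortality_age_scale": dict(self.mortality_age_scale),
            "baseline_hf_distribution": _nested(self.baseline_hf_distribution),
            "nyha_monthly_transition": np.asarray(self.nyha_monthly_transition).tolist(),
            "annual_hf_cost": _nested(self.annual_hf_cost),
            "medication_prescription": _nested_drug(self.medication_prescription),
            "echo_cost": self.echo_cost,
            "ecg_stress_cost": self.ecg_stress_cost,
            "utilities": {s.name: u for s, u in self.utilities.items()},
            "discount_rate_costs": self.discount_rate_costs,
            "discount_rate_effects": self.discount_rate_effects,
            "hfpef_fraction": self.hfpef_fraction,
            "hfref_treatment_hr": self.hfref_treatment_hr,
            "hfpef_relative_effectiveness": self.hfpef_relative_effectiveness,
            "baseline_detection": self.baseline_detection,
            "half_cycle_correction": self.half_cycle_correction,
        }
        if self.hosp_hazard_ratio_by_nyha is not None:
            cfg["hosp_hazard_ratio_by_nyha"] = {
                f"NYHA{k}": v for k, v in self.hosp_hazard_ratio_by_nyha.items()
            }
        if self.drug_annual_cost is not None:
            cfg["drug_annual_cost"] = dict(self.drug_annual_cost)
        if self.base_hosp_nursing_annual_cost is not None:
            cfg["base_hosp_nursing_annual_cost"] = self.base_hosp_nursing_annual_cost
        if self.annual_screen_gp_cost is not None:
            cfg["annual_screen_gp_cost"] = self.annual_screen_gp_cost
        return cfg

    @classmethod
    def from_config_dict(cls, cfg: Mapping[str, Any]) -> "ParameterSet":
        cfg = dict(cfg)
        required = [
            "gender",
            "hf_incidence_per_100k",
            "background_mortality_annual",
            "hf_mortality_annual",
            "baseline_hf_distribution",
            "annual_hf_cost",
            "medication_prescription",
            "utilities",
        ]
        missing = [k for k in required if k not in cfg]
        if missing:
            raise ConfigurationError(f"config missing required fields: {missing}")
        try:
            utilities = {HealthState[name]: float(u) for name, u in cfg["utilities"].items()}
        except KeyError as exc:
            raise ConfigurationError(f"utilities: unknown health state {exc}") from None
        kwargs: dict[str, Any] = dict(
            gender=cfg["gender"],
            hf_incidence_per_100k=float(cfg["hf_incidence_per_100k"]),
            background_mortality_annual=_parse_background(cfg["background_mortality_annual"]),
            hf_mortality_annual=_flat(cfg["hf_mortality_annual"]),
            baseline_hf_distribution=_flat(cfg["baseline_hf_distribution"]),
            annual_hf_cost=_flat(cfg["annual_hf_cost"]),
            medication_prescription=_flat_drug(cfg["medication_prescription"]),
            utilities=utilities,
        )
        if "nyha_monthly_transition" in cfg:
            kwargs["nyha_monthly_transition"] = np.asarray(
                cfg["nyha_monthly_transition"], dtype=float
            )
        if "mortality_age_scale" in cfg:
            kwargs["mortality_age_scale"] = {
                int(k): float(v) for k, v in cfg["mortality_age_scale"].items()
            }
        if "hosp_hazard_ratio_by_nyha" in cfg:
            kwargs["hosp_hazard_ratio_by_nyha"] = {
                int(str(k).removeprefix("NYHA")): float(v)
                for k, v in cfg["hosp_hazard_ratio_by_nyha"].items()
            }
        if "drug_annual_cost" in cfg:
            kwargs["drug_annual_cost"] = {k: float(v) for k, v in cfg["drug_annual_cost"].items()}
        for key in (
            "start_age",
            "cycle_length",
            "max_age",
            "diabetes_incidence_multiplier",
            "base_hosp_nursing_annual_cost",
            "echo_cost",
            "ecg_stress_cost",
            "discount_rate_costs",
            "discount_rate_effects",
            "hfpef_fraction",
            "hfref_treatment_hr",
            "hfpef_relative_effectiveness",
            "annual_screen_gp_cost",
        ):
            if key in cfg and cfg[key] is not None:
                kwargs[key] = float(cfg[key])
        for key in ("baseline_detection",):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "half_cycle_correction" in cfg:
            kwargs["half_cycle_correction"] = bool(cfg["half_cycle_correction"])
        return cls(**kwargs)


def _dkey(detected: bool) -> str:
    return "detected" if detected else "undetected"


def _nested(flat: Mapping[tuple[int, bool], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (k, d), v in sorted(flat.items()):
        out.setdefault(f"NYHA{k}", {})[_dkey(d)] = float(v)
    return out


def _flat(nested: Mapping[str, Mapping[str, float]]) -> dict[tuple[int, bool], float]:
    out: dict[tuple[int, bool], float] = {}
    for key, sub in nested.items():
        k = int(str(key).removeprefix("NYHA"))
        for dname, v in sub.items():
            out[(k, dname == "detected")] = float(v)
    return out


def _nested_drug(flat: Mapping[tuple[str, bool], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (drug, d), v in sorted(flat.items()):
        out.setdefault(drug, {})[_dkey(d)] = float(v)
    return out


def _flat_drug(nested: Mapping[str, Mapping[str, float]]) -> dict[tuple[str, bool], float]:
    return {
        (drug, dname == "detected"): float(v)
        for drug, sub in nested.items()
        for dname, v in sub.items()
    }


def _parse_background(raw: Any) -> float | dict[int, float]:
    if isinstance(raw, Mapping):
        return {int(a): float(p) for a, p in raw.items()}
    return float(raw)


# ---------------------------------------------------------------------------
# Built-in fixtures: the published Dutch point estimates
# ---------------------------------------------------------------------------

_UTILITIES = {
    HealthState.DIAB_NO_HF: 0.868,
    HealthState.NYHA1_D: 0.855,
    HealthState.NYHA1_U: 0.817,
    HealthState.NYHA2_D: 0.790,
    HealthState.NYHA2_U: 0.739,
    HealthState.NYHA3_D: 0.734,
    HealthState.NYHA3_U: 0.685,
    HealthState.NYHA4_D: 0.665,
    HealthState.NYHA4_U: 0.683,
}

_BASELINE_PREVALENCE = {
    (1, True): 0.007,
    (1, False): 0.000,
    (2, True): 0.148,
    (2, False): 0.142,
    (3, True): 0.047,
    (3, False): 0.031,
    (4, True): 0.000,
    (4, False): 0.000,
}


def _make_fixture(gender: str) -> ParameterSet:
    men = gender == "male"
    hf_mortality = (
        {
            (1, True): 0.042, (1, False): 0.043,
            (2, True): 0.066, (2, False): 0.067,
            (3, True): 0.103, (3, False): 0.105,
            (4, True): 0.159, (4, False): 0.163,
        }
        if men
        else {
            (1, True): 0.035, (1, False): 0.036,
            (2, True): 0.056, (2, False): 0.057,
            (3, True): 0.087, (3, False): 0.089,
            (4, True): 0.137, (4, False): 0.139,
        }
    )
    annual_cost = (
        {
            (1, True): 1777.0, (1, False): 1786.0,
            (2, True): 2099.0, (2, False): 2114.0,
            (3, True): 3235.0, (3, False): 3275.0,
            (4, True): 8752.0, (4, False): 8912.0,
        }
        if men
        else {
            (1, True): 1172.0, (1, False): 1100.0,
            (2, True): 1370.0, (2, False): 1302.0,
            (3, True): 2070.0, (3, False): 2018.0,
            (4, True): 5470.0, (4, False): 5490.0,
        }
    )
    medication = (
        {
            ("ace_inhibitor", True): 0.53, ("ace_inhibitor", False): 0.53,
            ("beta_blocker", True): 0.57, ("beta_blocker", False): 0.50,
        }
        if men
        else {
            ("ace_inhibitor", True): 0.27, ("ace_inhibitor", False): 0.18,
            ("beta_blocker", True): 0.50, ("beta_blocker", False): 0.50,
        }
    )
    anchor = 0.010 if men else 0.007
    return ParameterSet(
        gender=gender,
        hf_incidence_per_100k=658.0 if men else 666.0,
        background_mortality_annual=gompertz_mortality_table(anchor),
        hf_mortality_annual=hf_mortality,
        baseline_hf_distribution=dict(_BASELINE_PREVALENCE),
        annual_hf_cost=annual_cost,
        medication_prescription=medication,
        utilities=dict(_UTILITIES),
        mortality_age_scale=dict(DEFAULT_MORTALITY_AGE_SCALE),
        hosp_hazard_ratio_by_nyha=dict(DEFAULT_HOSP_HAZARD_RATIOS),
        drug_annual_cost=dict(DEFAULT_DRUG_ANNUAL_COST),
    ).validate()


_FIXTURES = {"dutch_men": "male", "dutch_women": "female"}


def fixture(name: str) -> ParameterSet:
    """Return a built-in parameter fixture (``dutch_men`` or ``dutch_women``)."""
    try:
        gender = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return _make_fixture(gender)


def load_parameters(source: str | Mapping[str, Any]) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    ``source`` may be a built-in fixture name, a path to a YAML config file,
    or an already-parsed mapping.  Fields absent from a mapping fall back to
    dataclass defaults; truly required fields raise
    :class:`ConfigurationError`.
    """
    if isinstance(source, Mapping):
        return ParameterSet.from_config_dict(source).validate()
    if source in _FIXTURES:
        return fixture(source)
    try:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigurationError(
            f"{source!r} is neither a built-in fixture nor a readable config file"
        ) from None
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {source!r}: {exc}") from None
    if not isinstance(cfg, Mapping):
        raise ConfigurationError(f"{source!r} did not parse to a mapping")
    return ParameterSet.from_config_dict(cfg).validate()


def write_config(params: ParameterSet, path: str) -> None:
    """Serialize a :class:`ParameterSet` to a YAML config file (round-trips)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_config_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# PSA distribution specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one model input.

    ``family`` is ``beta`` (two shapes), ``gamma`` (shape, scale),
    ``dirichlet`` (>=2 concentrations) or ``fixed`` (no sampling).
    ``target`` is a dotted path naming the field the draw replaces, e.g.
    ``"echo_cost"``, ``"utilities.NYHA2_D"``,
    ``"annual_hf_cost.NYHA3.undetected"`` or
    ``"strategies.1.sensitivity.2"``.
    """

    family: str
    parameters: tuple[float, ...]
    target: str = ""

    def __post_init__(self) -> None:
        fam = self.family
        p = self.parameters
        if fam == "beta":
            if len(p) != 2 or min(p) <= 0:
                raise ValidationError(f"beta spec needs two positive shapes, got {p}")
        elif fam == "gamma":
            if len(p) != 2 or min(p) <= 0:
                raise ValidationError(f"gamma spec needs positive shape and scale, got {p}")
        elif fam == "dirichlet":
            if len(p) < 2 or min(p) <= 0:
                raise ValidationError(f"dirichlet spec needs >=2 positive concentrations, got {p}")
        elif fam == "fixed":
            if p:
                raise ValidationError("fixed spec takes no parameters")
        else:
            raise ValidationError(f"unknown distribution family {fam!r}")

    def mean(self) -> float | np.ndarray | None:
        """Analytic mean (``None`` for fixed: the base value is kept)."""
        a = np.asarray(self.parameters, dtype=float)
        if self.family == "beta":
            return a[0] / (a[0] + a[1])
        if self.family == "gamma":
            return a[0] * a[1]
        if self.family == "dirichlet":
            return a / a.sum()
        return None


def gamma_spec_from_mean(mean_cost: float, target: str = "") -> DistributionSpec:
    """Variance-equals-mean gamma for a cost parameter (shape=mean, scale=1)."""
    if not mean_cost > 0:
        raise ValueError(f"mean_cost must be > 0, got {mean_cost}")
    return DistributionSpec("gamma", (float(mean_cost), 1.0), target)


def beta_spec_from_counts(
    true_positives: float, false_negatives: float, target: str = ""
) -> DistributionSpec:
    """Beta spec for a sensitivity/specificity from (pseudo-)counts.

    Shapes are (TP, FN), so the mean equals TP/(TP+FN), the observed
    proportion.  A degenerate proportion (either count zero) is treated as
    fixed — an observed 0.000 or 1.000 is not sampled.
    """
    if true_positives < 0 or false_negatives < 0:
        raise ValueError("counts must be non-negative")
    if true_positives + false_negatives <= 0:
        raise ValueError("at least one count must be positive")
    if true_positives == 0 or false_negatives == 0:
        return DistributionSpec("fixed", (), target)
    return DistributionSpec("beta", (float(true_positives), float(false_negatives)), target)


def beta_spec_from_moments(mean: float, se: float, target: str = "") -> DistributionSpec:
    """Method-of-moments beta for a utility with mean ``mean`` and SE ``se``.

    Falls back to fixed when the moments are infeasible for a beta
    (``se**2 >= mean*(1-mean)``) or the mean is degenerate.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"mean must be in [0,1], got {mean}")
    var = se * se
    if mean in (0.0, 1.0) or var <= 0 or var >= mean * (1 - mean):
        return DistributionSpec("fixed", (), target)
    nu = mean * (1 - mean) / var - 1
    return DistributionSpec("beta", (mean * nu, (1 - mean) * nu), target)


def export_parameter_table(
    params: ParameterSet, strategies: list[ScreeningStrategy] | None = None
) -> "pd.DataFrame":
    """One row per parameter: name, point value, PSA family and parameters."""
    import pandas as pd

    from .uncertainty import default_psa_specs

    strategies = strategies if strategies is not None else default_strategies()
    specs = {s.target: s for s in default_psa_specs(params, strategies)}
    rows: list[dict[str, Any]] = []

    def add(name: str, value: float) -> None:
        spec = specs.get(name)
        rows.append(
            {
                "parameter": name,
                "value": value,
                "distribution": spec.family if spec else "fixed",
                "distribution_parameters": spec.parameters if spec else (),
            }
        )

    add("hf_incidence_per_100k", params.hf_incidence_per_100k)
    add("background_mortality_annual@60", params.background_mortality_at(params.start_age))
    for (k, d), v in sorted(params.hf_mortality_annual.items()):
        add(f"hf_mortality_annual.NYHA{k}.{_dkey(d)}", v)
    for (k, d), v in sorted(params.baseline_hf_distribution.items()):
        add(f"baseline_hf_distribution.NYHA{k}.{_dkey(d)}", v)
    for (k, d), v in sorted(params.annual_hf_cost.items()):
        add(f"annual_hf_cost.NYHA{k}.{_dkey(d)}", v)
    for state in sorted(params.utilities):
        add(f"utilities.{state.name}", params.utilities[state])
    add("echo_cost", params.echo_cost)
    add("ecg_stress_cost", params.ecg_stress_cost)
    for s in strategies:
        for k in NYHA_CLASSES:
            add(f"strategies.{s.id}.sensitivity.{k}", s.sensitivity_by_nyha[k])
        add(f"strategies.{s.id}.specificity", s.specificity)
        add(f"strategies.{s.id}.gp_screen_cost", s.gp_screen_cost)
    return pd.DataFrame(rows)
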