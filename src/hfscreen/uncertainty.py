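"""Probabilistic sensitivity analysis and scenario grids.

Second-order uncertainty is propagated by Monte-Carlo sampling of the input
distributions (beta for test accuracies and utilities, variance-equals-mean
gamma for costs, Dirichlet for the baseline prevalence block; incidence and
mortality are fixed).  Every strategy is evaluated on the *same* sampled
parameter set within a draw, so incremental comparisons are meaningful.  The
cloud feeds cost-effectiveness acceptability curves (probability each
strategy maximizes net monetary benefit as a function of willingness to
pay).  The scenario grid reruns the deterministic pipeline across HFpEF
treatment-effectiveness values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import TransitionMatrixCache, run_cohort
from .economics import accrue
from .cea import icer
from .parameters import (
    ConfigurationError,
    DistributionSpec,
    ParameterSet,
    ScreeningStrategy,
    beta_spec_from_counts,
    beta_spec_from_moments,
    gamma_spec_from_mean,
)
from .pipeline import evaluate_strategies
from .states import HealthState, NYHA_CLASSES

__all__ = [
    "PsaCloud",
    "CeacCurve",
    "default_psa_specs",
    "sample_parameters",
    "sample_strategies",
    "run_psa",
    "ceac",
    "scenario_grid",
]

#: Study dimensions behind the reconstructed pseudo-counts of the beta
#: distributions: cohort size, observed HF prevalence, and the utility
#: standard error used for method-of-moments betas.
DEFAULT_COHORT_SIZE = 581
DEFAULT_HF_PREVALENCE = 0.277
DEFAULT_UTILITY_SE = 0.02

# ParameterSet fields whose perturbation would invalidate a shared
# transition-matrix cache.
_MATRIX_FIELDS = (
    "hf_incidence_per_100k",
    "diabetes_incidence_multiplier",
    "background_mortality_annual",
    "hf_mortality_annual",
    "mortality_age_scale",
    "nyha_monthly_transition",
    "hfpef",
    "hfref",
)


# ---------------------------------------------------------------------------
# Spec construction
# ---------------------------------------------------------------------------


def default_psa_specs(
    params: ParameterSet,
    strategies: Iterable[ScreeningStrategy],
    cohort_size: int = DEFAULT_COHORT_SIZE,
    hf_prevalence: float = DEFAULT_HF_PREVALENCE,
    utility_se: float = DEFAULT_UTILITY_SE,
) -> list[DistributionSpec]:
    """The standard sampling plan.

    Sensitivities and specificities get beta distributions whose
    pseudo-counts are reconstructed from the cohort size: HF cases are split
    over NYHA classes by the baseline prevalence mix, non-cases inform the
    specificities.  Utilities get method-of-moments betas, costs
    variance-equals-mean gammas, the baseline prevalence block one Dirichlet
    with concentrations proportional to counts.  Exact 0/1 accuracies are
    degenerate and stay fixed.
    """
    specs: list[DistributionSpec] = []

    block_total = sum(params.baseline_hf_distribution.values())
    class_share = {
        k: sum(
            p for (kk, _d), p in params.baseline_hf_distribution.items() if kk == k
        )
        / block_total
        for k in NYHA_CLASSES
    }
    n_cases = cohort_size * hf_prevalence
    n_controls = cohort_size * (1.0 - hf_prevalence)

    for s in strategies:
        if s.id == 0:
            continue  # no screening: nothing to sample
        for k in NYHA_CLASSES:
            sens = s.sensitivity_by_nyha[k]
            n_k = n_cases * class_share[k]
            if n_k <= 0 or sens in (0.0, 1.0):
                continue
            specs.append(
                beta_spec_from_counts(
                    sens * n_k, (1.0 - sens) * n_k, target=f"strategies.{s.id}.sensitivity.{k}"
                )
            )
        if 0.0 < s.specificity < 1.0:
            specs.append(
                beta_spec_from_counts(
                    s.specificity * n_controls,
                    (1.0 - s.specificity) * n_controls,
                    target=f"strategies.{s.id}.specificity",
                )
            )
        if s.gp_screen_cost > 0:
            specs.append(
                gamma_spec_from_mean(s.gp_screen_cost, target=f"strategies.{s.id}.gp_screen_cost")
            )

    specs.append(gamma_spec_from_mean(params.echo_cost, target="echo_cost"))
    specs.append(gamma_spec_from_mean(params.ecg_stress_cost, target="ecg_stress_cost"))
    for (k, det), c in sorted(params.annual_hf_cost.items()):
        if c > 0:
            name = "detected" if det else "undetected"
            specs.append(gamma_spec_from_mean(c, target=f"annual_hf_cost.NYHA{k}.{name}"))
    for state in sorted(params.utilities):
        specs.append(
            beta_spec_from_moments(
                params.utilities[state], utility_se, target=f"utilities.{state.name}"
            )
        )

    nonzero = _prevalence_cells(params)
    if len(nonzero) >= 2:
        alphas = tuple(params.baseline_hf_distribution[c] * cohort_size for c in nonzero)
        specs.append(DistributionSpec("dirichlet", alphas, target="baseline_hf_distribution"))
    return [s for s in specs if s.family != "fixed"]


def _prevalence_cells(params: ParameterSet) -> list[tuple[int, bool]]:
    """Canonical (sorted) order of the nonzero baseline-prevalence cells."""
    return sorted(c for c, p in params.baseline_hf_distribution.items() if p > 0)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float | np.ndarray:
    if spec.family == "beta":
        return float(rng.beta(*spec.parameters))
    if spec.family == "gamma":
        return float(rng.gamma(spec.parameters[0], spec.parameters[1]))
    if spec.family == "dirichlet":
        return rng.dirichlet(spec.parameters)
    raise AssertionError(spec.family)  # fixed specs never reach here


def sample_parameters(
    base: ParameterSet,
    specs: Iterable[DistributionSpec],
    rng_seed: int | np.random.Generator,
) -> ParameterSet:
    """One joint draw of all parameter-level specs, applied to a copy of ``base``.

    Specs targeting screening-strategy fields are ignored here (see
    :func:`sample_strategies`); any other unresolvable target raises
    :class:`ConfigurationError`.  Fixed specs leave the base value untouched.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out = base.copy()
    for spec in specs:
        if spec.family == "fixed" or spec.target.startswith("strategies."):
            continue
        _apply_to_params(out, spec, _draw(spec, rng))
    return out


def _apply_to_params(params: ParameterSet, spec: DistributionSpec, value) -> None:
    path = spec.target.split(".")
    if path == ["baseline_hf_distribution"]:
        cells = _prevalence_cells(params)
        if len(cells) != len(spec.parameters):
            raise ConfigurationError(
                "dirichlet concentration count does not match nonzero prevalence cells"
            )
        total = sum(params.baseline_hf_distribution[c] for c in cells)
        for cell, share in zip(cells, value):
            params.baseline_hf_distribution[cell] = float(share) * total
        return
    if path[0] in ("echo_cost", "ecg_stress_cost") and len(path) == 1:
        setattr(params, path[0], float(value))
        return
    if path[0] == "utilities" and len(path) == 2:
        try:
            state = HealthState[path[1]]
        except KeyError:
            raise ConfigurationError(f"unknown health state in target {spec.target!r}") from None
        params.utilities[state] = float(value)
        return
    if path[0] in ("annual_hf_cost", "hf_mortality_annual") and len(path) == 3:
        k = int(path[1].removeprefix("NYHA"))
        det = path[2] == "detected"
        getattr(params, path[0])[(k, det)] = float(value)
        return
    raise ConfigurationError(f"spec targets unknown field {spec.target!r}")


def sample_strategies(
    strategies: Sequence[ScreeningStrategy],
    specs: Iterable[DistributionSpec],
    rng: np.random.Generator,
) -> list[ScreeningStrategy]:
    """One joint draw of all strategy-level specs (sensitivity/specificity/cost)."""
    by_id = {s.id: s for s in strategies}
    sens: dict[int, dict[int, float]] = {s.id: dict(s.sensitivity_by_nyha) for s in strategies}
    fields: dict[int, dict[str, float]] = {s.id: {} for s in strategies}
    for spec in specs:
        if spec.family == "fixed" or not spec.target.startswith("strategies."):
            continue
        path = spec.target.split(".")
        sid = int(path[1])
        if sid not in by_id:
            raise ConfigurationError(f"spec targets unknown strategy in {spec.target!r}")
        value = float(_draw(spec, rng))
        if path[2] == "sensitivity":
            sens[sid][int(path[3])] = value
        elif path[2] == "specificity":
            fields[sid]["specificity"] = value
        elif path[2] == "gp_screen_cost":
            fields[sid]["gp_screen_cost"] = value
        else:
            raise ConfigurationError(f"spec targets unknown field {spec.target!r}")
    return [
        replace(s, sensitivity_by_nyha=sens[s.id], **fields[s.id]) for s in strategies
    ]


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


@dataclass
class PsaCloud:
    """Per-draw, per-strategy (QALYs, cost) pairs from the PSA."""

    samples: np.ndarray  # shape (n_samples, n_strategies, 2): [:, :, 0]=QALYs, 1=cost
    strategy_ids: list[int]
    n_samples: int
    seed: int
    rejections: int = 0

    def qalys(self) -> np.ndarray:
        return self.samples[:, :, 0]

    def costs(self) -> np.ndarray:
        return self.samples[:, :, 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in range(self.n_samples):
            for j, sid in enumerate(self.strategy_ids):
                rows.append(
                    {
                        "draw": d,
                        "strategy": sid,
                        "qalys": self.samples[d, j, 0],
                        "cost": self.samples[d, j, 1],
                    }
                )
        return pd.DataFrame(rows)


def run_psa(
    strategies: Sequence[ScreeningStrategy],
    base: ParameterSet,
    specs: Iterable[DistributionSpec] | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> PsaCloud:
    """Monte-Carlo PSA: ``n`` joint draws, all strategies per draw.

    Draws yielding an invalid parameter set are rejected and redrawn (the
    count is recorded on the cloud).  Identical seeds reproduce the cloud
    bit-for-bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = list(specs) if specs is not None else default_psa_specs(base, strategies)
    rng = np.random.default_rng(seed)

    share_cache = not any(s.target.startswith(_MATRIX_FIELDS) for s in specs)
    base_cache = TransitionMatrixCache(base) if share_cache else None

    samples = np.empty((n, len(strategies), 2))
    rejections = 0
    for d in range(n):
        for _attempt in range(1000):
            try:
                params = sample_parameters(base, specs, rng)
                params.validate()
                strats = sample_strategies(strategies, specs, rng)
                break
            except (ValueError, ConfigurationError):
                rejections += 1
        else:
            raise RuntimeError("PSA: could not draw a valid parameter set in 1000 attempts")
        cache = base_cache if share_cache else TransitionMatrixCache(params)
        for j, s in enumerate(strats):
            res = accrue(run_cohort(s, params, matrix_cache=cache), params)
            samples[d, j, 0] = res.qalys
            samples[d, j, 1] = res.total_cost
    return PsaCloud(samples, [s.id for s in strategies], n, seed, rejections)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------


@dataclass
class CeacCurve:
    """Probability each strategy is optimal, per willingness-to-pay value."""

    wtp_grid: np.ndarray
    prob_optimal: dict[int, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.wtp_grid})
        for sid, probs in self.prob_optimal.items():
            df[f"strategy_{sid}"] = probs
        return df


def ceac(cloud: PsaCloud, wtp_grid: Sequence[float]) -> CeacCurve:
    """Acceptability curves: per WTP, the fraction of draws in which each
    strategy has the highest net monetary benefit (exact ties split equally)."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    q, c = cloud.qalys(), cloud.costs()
    probs = np.empty((grid.size, len(cloud.strategy_ids)))
    for i, w in enumerate(grid):
        nmb = w * q - c
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(grid, {sid: probs[:, j] for j, sid in enumerate(cloud.strategy_ids)})


# ---------------------------------------------------------------------------
# HFpEF treatment-effectiveness scenario grid
# ---------------------------------------------------------------------------

SCENARIO_COMPARISONS: tuple[tuple[str, int, int], ...] = (
    ("1 vs 0", 1, 0),
    ("5 vs 1", 5, 1),
)


def scenario_grid(
    strategies: Sequence[ScreeningStrategy],
    base: ParameterSet,
    rho_values: Sequence[float],
) -> pd.DataFrame:
    """Deterministic ICERs across HFpEF relative-effectiveness values.

    For each rho the full pipeline is rerun with
    ``hfpef_relative_effectiveness = rho`` and the two frontier comparisons
    (EMR/symptoms vs no screening; echocardiography vs EMR/symptoms) are
    tabulated.
    """
    rows = []
    for rho in rho_values:
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {rho}")
        params = base.copy()
        params.hfpef_relative_effectiveness = float(rho)
        results = {r.strategy_id: r for r in evaluate_strategies(strategies, params)}
        for label, hi, lo in SCENARIO_COMPARISONS:
            if hi not in results or lo not in results:
                continue
            dq = results[hi].qalys - results[lo].qalys
            dc = results[hi].total_cost - results[lo].total_cost
            rows.append(
                {
                    "rho": float(rho),
                    "comparison": label,
                    "delta_qalys": dq,
                    "delta_cost": dc,
                    "icer": icer(dc, dq) if dq != 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
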