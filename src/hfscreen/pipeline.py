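"""Convenience wiring: run every strategy through the cohort model and value it."""

from __future__ import annotations

from typing import Iterable, Sequence

from .economics import EconResult, accrue
from .markov import TransitionMatrixCache, run_cohort
from .parameters import ParameterSet, ScreeningStrategy


def evaluate_strategies(
    strategies: Iterable[ScreeningStrategy],
    params: ParameterSet,
    matrix_cache: TransitionMatrixCache | None = None,
) -> list[EconResult]:
    """Deterministic full pipeline (cohort run + accrual) per strategy.

    All strategies share one transition-matrix cache: the per-cycle matrices
    depend only on the parameters, strategies differ in screening alone.
    """
    cache = matrix_cache or TransitionMatrixCache(params)
    return [accrue(run_cohort(s, params, matrix_cache=cache), params) for s in strategies]
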