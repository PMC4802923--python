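"""Incremental cost-effectiveness analysis over a set of strategy results.

Strategies are ranked by effect (QALYs); strongly dominated strategies (some
alternative is at least as effective and strictly cheaper, or strictly more
effective and no dearer) and extendedly dominated ones (their incremental
ratio exceeds that of the next frontier segment, so a mixture of neighbours
beats them) are excluded from the frontier, along which ICERs are strictly
increasing.  Net monetary benefit NMB = WTP x QALYs - cost identifies the
optimal strategy at a given willingness to pay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .economics import EconResult

__all__ = [
    "UndefinedICERError",
    "CeaResult",
    "icer",
    "net_monetary_benefit",
    "incremental_analysis",
    "optimal_strategy",
]

NONDOMINATED = "nondominated"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


class UndefinedICERError(ZeroDivisionError):
    """Zero effect difference: the comparison is a matter of dominance."""


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio, cost units per QALY."""
    if delta_effect == 0:
        raise UndefinedICERError("delta_effect is zero; ICER undefined")
    return delta_cost / delta_effect


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = wtp x QALYs - total cost (monetary units)."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * result.qalys - result.total_cost


@dataclass
class CeaResult:
    """Classification and frontier from an incremental analysis."""

    ordered_strategies: list[int]  # strategy ids sorted by increasing effect
    dominance: dict[int, str]
    frontier: list[tuple[int, float | None]]  # (strategy id, ICER vs previous)
    ties: list[tuple[int, int]] = field(default_factory=list)
    optimal_at: dict[float, int] = field(default_factory=dict)

    @property
    def n_dominated(self) -> int:
        return sum(1 for v in self.dominance.values() if v != NONDOMINATED)

    def frontier_ids(self) -> list[int]:
        return [sid for sid, _ in self.frontier]


def incremental_analysis(
    results: Iterable[EconResult], wtp_grid: Sequence[float] = ()
) -> CeaResult:
    """Rank strategies, classify dominance, and compute frontier ICERs.

    Identical (effect, cost) pairs are kept and flagged as ties; one member
    represents the pair on the frontier.
    """
    res = list(results)
    if not res:
        raise ValueError("need at least one strategy result")
    for r in res:
        if not (_finite(r.qalys) and _finite(r.total_cost)):
            raise ValueError(f"strategy {r.strategy_id}: non-finite effect or cost")

    order = sorted(res, key=lambda r: (r.qalys, r.total_cost))
    dominance = {r.strategy_id: NONDOMINATED for r in res}
    ties = [
        (a.strategy_id, b.strategy_id)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if a.qalys == b.qalys and a.total_cost == b.total_cost
    ]

    for r in res:
        for other in res:
            if other is r:
                continue
            if (other.qalys >= r.qalys and other.total_cost < r.total_cost) or (
                other.qalys > r.qalys and other.total_cost <= r.total_cost
            ):
                dominance[r.strategy_id] = STRONGLY_DOMINATED
                break

    tied_out = {b for _, b in ties}
    candidates = [
        r
        for r in order
        if dominance[r.strategy_id] == NONDOMINATED and r.strategy_id not in tied_out
    ]
    # iterative extended-dominance removal: drop interior points whose
    # incremental ratio is not below that of the following segment
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            lo, mid, hi = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_lo = icer(mid.total_cost - lo.total_cost, mid.qalys - lo.qalys)
            icer_hi = icer(hi.total_cost - mid.total_cost, hi.qalys - mid.qalys)
            if icer_lo >= icer_hi:
                dominance[mid.strategy_id] = EXTENDEDLY_DOMINATED
                del candidates[i]
                changed = True
                break

    frontier: list[tuple[int, float | None]] = []
    for i, r in enumerate(candidates):
        if i == 0:
            frontier.append((r.strategy_id, None))
        else:
            prev = candidates[i - 1]
            frontier.append(
                (r.strategy_id, icer(r.total_cost - prev.total_cost, r.qalys - prev.qalys))
            )

    optimal_at = {float(w): optimal_strategy(res, w) for w in wtp_grid}
    return CeaResult(
        ordered_strategies=[r.strategy_id for r in order],
        dominance=dominance,
        frontier=frontier,
        ties=ties,
        optimal_at=optimal_at,
    )


def optimal_strategy(results: Iterable[EconResult], wtp: float) -> int:
    """Strategy id maximizing net monetary benefit at ``wtp`` (ties: cheaper wins)."""
    return max(results, key=lambda r: (net_monetary_benefit(r, wtp), -r.total_cost)).strategy_id


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")
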