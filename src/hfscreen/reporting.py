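"""Report assembly: base-case tables, full runs, run manifests.

The base-case report mirrors the published layout: an absolute block (life
expectancy, QALYs, cost per strategy) and an incremental block (extra QALYs
and costs versus the current optimal comparator, dominance, ICER).  Values
are kept at full precision in the machine-readable output; rounding (whole
euros, 3-decimal QALYs) happens only in the human-readable rendering.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .cea import NONDOMINATED, CeaResult, incremental_analysis
from .economics import EconResult
from .parameters import ParameterSet, ScreeningStrategy, default_strategies, load_parameters
from .pipeline import evaluate_strategies
from .uncertainty import ceac, run_psa, scenario_grid

__all__ = ["RunManifest", "base_case_table", "run_base_case", "run_full"]


@dataclass
class RunManifest:
    """What a run did: command, inputs, seed, outputs, failures."""

    command: str
    config: str | None
    seed: int | None
    version: str = __version__
    started: str = field(default_factory=lambda: datetime.datetime.now().isoformat())
    outputs: list[str] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def base_case_table(
    results: Sequence[EconResult], cea: CeaResult | None = None
) -> pd.DataFrame:
    """Absolute + incremental block, one row per strategy.

    Incremental columns compare each strategy to the current optimal
    comparator along the frontier (the previous frontier member); dominated
    strategies carry their dominance label instead of an ICER.
    """
    cea = cea or incremental_analysis(results)
    by_id = {r.strategy_id: r for r in results}
    frontier = dict(cea.frontier)
    prev_on_frontier: dict[int, int | None] = {}
    fids = cea.frontier_ids()
    for i, sid in enumerate(fids):
        prev_on_frontier[sid] = fids[i - 1] if i > 0 else None

    rows = []
    for sid in sorted(by_id):
        r = by_id[sid]
        status = cea.dominance[sid]
        row: dict[str, Any] = {
            "strategy": sid,
            "life_years": r.life_years,
            "qalys": r.qalys,
            "cost": r.total_cost,
            "dominance": status,
        }
        if sid in frontier:
            comp = prev_on_frontier[sid]
            row["comparator"] = comp
            if comp is not None:
                row["delta_qalys"] = r.qalys - by_id[comp].qalys
                row["delta_cost"] = r.total_cost - by_id[comp].total_cost
                row["icer"] = frontier[sid]
        rows.append(row)
    return pd.DataFrame(rows)


def render_base_case(table: pd.DataFrame) -> str:
    """Human-readable rendering (whole euros, 3-decimal QALYs)."""
    shown = table.copy()
    for col in ("cost", "delta_cost", "icer"):
        if col in shown:
            shown[col] = shown[col].map(lambda v: f"{v:,.0f}" if pd.notna(v) else "")
    for col in ("life_years", "qalys", "delta_qalys"):
        if col in shown:
            shown[col] = shown[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    return shown.to_string(index=False)


def run_base_case(
    config: str | Mapping[str, Any] | ParameterSet,
    strategies: Sequence[ScreeningStrategy] | None = None,
) -> tuple[pd.DataFrame, CeaResult, list[EconResult]]:
    """Deterministic base case for one gender's configuration."""
    params = config if isinstance(config, ParameterSet) else load_parameters(config)
    strategies = list(strategies) if strategies is not None else default_strategies()
    results = evaluate_strategies(strategies, params)
    cea = incremental_analysis(results)
    return base_case_table(results, cea), cea, results


def run_full(
    configs: Mapping[str, str | Mapping[str, Any] | ParameterSet] | None = None,
    out_dir: str | Path = "hfscreen_out",
    psa_n: int = 10_000,
    seed: int = 0,
    rho_grid: Sequence[float] = tuple(i / 10 for i in range(11)),
    wtp_grid: Sequence[float] = tuple(range(0, 100_001, 1000)),
) -> RunManifest:
    """Run everything: base case per gender, PSA + CEAC, scenario grid.

    Outputs are written as CSV under ``out_dir`` with one JSON manifest;
    partial failures keep completed outputs and are recorded in the
    manifest.
    """
    configs = configs or {"men": "dutch_men", "women": "dutch_women"}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strategies = default_strategies()
    manifest = RunManifest(command="run_full", config=str(configs), seed=seed)

    for label, cfg in configs.items():
        params = cfg if isinstance(cfg, ParameterSet) else load_parameters(cfg)
        try:
            table, _, _ = run_base_case(params, strategies)
            path = out / f"base_case_{label}.csv"
            table.to_csv(path, index=False)
            manifest.outputs.append(str(path))
        except Exception as exc:  # keep going; record the failure
            manifest.failures[f"base_case_{label}"] = repr(exc)
            continue
        try:
            cloud = run_psa(strategies, params, n=psa_n, seed=seed)
            cloud_path = out / f"psa_cloud_{label}.csv"
            cloud.to_frame().to_csv(cloud_path, index=False)
            curve = ceac(cloud, wtp_grid)
            ceac_path = out / f"ceac_{label}.csv"
            curve.to_frame().to_csv(ceac_path, index=False)
            manifest.outputs += [str(cloud_path), str(ceac_path)]
        except Exception as exc:
            manifest.failures[f"psa_{label}"] = repr(exc)
        try:
            grid = scenario_grid(strategies, params, rho_grid)
            grid_path = out / f"scenario_{label}.csv"
            grid.to_csv(grid_path, index=False)
            manifest.outputs.append(str(grid_path))
        except Exception as exc:
            manifest.failures[f"scenario_{label}"] = repr(exc)

    manifest.write(out / "manifest.json")
    return manifest
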