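"""Intervention outcomes and benchmark-relative improvement metrics.

Three outcomes summarize each intervention scenario:

1. **population coverage** — percent of the community's population living in
   a neighborhood with an assigned in-range FV market.  The optimization
   objective weights neighborhoods by FV demand a_i; the reported coverage
   weights them by population.  When demand is proportional to population
   (the generator default) the two coincide.
2. **number of new FV markets** opened.
3. **fast-food-to-FV-market ratio** — per-neighborhood count of in-range
   fast-food outlets per in-range FV market, aggregated across neighborhoods.
   A neighborhood with no in-range FV market contributes its fast-food count
   divided by 1 (zero-denominator rule).  The aggregation scheme is
   configurable (unweighted mean is the reported default; population-weighted
   mean and citywide-totals variants are provided).

Improvement metrics compare a scenario against the do-nothing benchmark:
relative coverage improvement in percent, ratio reduction in percent, and
plain percentage-point differences.  All rounding is half-up — 1 decimal for
percentages and ratios, nearest integer for improvement percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .community import Community, CoverageSets
from .optimizer import Solution

__all__ = [
    "OutcomeReport",
    "coverage_percent",
    "ff_fv_ratio",
    "exposure_differential",
    "relative_improvement",
    "ratio_improvement",
    "point_difference",
    "render_results_table",
    "improvement_table",
]

RatioAggregation = Literal["mean", "population_weighted", "citywide"]


def _round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OutcomeReport:
    """Outcomes of one scenario (or the benchmark) on one community."""

    scenario_key: str
    coverage_pct: float  # % of population with FV access, 1 decimal
    new_markets: int
    ff_fv_ratio: float  # fast-food outlets per FV market, 1 decimal
    objective_servings: int  # covered demand z
    R: tuple[int, ...]  # per-neighborhood fast-food vs FV exposure differential
    w: tuple[tuple[int, ...], ...]  # fast-food exposure indicators w_ik = f_ik
    chosen_site_ids: tuple[str, ...] = ()
    total_cost: int = 0

    def __post_init__(self):
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValueError(f"coverage_pct {self.coverage_pct} outside [0, 100]")
        if self.new_markets < 0 or self.ff_fv_ratio < 0:
            raise ValueError("new_markets and ff_fv_ratio must be nonnegative")


def coverage_percent(sol: Solution, community: Community) -> float:
    """Population-weighted coverage percentage, rounded half-up to 1 decimal."""
    pops = community.populations
    if len(sol.y) != len(pops):
        raise ValueError("solution dimensions do not match the community")
    total = int(pops.sum())
    if total <= 0:
        raise ValueError("total population must be positive")
    covered = int((pops * sol.y).sum())
    return _round_half_up(100.0 * covered / total, 1)


def demand_coverage_percent(sol: Solution, community: Community) -> float:
    """Demand-weighted coverage percent — the objective on a 0-100 scale."""
    total = int(community.demands.sum())
    if total <= 0:
        raise ValueError("total demand must be positive")
    return _round_half_up(100.0 * sol.objective / total, 1)


def _per_neighborhood_ratio(community: Community, cov: CoverageSets, x: np.ndarray) -> np.ndarray:
    ff = cov.f.sum(axis=1).astype(float)
    fv = cov.e.sum(axis=1) + cov.n @ x.astype(np.int64)
    return ff / np.maximum(fv, 1)


def ff_fv_ratio(
    community: Community,
    cov: CoverageSets,
    sol: Solution,
    aggregation: RatioAggregation = "mean",
) -> float:
    """Fast-food outlets per FV market after implementation, 1 decimal.

    Computed per neighborhood from the coverage sets and the opened sites
    (the zero-denominator rule counts an FV-free neighborhood's fast-food
    outlets over a denominator of 1), then aggregated.
    """
    ratios = _per_neighborhood_ratio(community, cov, sol.x)
    if aggregation == "mean":
        value = float(ratios.mean())
    elif aggregation == "population_weighted":
        pops = community.populations
        value = float((ratios * pops).sum() / pops.sum())
    elif aggregation == "citywide":
        ff = int(cov.f.sum())
        fv = int(cov.e.sum() + (cov.n @ sol.x.astype(np.int64)).sum())
        value = ff / max(fv, 1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return _round_half_up(value, 1)


def exposure_differential(cov: CoverageSets, sol: Solution) -> np.ndarray:
    """Per-neighborhood fast-food minus FV exposure, R_i.

    R_i = sum_k f_ik - sum_j e_ij - sum_l n_il x_l: the count of in-range
    fast-food outlets in excess of in-range FV markets (existing and newly
    opened).  An accounting identity of the solution, not a constraint.
    """
    return (
        cov.f.sum(axis=1).astype(np.int64)
        - cov.e.sum(axis=1).astype(np.int64)
        - cov.n.astype(np.int64) @ sol.x.astype(np.int64)
    )


def relative_improvement(benchmark_pct: float, scenario_pct: float) -> int:
    """Relative coverage gain over the benchmark, percent (half-up integer)."""
    if benchmark_pct <= 0:
        raise ValueError("benchmark coverage must be positive to compute improvement")
    return int(_round_half_up(100.0 * (scenario_pct - benchmark_pct) / benchmark_pct, 0))


def ratio_improvement(benchmark_ratio: float, scenario_ratio: float) -> int:
    """Relative reduction of the fast-food-to-FV ratio, percent (half-up integer)."""
    if benchmark_ratio <= 0:
        raise ValueError("benchmark ratio must be positive to compute improvement")
    return int(_round_half_up(100.0 * (benchmark_ratio - scenario_ratio) / benchmark_ratio, 0))


def point_difference(a: float, b: float) -> float:
    """Difference in percentage points, 1 decimal."""
    return _round_half_up(a - b, 1)


def build_outcome_report(
    community: Community,
    cov: CoverageSets,
    sol: Solution,
    scenario_key: str,
    aggregation: RatioAggregation = "mean",
) -> OutcomeReport:
    """Assemble the three outcomes plus exposure accounting for one solution."""
    return OutcomeReport(
        scenario_key=scenario_key,
        coverage_pct=coverage_percent(sol, community),
        new_markets=sol.num_new_markets,
        ff_fv_ratio=ff_fv_ratio(community, cov, sol, aggregation),
        objective_servings=int(sol.objective),
        R=tuple(int(r) for r in exposure_differential(cov, sol)),
        w=tuple(tuple(int(v) for v in row) for row in cov.f),
        chosen_site_ids=tuple(sol.chosen_site_ids(community)),
        total_cost=sol.total_cost(community),
    )


def scenario_table_frame(rows) -> pd.DataFrame:
    """Tabulate OutcomeReports (benchmark first) as a DataFrame."""
    records = []
    for row in rows:
        key = row.scenario_key
        if key == "benchmark":
            dist, budget, cap = "benchmark", "benchmark", "benchmark"
        else:
            dist, budget, cap = key.split("|")
        records.append(
            {
                "distance_miles": dist,
                "budget": budget,
                "capacity_level": cap,
                "coverage_pct": row.coverage_pct,
                "new_markets": row.new_markets,
                "ff_fv_ratio": row.ff_fv_ratio,
                "chosen_site_ids": ";".join(row.chosen_site_ids),
            }
        )
    return pd.DataFrame.from_records(records)


def render_results_table(table, out: str | Path, text: bool = False) -> Path:
    """Write the scenario table as CSV (benchmark row first).

    With ``text=True`` additionally writes a fixed-width human-readable
    rendering next to the CSV.
    """
    out = Path(out)
    frame = scenario_table_frame(table.rows)
    frame.to_csv(out, index=False)
    if text:
        txt = out.with_suffix(".txt")
        txt.write_text(frame.to_string(index=False) + "\n")
    return out


def improvement_table(table) -> pd.DataFrame:
    """Per-scenario improvements versus the benchmark row.

    Emits relative coverage improvement (%), ratio improvement (%), and
    point differences for every non-benchmark row.
    """
    bench = next(r for r in table.rows if r.scenario_key == "benchmark")
    records = []
    for row in table.rows:
        if row.scenario_key == "benchmark":
            continue
        dist, budget, cap = row.scenario_key.split("|")
        records.append(
            {
                "distance_miles": dist,
                "budget": budget,
                "capacity_level": cap,
                "coverage_pct": row.coverage_pct,
                "coverage_improvement_pct": relative_improvement(
                    bench.coverage_pct, row.coverage_pct
                ),
                "coverage_point_diff": point_difference(row.coverage_pct, bench.coverage_pct),
                "ff_fv_ratio": row.ff_fv_ratio,
                "ratio_improvement_pct": ratio_improvement(bench.ff_fv_ratio, row.ff_fv_ratio),
            }
        )
    return pd.DataFrame.from_records(records)
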