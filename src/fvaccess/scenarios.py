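"""Benchmark evaluation and the full factorial intervention grid.

Three intervention factors, each at three levels, define 27 scenarios:

* recommended driving distance to the nearest FV market — 1, 2.5, 5 miles
  (5 miles is the rural access benchmark),
* monthly financial resources to operate new markets — $15,000 / $20,000 /
  $25,000,
* service capacity of new FV markets — 20,000 / 40,000 / 80,000 servings
  per month (low / normal / high).

A 28th row evaluates the do-nothing benchmark: the existing food environment
at the 5-mile threshold with zero budget, no optimization involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import Community, CoverageSets, compute_coverage_sets, validate_community
from .optimizer import ScenarioConfig, Solution, SolverOptions, solve_model
from .reporting import OutcomeReport, RatioAggregation, build_outcome_report

__all__ = ["FactorLevels", "ScenarioTable", "run_benchmark", "run_scenario", "run_factorial_grid"]

_LEVEL_NAMES = ("low", "normal", "high")


@dataclass(frozen=True)
class FactorLevels:
    """The factor levels of the intervention grid (strictly increasing)."""

    distances: tuple[float, ...] = (1.0, 2.5, 5.0)
    budgets: tuple[int, ...] = (15_000, 20_000, 25_000)
    capacities: tuple[int, ...] = (20_000, 40_000, 80_000)
    benchmark_distance: float = 5.0

    def __post_init__(self):
        for name in ("distances", "budgets", "capacities"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be positive")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")

    def capacity_label(self, capacity: int) -> str:
        idx = self.capacities.index(capacity)
        if len(self.capacities) == len(_LEVEL_NAMES):
            return _LEVEL_NAMES[idx]
        return str(capacity)


@dataclass(frozen=True)
class ScenarioTable:
    """One OutcomeReport per scenario plus the benchmark row (first)."""

    rows: tuple[OutcomeReport, ...]
    levels: FactorLevels

    @property
    def benchmark(self) -> OutcomeReport:
        return self.rows[0]

    @property
    def scenario_rows(self) -> tuple[OutcomeReport, ...]:
        return self.rows[1:]


def _benchmark_solution(community: Community, cov: CoverageSets) -> Solution:
    """Do-nothing solution: coverage by existing markets only, no assignment limits."""
    nI, nJ, nL = len(community.neighborhoods), len(community.markets), len(community.candidates)
    v = np.zeros((nI, nJ), dtype=np.int8)
    y = np.zeros(nI, dtype=np.int8)
    for i in range(nI):
        in_range = np.flatnonzero(cov.e[i])
        if in_range.size:
            y[i] = 1
            v[i, in_range[0]] = 1
    return Solution(
        status="optimal",
        objective=int((community.demands * y).sum()),
        x=np.zeros(nL, dtype=np.int8),
        y=y,
        u=np.zeros((nI, nL), dtype=np.int8),
        v=v,
    )


def run_benchmark(
    community: Community, S: float, aggregation: RatioAggregation = "mean"
) -> OutcomeReport:
    """Evaluate the existing food environment at threshold ``S``, opening nothing.

    Coverage, market count (zero new) and the fast-food-to-FV ratio are read
    directly off the coverage sets; no optimization is performed.
    """
    validate_community(community)
    cov = compute_coverage_sets(community, S)
    sol = _benchmark_solution(community, cov)
    return build_outcome_report(community, cov, sol, "benchmark", aggregation)


def run_scenario(
    community: Community,
    cfg: ScenarioConfig,
    options: SolverOptions = SolverOptions(),
    aggregation: RatioAggregation = "mean",
    scenario_key: str | None = None,
) -> OutcomeReport:
    """Solve one intervention cell and report its outcomes."""
    validate_community(community)
    cov = compute_coverage_sets(community, cfg.S)
    sol = solve_model(community, cov, cfg, options)
    key = scenario_key or f"{cfg.S:g}|{cfg.budget}|{cfg.new_market_capacity}"
    return build_outcome_report(community, cov, sol, key, aggregation)


def run_factorial_grid(
    community: Community,
    levels: FactorLevels = FactorLevels(),
    options: SolverOptions = SolverOptions(),
    aggregation: RatioAggregation = "mean",
    secondary_objective: str = "min_new_markets",
) -> ScenarioTable:
    """Run the benchmark plus the full factorial of intervention scenarios.

    Rows are ordered benchmark first, then distance-major, budget, capacity.
    The capacity factor overrides candidate capacities uniformly (new markets
    only); existing-market capacities come from the instance.
    """
    validate_community(community)
    rows = [run_benchmark(community, levels.benchmark_distance, aggregation)]
    for S in levels.distances:
        for budget in levels.budgets:
            for capacity in levels.capacities:
                cfg = ScenarioConfig(
                    S=S,
                    budget=int(budget),
                    capacity_enabled=True,
                    budget_enabled=True,
                    new_market_capacity=int(capacity),
                    secondary_objective=secondary_objective,
                )
                key = f"{S:g}|{budget}|{levels.capacity_label(capacity)}"
                rows.append(
                    run_scenario(community, cfg, options, aggregation, scenario_key=key)
                )
    return ScenarioTable(rows=tuple(rows), levels=levels)
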