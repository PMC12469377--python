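"""Benchmark evaluation and the factorial scenario grid."""

import numpy as np
import pytest

from fvaccess import (
    FactorLevels,
    compute_coverage_sets,
    enumerate_optimal,
    run_benchmark,
    run_factorial_grid,
    run_scenario,
)
from fvaccess.community import (
    CandidateSite,
    Community,
    ExistingMarket,
    FastFoodOutlet,
    Neighborhood,
)
from fvaccess.optimizer import ScenarioConfig

from conftest import make_random_instance


def _ample_community(d_candidate):
    """Three neighborhoods, one all-serving existing market near n0 only."""
    nI = 3
    return Community(
        neighborhoods=tuple(Neighborhood(f"n{i}", 100, 100) for i in range(nI)),
        markets=(ExistingMarket("m0", 10_000),),
        candidates=(CandidateSite("c0", 10_000, 9000),),
        fastfood=(FastFoodOutlet("f0"), FastFoodOutlet("f1")),
        d_market=np.array([[1.0], [9.0], [9.0]]),
        d_candidate=np.asarray(d_candidate, dtype=float),
        d_fastfood=np.full((nI, 2), 1.0),
    )


class TestRunBenchmark:
    def test_everyone_near_existing_market_gives_full_coverage(self):
        import dataclasses

        community = dataclasses.replace(
            _ample_community([[1.0], [1.0], [1.0]]), d_market=np.full((3, 1), 1.0)
        )
        report = run_benchmark(community, 5.0)
        assert report.coverage_pct == 100.0
        assert report.new_markets == 0

    def test_no_existing_markets_gives_zero_coverage_and_ff_only_ratio(self):
        community = Community(
            neighborhoods=(Neighborhood("n0", 100, 100),),
            markets=(),
            candidates=(),
            fastfood=(FastFoodOutlet("f0"), FastFoodOutlet("f1")),
            d_market=np.zeros((1, 0)),
            d_candidate=np.zeros((1, 0)),
            d_fastfood=np.full((1, 2), 1.0),
        )
        report = run_benchmark(community, 5.0)
        assert report.coverage_pct == 0.0
        assert report.ff_fv_ratio == 2.0  # zero-denominator rule

    def test_benchmark_ignores_budget_and_capacity(self, calibrated_community):
        reports = [run_benchmark(calibrated_community, 5.0) for _ in range(2)]
        assert reports[0] == reports[1]


class TestRunScenario:
    def test_budget_below_every_cost_reduces_to_benchmark(self):
        community = _ample_community([[1.0], [1.0], [1.0]])
        cfg = ScenarioConfig(S=5.0, budget=500, capacity_enabled=True, budget_enabled=True)
        scenario = run_scenario(community, cfg)
        bench = run_benchmark(community, 5.0)
        assert scenario.coverage_pct == bench.coverage_pct
        assert scenario.new_markets == 0
        assert scenario.ff_fv_ratio == bench.ff_fv_ratio

    def test_nonbinding_budget_and_capacity_reach_geometric_coverage(self):
        community = _ample_community([[9.0], [1.0], [9.0]])  # candidate near n1 only
        cfg = ScenarioConfig(S=5.0, budget=9000, capacity_enabled=True, budget_enabled=True,
                             new_market_capacity=10_000)
        scenario = run_scenario(community, cfg)
        # n0 via existing market, n1 via the new market, n2 unreachable
        assert scenario.coverage_pct == pytest.approx(66.7)
        assert scenario.new_markets == 1

    def test_small_instance_outcomes_match_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            community = make_random_instance(rng, n_neighborhoods=5, n_candidates=3, n_markets=1)
            cfg = ScenarioConfig(S=5.0, budget=int(rng.integers(0, 30) * 1000),
                                 capacity_enabled=True, budget_enabled=True)
            scenario = run_scenario(community, cfg)
            cov = compute_coverage_sets(community, 5.0)
            oracle_sol = enumerate_optimal(community, cov, cfg)
            assert scenario.objective_servings == oracle_sol.objective
            assert scenario.new_markets == oracle_sol.num_new_markets


class TestFactorialGrid:
    def test_default_grid_has_27_scenarios_plus_benchmark(self, calibrated_community):
        table = run_factorial_grid(calibrated_community)
        assert len(table.rows) == 28
        assert table.benchmark.scenario_key == "benchmark"
        assert len(table.scenario_rows) == 27

    def test_row_count_follows_product_rule(self, calibrated_community):
        levels = FactorLevels(distances=(1.0, 5.0), budgets=(20_000,), capacities=(40_000,))
        table = run_factorial_grid(calibrated_community, levels)
        assert len(table.rows) == 2 + 1

    def test_rows_ordered_distance_major(self, calibrated_community):
        levels = FactorLevels(distances=(1.0, 5.0), budgets=(15_000, 20_000), capacities=(40_000,))
        table = run_factorial_grid(calibrated_community, levels)
        keys = [r.scenario_key for r in table.scenario_rows]
        assert keys == ["1|15000|40000", "1|20000|40000", "5|15000|40000", "5|20000|40000"]

    def test_coverage_nondecreasing_in_budget_at_fixed_distance_capacity(self, calibrated_community):
        table = run_factorial_grid(calibrated_community)
        by_key = {r.scenario_key: r for r in table.scenario_rows}
        for S in ("1", "2.5", "5"):
            for cap in ("low", "normal", "high"):
                covs = [by_key[f"{S}|{b}|{cap}"].coverage_pct for b in (15000, 20000, 25000)]
                assert covs == sorted(covs)

    def test_grid_is_deterministic(self, calibrated_community):
        levels = FactorLevels(distances=(2.5,), budgets=(20_000,), capacities=(40_000, 80_000))
        t1 = run_factorial_grid(calibrated_community, levels)
        t2 = run_factorial_grid(calibrated_community, levels)
        assert t1.rows == t2.rows
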