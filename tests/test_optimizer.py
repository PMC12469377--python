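"""Model assembly, solving, and the exact feasibility audit."""

import numpy as np
import pytest

from fvaccess import build_model, check_feasibility, compute_coverage_sets, solve_model
from fvaccess.community import (
    CandidateSite,
    Community,
    ExistingMarket,
    FastFoodOutlet,
    Neighborhood,
)
from fvaccess.optimizer import ScenarioConfig, Solution

from conftest import make_random_instance


def _toy(nI=3, nJ=1, nL=2, d=1.0):
    """All facilities within range at S=5 by default."""
    return Community(
        neighborhoods=tuple(Neighborhood(f"n{i}", 100, 100) for i in range(nI)),
        markets=tuple(ExistingMarket(f"m{j}", 10_000) for j in range(nJ)),
        candidates=tuple(CandidateSite(f"c{l}", 10_000, 5000) for l in range(nL)),
        fastfood=(FastFoodOutlet("f0"),),
        d_market=np.full((nI, nJ), d),
        d_candidate=np.full((nI, nL), d),
        d_fastfood=np.full((nI, 1), d),
    )


class TestBuildModel:
    def test_base_model_constraint_count(self):
        community = _toy(nI=3, nJ=1, nL=2)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=False, budget_enabled=False)
        spec = build_model(community, cov, cfg)
        # per-block instance counts: |I| + |L| + |L| + |I||J| + |I||L|
        assert spec.block_count("coverage_link") == 3
        assert spec.block_count("open_link_ub") == 2
        assert spec.block_count("open_link_lb") == 2
        assert spec.block_count("existing_range") == 3
        assert spec.block_count("new_range") == 6
        assert len(spec.constraints) == 16

    def test_capacity_block_adds_J_plus_L_plus_I_constraints(self):
        community = _toy(nI=3, nJ=1, nL=2)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=True, budget_enabled=False)
        spec = build_model(community, cov, cfg)
        assert len(spec.constraints) == 16 + (1 + 2 + 3)

    def test_budget_block_adds_one_constraint(self):
        community = _toy(nI=3, nJ=1, nL=2)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, budget=10_000, capacity_enabled=True, budget_enabled=True)
        spec = build_model(community, cov, cfg)
        assert len(spec.constraints) == 16 + 6 + 1

    def test_threshold_mismatch_rejected(self):
        community = _toy()
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=2.5, capacity_enabled=False, budget_enabled=False)
        with pytest.raises(ValueError, match="S=5.0.*S=2.5"):
            build_model(community, cov, cfg)

    def test_big_M_below_neighborhood_count_rejected(self):
        community = _toy(nI=3)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, big_M=2, capacity_enabled=False, budget_enabled=False)
        with pytest.raises(ValueError, match="big_M"):
            build_model(community, cov, cfg)


class TestSolveModel:
    def test_nothing_in_range_gives_zero_coverage(self):
        community = _toy(d=100.0)  # every facility far beyond S
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=False, budget_enabled=False)
        sol = solve_model(community, cov, cfg)
        assert sol.status == "optimal"
        assert sol.objective == 0
        assert sol.x.sum() == 0 and sol.y.sum() == 0

    def test_zero_budget_forces_existing_coverage_only(self):
        community = _toy()
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, budget=0, capacity_enabled=False, budget_enabled=True)
        sol = solve_model(community, cov, cfg)
        assert sol.num_new_markets == 0
        # all three neighborhoods reachable by the existing market
        assert sol.objective == 300
        assert check_feasibility(sol, community, cov, cfg) == []

    def test_min_new_markets_prunes_redundant_openings(self):
        # one market suffices for full coverage; secondary objective must not open two
        community = _toy(nI=4, nJ=0, nL=2)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=False, budget_enabled=False,
                             secondary_objective="min_new_markets")
        sol = solve_model(community, cov, cfg)
        assert sol.objective == 400
        assert sol.num_new_markets == 1

    def test_min_ff_ratio_opens_extra_affordable_markets(self):
        # both candidates reach everyone; ratio-minimizing tie-break opens both,
        # count-minimizing opens one
        community = _toy(nI=4, nJ=0, nL=2)
        cov = compute_coverage_sets(community, 5.0)
        base = dict(S=5.0, capacity_enabled=False, budget_enabled=False)
        sol_ratio = solve_model(community, cov, ScenarioConfig(**base, secondary_objective="min_ff_ratio"))
        sol_count = solve_model(community, cov, ScenarioConfig(**base, secondary_objective="min_new_markets"))
        assert sol_ratio.objective == sol_count.objective == 400
        assert sol_count.num_new_markets == 1
        assert sol_ratio.num_new_markets == 2


class TestCheckFeasibility:
    def test_do_nothing_is_always_feasible(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            community = make_random_instance(rng)
            cov = compute_coverage_sets(community, 5.0)
            cfg = ScenarioConfig(S=5.0, budget=0, capacity_enabled=True, budget_enabled=True)
            nI, nJ, nL = (len(community.neighborhoods), len(community.markets),
                          len(community.candidates))
            zero = Solution(
                status="optimal", objective=0,
                x=np.zeros(nL, dtype=np.int8), y=np.zeros(nI, dtype=np.int8),
                u=np.zeros((nI, nL), dtype=np.int8), v=np.zeros((nI, nJ), dtype=np.int8),
            )
            assert check_feasibility(zero, community, cov, cfg) == []

    def test_out_of_range_assignment_is_reported(self):
        community = _toy(nI=1, nJ=1, nL=0, d=100.0)  # market out of range
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=False, budget_enabled=False)
        bad = Solution(
            status="optimal", objective=100,
            x=np.zeros(0, dtype=np.int8), y=np.ones(1, dtype=np.int8),
            u=np.zeros((1, 0), dtype=np.int8), v=np.ones((1, 1), dtype=np.int8),
        )
        report = check_feasibility(bad, community, cov, cfg)
        assert any(v.equation == "existing_range" for v in report)

    def test_dimension_mismatch_is_structural_error(self):
        community = _toy(nI=2)
        cov = compute_coverage_sets(community, 5.0)
        cfg = ScenarioConfig(S=5.0, capacity_enabled=False, budget_enabled=False)
        wrong = Solution(
            status="optimal", objective=0,
            x=np.zeros(2, dtype=np.int8), y=np.zeros(3, dtype=np.int8),  # |I| is 2
            u=np.zeros((2, 2), dtype=np.int8), v=np.zeros((2, 1), dtype=np.int8),
        )
        with pytest.raises(ValueError, match="dimensions"):
            check_feasibility(wrong, community, cov, cfg)
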