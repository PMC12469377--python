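"""Outcome metrics, exposure accounting, and benchmark-relative improvements."""

import numpy as np
import pytest

from fvaccess import (
    compute_coverage_sets,
    coverage_percent,
    exposure_differential,
    ff_fv_ratio,
    point_difference,
    ratio_improvement,
    relative_improvement,
)
from fvaccess.community import (
    CandidateSite,
    Community,
    ExistingMarket,
    FastFoodOutlet,
    Neighborhood,
)
from fvaccess.optimizer import Solution
from fvaccess.reporting import demand_coverage_percent


def _solution(nI, nJ, nL, y=None, x=None):
    return Solution(
        status="optimal",
        objective=0,
        x=np.array(x if x is not None else [0] * nL, dtype=np.int8),
        y=np.array(y if y is not None else [0] * nI, dtype=np.int8),
        u=np.zeros((nI, nL), dtype=np.int8),
        v=np.zeros((nI, nJ), dtype=np.int8),
    )


def _community(pops, n_ff=0, n_mk=0, n_cd=0, d_ff=1.0, d_mk=1.0, d_cd=1.0):
    nI = len(pops)
    return Community(
        neighborhoods=tuple(Neighborhood(f"n{i}", p, p) for i, p in enumerate(pops)),
        markets=tuple(ExistingMarket(f"m{j}", 1000) for j in range(n_mk)),
        candidates=tuple(CandidateSite(f"c{l}", 1000, 100) for l in range(n_cd)),
        fastfood=tuple(FastFoodOutlet(f"f{k}") for k in range(n_ff)),
        d_market=np.full((nI, n_mk), d_mk),
        d_candidate=np.full((nI, n_cd), d_cd),
        d_fastfood=np.full((nI, n_ff), d_ff),
    )


class TestCoveragePercent:
    def test_full_coverage(self):
        community = _community([300, 700])
        assert coverage_percent(_solution(2, 0, 0, y=[1, 1]), community) == 100.0

    def test_population_weighting(self):
        community = _community([300, 700])
        assert coverage_percent(_solution(2, 0, 0, y=[1, 0]), community) == 30.0

    def test_benchmark_scale_arithmetic(self):
        community = _community([464, 536])
        assert coverage_percent(_solution(2, 0, 0, y=[1, 0]), community) == 46.4

    def test_matches_demand_weighting_when_proportional(self):
        community = _community([123, 456, 789])
        sol = Solution(
            status="optimal", objective=123 + 789,
            x=np.zeros(0, dtype=np.int8), y=np.array([1, 0, 1], dtype=np.int8),
            u=np.zeros((3, 0), dtype=np.int8), v=np.zeros((3, 0), dtype=np.int8),
        )
        assert coverage_percent(sol, community) == demand_coverage_percent(sol, community)


class TestFFRatio:
    def test_uniform_eight_to_one(self):
        # every neighborhood sees 8 fast-food outlets and exactly 1 FV market
        community = _community([100, 100], n_ff=8, n_mk=1)
        cov = compute_coverage_sets(community, 5.0)
        assert ff_fv_ratio(community, cov, _solution(2, 1, 0)) == 8.0

    def test_no_fastfood_gives_zero(self):
        community = _community([100], n_mk=1)
        cov = compute_coverage_sets(community, 5.0)
        assert ff_fv_ratio(community, cov, _solution(1, 1, 0)) == 0.0

    def test_rounding_of_seven_thirds(self):
        # 7 fast food over 3 markets in each neighborhood: 2.333... -> 2.3
        community = _community([100, 100], n_ff=7, n_mk=3)
        cov = compute_coverage_sets(community, 5.0)
        assert ff_fv_ratio(community, cov, _solution(2, 3, 0)) == 2.3

    def test_zero_denominator_rule_counts_fastfood_over_one(self):
        community = _community([100], n_ff=5)  # no FV market anywhere
        cov = compute_coverage_sets(community, 5.0)
        assert ff_fv_ratio(community, cov, _solution(1, 0, 0)) == 5.0

    def test_opening_a_market_never_increases_the_ratio(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nI, nL = int(rng.integers(1, 6)), int(rng.integers(1, 4))
            community = Community(
                neighborhoods=tuple(Neighborhood(f"n{i}", 10, 10) for i in range(nI)),
                markets=(),
                candidates=tuple(CandidateSite(f"c{l}", 100, 100) for l in range(nL)),
                fastfood=tuple(FastFoodOutlet(f"f{k}") for k in range(4)),
                d_market=np.zeros((nI, 0)),
                d_candidate=rng.uniform(0, 10, (nI, nL)),
                d_fastfood=rng.uniform(0, 10, (nI, 4)),
            )
            cov = compute_coverage_sets(community, 5.0)
            x = rng.integers(0, 2, nL)
            closed = _solution(nI, 0, nL, x=[0] * nL)
            opened = _solution(nI, 0, nL, x=x.tolist())
            assert ff_fv_ratio(community, cov, opened) <= ff_fv_ratio(community, cov, closed)


class TestExposureDifferential:
    def test_direct_formula(self):
        community = _community([100], n_ff=5, n_mk=1)
        cov = compute_coverage_sets(community, 5.0)
        assert exposure_differential(cov, _solution(1, 1, 0)).tolist() == [4]

    def test_opening_in_range_market_decrements_R(self):
        community = _community([100], n_ff=5, n_mk=1, n_cd=1)
        cov = compute_coverage_sets(community, 5.0)
        before = exposure_differential(cov, _solution(1, 1, 1, x=[0]))
        after = exposure_differential(cov, _solution(1, 1, 1, x=[1]))
        assert (before - after).tolist() == [1]

    def test_empty_coverage_gives_zero_vector(self):
        community = _community([100], n_ff=2, n_mk=1, d_ff=99.0, d_mk=99.0)
        cov = compute_coverage_sets(community, 5.0)
        assert exposure_differential(cov, _solution(1, 1, 0)).tolist() == [0]


class TestImprovementArithmetic:
    @pytest.mark.parametrize(
        "bench, scenario, expected",
        [(46.4, 61.7, 33), (46.4, 55.1, 19), (50.0, 50.0, 0)],
    )
    def test_relative_improvement(self, bench, scenario, expected):
        assert relative_improvement(bench, scenario) == expected

    @pytest.mark.parametrize(
        "bench, scenario, expected",
        [(8.0, 2.3, 71), (8.0, 5.7, 29), (4.2, 4.2, 0)],
    )
    def test_ratio_improvement(self, bench, scenario, expected):
        assert ratio_improvement(bench, scenario) == expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [(73.6, 55.1, 18.5), (73.5, 46.4, 27.1), (12.0, 12.0, 0.0)],
    )
    def test_point_difference(self, a, b, expected):
        assert point_difference(a, b) == expected

    def test_sign_conventions(self):
        # better scenario -> positive improvement, worse -> negative
        assert relative_improvement(50.0, 60.0) > 0 > relative_improvement(50.0, 40.0)
        assert ratio_improvement(8.0, 4.0) > 0 > ratio_improvement(8.0, 12.0)

    def test_zero_benchmark_is_undefined(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 10.0)
        with pytest.raises(ValueError):
            ratio_improvement(0.0, 1.0)
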