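"""Shared fixtures: the packaged calibrated community and a random-instance factory."""

from __future__ import annotations

import numpy as np
import pytest

from fvaccess import Community, load_calibrated_community
from fvaccess.community import (
    CandidateSite,
    ExistingMarket,
    FastFoodOutlet,
    Neighborhood,
)
from fvaccess.optimizer import ScenarioConfig


@pytest.fixture(scope="session")
def calibrated_community() -> Community:
    return load_calibrated_community()


def make_random_instance(
    rng: np.random.Generator,
    n_neighborhoods: int | None = None,
    n_markets: int | None = None,
    n_candidates: int | None = None,
    n_fastfood: int = 3,
) -> Community:
    """A small random instance with distances given directly (no coordinates).

    Demands equal populations (rate 1 serving/person/month) so population-
    and demand-weighted coverage coincide.  All monetary and capacity values
    are integers, as the exact feasibility audit requires.
    """
    nI = int(n_neighborhoods if n_neighborhoods is not None else rng.integers(2, 9))
    nJ = int(n_markets if n_markets is not None else rng.integers(0, 3))
    nL = int(n_candidates if n_candidates is not None else rng.integers(1, 6))
    pops = rng.integers(10, 300, nI)
    neighborhoods = tuple(
        Neighborhood(f"n{i}", int(pops[i]), int(pops[i])) for i in range(nI)
    )
    markets = tuple(
        ExistingMarket(f"m{j}", int(rng.integers(0, 500))) for j in range(nJ)
    )
    candidates = tuple(
        CandidateSite(f"c{l}", int(rng.integers(50, 500)), int(rng.integers(1, 20) * 1000))
        for l in range(nL)
    )
    fastfood = tuple(FastFoodOutlet(f"f{k}") for k in range(n_fastfood))
    return Community(
        neighborhoods=neighborhoods,
        markets=markets,
        candidates=candidates,
        fastfood=fastfood,
        d_market=rng.uniform(0, 10, (nI, nJ)),
        d_candidate=rng.uniform(0, 10, (nI, nL)),
        d_fastfood=rng.uniform(0, 10, (nI, n_fastfood)),
    )


def random_config(rng: np.random.Generator, flavor: str, secondary: str = "none") -> ScenarioConfig:
    """A scenario config of one of the three factor-toggle flavors."""
    S = float(rng.uniform(2.0, 8.0))
    if flavor == "base":
        return ScenarioConfig(S=S, capacity_enabled=False, budget_enabled=False,
                              secondary_objective=secondary)
    if flavor == "capacity":
        return ScenarioConfig(S=S, capacity_enabled=True, budget_enabled=False,
                              secondary_objective=secondary)
    if flavor == "capacity_budget":
        return ScenarioConfig(S=S, budget=int(rng.integers(0, 40) * 1000),
                              capacity_enabled=True, budget_enabled=True,
                              secondary_objective=secondary)
    raise ValueError(flavor)


CONFIG_FLAVORS = ("base", "capacity", "capacity_budget")
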