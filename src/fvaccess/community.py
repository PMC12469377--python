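"""Problem-instance data model for rural food-environment siting.

A :class:`Community` bundles the four location layers of the model —
neighborhoods (demand points), existing fruit-and-vegetable (FV) markets,
candidate sites for new FV markets (empty commercial spaces), and fast-food
outlets — together with neighborhood-to-facility driving distances in miles.

Coverage is threshold-based: a facility "covers" a neighborhood when the
driving distance is at most the recommended driving distance ``S`` (the
threshold is inclusive, so a facility exactly ``S`` miles away counts).
:func:`compute_coverage_sets` turns the distance matrices into the three
binary incidence matrices the optimization model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Neighborhood",
    "ExistingMarket",
    "CandidateSite",
    "FastFoodOutlet",
    "Community",
    "CoverageSets",
    "CommunityValidationError",
    "compute_coverage_sets",
    "demand_from_population",
    "validate_community",
    "distances_from_coordinates",
]

#: Road-circuity multiplier applied to Euclidean distances when driving
#: distances are derived from planar coordinates.  Rural road networks are
#: typically 1.2-1.4x the straight-line distance; 1.3 is a common planning
#: default.
DEFAULT_CIRCUITY = 1.3

#: Default per-capita FV demand, servings/person/month.  At this rate one
#: "normal"-capacity market (40,000 servings/month) serves about 667 people.
DEFAULT_PER_CAPITA_SERVINGS = 60


class CommunityValidationError(ValueError):
    """Raised when a community instance violates its structural invariants.

    Carries ``problems``, the full list of violations found, so callers see
    every defect in one pass rather than one at a time.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid community instance:\n  - " + "\n  - ".join(self.problems)
        )


@dataclass(frozen=True)
class Neighborhood:
    """A demand point: a neighborhood with its population and monthly FV demand.

    ``demand`` is in servings/month (the model's a_i); ``x``/``y`` are planar
    coordinates in miles, optional when distance matrices are supplied.
    """

    id: str
    population: int
    demand: int
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class ExistingMarket:
    """An FV market already operating; ``capacity`` is servings/month (r_j)."""

    id: str
    capacity: int
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class CandidateSite:
    """An empty commercial space where a new FV market could open.

    ``capacity`` is the expected service capacity in servings/month (r_l);
    ``cost`` the average operating cost in currency units/month (c_l).
    """

    id: str
    capacity: int
    cost: int
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class FastFoodOutlet:
    """A fast-food outlet; exposure-only, never a decision."""

    id: str
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class Community:
    """A complete problem instance.

    Distance matrices are neighborhood-major: row i holds driving distances
    (miles) from neighborhood i to each facility of the given layer.  Only the
    neighborhood-to-facility direction is modeled.
    """

    neighborhoods: tuple[Neighborhood, ...]
    markets: tuple[ExistingMarket, ...]
    candidates: tuple[CandidateSite, ...]
    fastfood: tuple[FastFoodOutlet, ...]
    d_market: np.ndarray  # |I| x |J|, miles
    d_candidate: np.ndarray  # |I| x |L|, miles
    d_fastfood: np.ndarray  # |I| x |K|, miles

    def __post_init__(self):
        object.__setattr__(self, "neighborhoods", tuple(self.neighborhoods))
        object.__setattr__(self, "markets", tuple(self.markets))
        object.__setattr__(self, "candidates", tuple(self.candidates))
        object.__setattr__(self, "fastfood", tuple(self.fastfood))
        for name in ("d_market", "d_candidate", "d_fastfood"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    # -- convenience accessors -------------------------------------------------
    @property
    def n_neighborhoods(self) -> int:
        return len(self.neighborhoods)

    @property
    def populations(self) -> np.ndarray:
        return np.array([n.population for n in self.neighborhoods], dtype=np.int64)

    @property
    def demands(self) -> np.ndarray:
        """Monthly FV demand a_i, servings/month."""
        return np.array([n.demand for n in self.neighborhoods], dtype=np.int64)

    @property
    def market_capacities(self) -> np.ndarray:
        return np.array([m.capacity for m in self.markets], dtype=np.int64)

    @property
    def candidate_capacities(self) -> np.ndarray:
        return np.array([c.capacity for c in self.candidates], dtype=np.int64)

    @property
    def candidate_costs(self) -> np.ndarray:
        return np.array([c.cost for c in self.candidates], dtype=np.int64)

    @property
    def total_population(self) -> int:
        return int(self.populations.sum())

    def with_candidate_capacity(self, capacity: int) -> "Community":
        """Return a copy with every candidate's capacity set uniformly.

        Used by the scenario engine to apply the service-capacity factor to
        new markets only.
        """
        new_cands = tuple(replace(c, capacity=int(capacity)) for c in self.candidates)
        return replace(self, candidates=new_cands)


@dataclass(frozen=True)
class CoverageSets:
    """Binary coverage incidence at threshold ``S`` (miles, inclusive).

    ``e[i, j] = 1`` iff existing market j is within S driving miles of
    neighborhood i; ``n`` likewise for candidate sites and ``f`` for fast-food
    outlets.  These are the model parameters e_ij, n_il and f_ik.
    """

    e: np.ndarray  # |I| x |J|
    n: np.ndarray  # |I| x |L|
    f: np.ndarray  # |I| x |K|
    S: float

    def __post_init__(self):
        for name in ("e", "n", "f"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int8))


def distances_from_coordinates(
    origins_xy: np.ndarray, facilities_xy: np.ndarray, circuity: float = DEFAULT_CIRCUITY
) -> np.ndarray:
    """Driving-distance proxy: pairwise Euclidean miles times a circuity factor."""
    o = np.asarray(origins_xy, dtype=float)
    f = np.asarray(facilities_xy, dtype=float)
    if f.size == 0:
        return np.zeros((len(o), 0))
    diff = o[:, None, :] - f[None, :, :]
    return circuity * np.hypot(diff[..., 0], diff[..., 1])


def _check_distance_matrix(d: np.ndarray, name: str, problems: list[str]) -> None:
    bad = ~np.isfinite(d)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        problems.append(f"{name}[{i},{j}] is non-finite")
    neg = d < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        problems.append(f"{name}[{i},{j}] = {d[i, j]} is negative")


def validate_community(community: Community) -> Community:
    """Validate all structural invariants, collecting every violation.

    Returns the instance unchanged when valid; raises
    :class:`CommunityValidationError` listing all problems otherwise.
    """
    problems: list[str] = []

    for label, items in (
        ("neighborhood", community.neighborhoods),
        ("market", community.markets),
        ("candidate", community.candidates),
        ("fastfood", community.fastfood),
    ):
        seen: set[str] = set()
        for item in items:
            if item.id in seen:
                problems.append(f"duplicate {label} id {item.id!r}")
            seen.add(item.id)

    for n in community.neighborhoods:
        if n.population < 0:
            problems.append(f"neighborhood {n.id!r}: population {n.population} < 0")
        if n.demand < 0:
            problems.append(f"neighborhood {n.id!r}: demand {n.demand} < 0")
    for m in community.markets:
        if m.capacity < 0:
            problems.append(f"market {m.id!r}: capacity {m.capacity} < 0")
    for c in community.candidates:
        if c.capacity < 0:
            problems.append(f"candidate {c.id!r}: capacity {c.capacity} < 0")
        if c.cost < 0:
            problems.append(f"candidate {c.id!r}: cost {c.cost} < 0")

    nI = len(community.neighborhoods)
    expected = {
        "d_market": (nI, len(community.markets)),
        "d_candidate": (nI, len(community.candidates)),
        "d_fastfood": (nI, len(community.fastfood)),
    }
    for name, shape in expected.items():
        d = getattr(community, name)
        if d.shape != shape:
            problems.append(f"{name} has shape {d.shape}, expected {shape}")
        else:
            _check_distance_matrix(d, name, problems)

    if nI == 0 or community.total_population <= 0:
        problems.append("total population must be positive")

    if problems:
        raise CommunityValidationError(problems)
    return community


def compute_coverage_sets(community: Community, S: float) -> CoverageSets:
    """Derive the binary coverage matrices at driving-distance threshold ``S``.

    The threshold is inclusive: an entry is 1 exactly when the driving
    distance is <= S miles.

    Parameters
    ----------
    community
        A validated problem instance with distance matrices.
    S
        Recommended driving distance in miles; must be positive.
    """
    if not (S > 0):
        raise ValueError(f"driving-distance threshold S must be positive, got {S}")
    validate_community(community)
    return CoverageSets(
        e=(community.d_market <= S),
        n=(community.d_candidate <= S),
        f=(community.d_fastfood <= S),
        S=float(S),
    )


def demand_from_population(
    populations, per_capita_servings: float = DEFAULT_PER_CAPITA_SERVINGS
) -> np.ndarray:
    """Monthly FV demand per neighborhood from population and a per-capita rate.

    demand_i = population_i * per_capita_servings (servings/month).
    """
    pops = np.asarray(populations)
    if not per_capita_servings > 0:
        raise ValueError("per_capita_servings must be positive")
    if (pops < 0).any():
        raise ValueError("populations must be nonnegative")
    return pops * per_capita_servings
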