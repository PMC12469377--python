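"""Exhaustive ground-truth solver for desk-scale instances.

Enumerates every candidate open-set and, per open-set, every feasible
assignment of neighborhoods to in-range facilities.  Exponential by nature:
the size caps are enforced, never advisory.  Used to validate the integer
program; every solution it returns is re-audited with
:func:`fvaccess.optimizer.check_feasibility` so an enumeration bug cannot
silently corrupt the ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .community import Community, CoverageSets
from .optimizer import (
    ScenarioConfig,
    Solution,
    _effective_candidate_capacities,
    _mean_ff_ratio_for_open_set,
    check_feasibility,
)

__all__ = ["SizeLimits", "OracleSizeError", "enumerate_optimal"]


@dataclass(frozen=True)
class SizeLimits:
    max_candidates: int = 6
    max_neighborhoods: int = 8


class OracleSizeError(ValueError):
    """The instance exceeds the oracle's enforced size caps."""


def _best_assignment(
    demands: np.ndarray,
    in_range: list[list[tuple[str, int]]],
    capacity: dict[tuple[str, int], int],
    must_use: frozenset[tuple[str, int]],
) -> tuple[int, dict[int, tuple[str, int]] | None]:
    """Depth-first search for a maximal-demand assignment.

    Each neighborhood is assigned to at most one in-range facility with
    enough spare ``capacity``; a leaf is valid only when every facility in
    ``must_use`` serves at least one neighborhood (an opened market may not
    sit idle).  Prunes on the remaining coverable demand.  Returns
    ``(-1, None)`` when no valid assignment exists.
    """
    n = len(demands)
    suffix = np.zeros(n + 1, dtype=np.int64)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] + (demands[k] if in_range[k] else 0)

    best_z = -1
    best_assign: dict[int, tuple[str, int]] | None = None
    assign: dict[int, tuple[str, int]] = {}
    use_count = {fac: 0 for fac in must_use}
    remaining = dict(capacity)

    def rec(k: int, z: int) -> None:
        nonlocal best_z, best_assign
        if z + suffix[k] < best_z:
            return
        if k == n:
            if all(c > 0 for c in use_count.values()) and z > best_z:
                best_z = z
                best_assign = dict(assign)
            return
        # cheap infeasibility prune: an unused must-use facility unreachable
        # from the remaining neighborhoods can never be fed
        for fac, c in use_count.items():
            if c == 0 and not any(fac in in_range[k2] for k2 in range(k, n)):
                return
        for fac in in_range[k]:
            if remaining[fac] >= demands[k]:
                remaining[fac] -= demands[k]
                assign[k] = fac
                if fac in use_count:
                    use_count[fac] += 1
                rec(k + 1, z + int(demands[k]))
                if fac in use_count:
                    use_count[fac] -= 1
                del assign[k]
                remaining[fac] += demands[k]
        rec(k + 1, z)  # leave neighborhood k uncovered

    rec(0, 0)
    return best_z, best_assign


def _solution_from_assignment(
    community: Community, open_set: np.ndarray, assign: dict[int, tuple[str, int]]
) -> Solution:
    nI, nJ, nL = len(community.neighborhoods), len(community.markets), len(community.candidates)
    u = np.zeros((nI, nL), dtype=np.int8)
    v = np.zeros((nI, nJ), dtype=np.int8)
    y = np.zeros(nI, dtype=np.int8)
    for i, (kind, idx) in assign.items():
        y[i] = 1
        if kind == "new":
            u[i, idx] = 1
        else:
            v[i, idx] = 1
    return Solution(
        status="optimal",
        objective=int((community.demands * y).sum()),
        x=open_set.astype(np.int8),
        y=y,
        u=u,
        v=v,
    )


def enumerate_optimal(
    community: Community,
    cov: CoverageSets,
    cfg: ScenarioConfig,
    limits: SizeLimits = SizeLimits(),
) -> Solution:
    """Exhaustively find an optimal siting solution on a small instance.

    Ties between equally-covering open-sets are broken by the configured
    secondary objective (market count or mean fast-food ratio), then by
    lexicographic candidate-id order of the open set.
    """
    nI, nJ, nL = len(community.neighborhoods), len(community.markets), len(community.candidates)
    if nL > limits.max_candidates or nI > limits.max_neighborhoods:
        raise OracleSizeError(
            f"instance size |I|={nI}, |L|={nL} exceeds oracle caps "
            f"(max_neighborhoods={limits.max_neighborhoods}, "
            f"max_candidates={limits.max_candidates})"
        )
    demands = community.demands
    costs = community.candidate_costs
    r_new = _effective_candidate_capacities(community, cfg)
    r_existing = community.market_capacities
    # without the capacity block, service amounts are unconstrained
    big = int(demands.sum()) + 1

    best_key = None
    best_sol: Solution | None = None
    for subset in itertools.product((0, 1), repeat=nL):
        open_set = np.array(subset, dtype=np.int8)
        if cfg.budget_enabled and int((costs * open_set).sum()) > cfg.budget:
            continue

        in_range: list[list[tuple[str, int]]] = []
        for i in range(nI):
            facs = [("existing", j) for j in range(nJ) if cov.e[i, j]]
            facs += [("new", l) for l in range(nL) if open_set[l] and cov.n[i, l]]
            in_range.append(facs)

        if cfg.capacity_enabled:
            capacity = {("existing", j): int(r_existing[j]) for j in range(nJ)}
            capacity.update({("new", l): int(r_new[l]) for l in range(nL) if open_set[l]})
        else:
            capacity = {("existing", j): big for j in range(nJ)}
            capacity.update({("new", l): big for l in range(nL) if open_set[l]})

        must_use = frozenset(("new", l) for l in range(nL) if open_set[l])
        z, assign = _best_assignment(demands, in_range, capacity, must_use)
        if assign is None:
            continue  # no assignment satisfies "every opened market serves someone"

        sol = _solution_from_assignment(community, open_set, assign)
        violations = check_feasibility(sol, community, cov, cfg)
        if violations:  # self-verification: enumeration bug, never a skip
            raise AssertionError(
                "oracle produced an infeasible assignment: "
                + "; ".join(map(str, violations))
            )
        if cfg.secondary_objective == "min_ff_ratio":
            secondary = (
                _mean_ff_ratio_for_open_set(community, cov, open_set),
                sol.num_new_markets,
            )
        elif cfg.secondary_objective == "min_new_markets":
            secondary = (sol.num_new_markets,)
        else:
            secondary = ()
        key = (-z, *secondary, tuple(c.id for c, o in zip(community.candidates, open_set) if o))
        if best_key is None or key < best_key:
            best_key, best_sol = key, sol
    assert best_sol is not None  # the empty open-set always admits do-nothing
    return best_sol
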