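"""Integer program for siting new FV markets.

The model is a capacitated, budgeted variant of the maximal covering location
problem (MCLP).  Binary decision variables:

* ``x_l`` — open a new FV market at candidate site l,
* ``y_i`` — neighborhood i has an FV market within the driving threshold S,
* ``u_il`` — neighborhood i is served by new market l,
* ``v_ij`` — neighborhood i is served by existing market j.

Objective: maximize total covered demand  z = sum_i a_i y_i.

Constraint blocks (names used throughout the code and in feasibility reports):

* ``coverage_link``   y_i - (sum_l u_il + sum_j v_ij) = 0 for every i — a
  neighborhood counts as covered exactly when it is assigned to one in-range
  market; with binary variables the equality also forces single assignment.
* ``open_link_ub``    M*x_l >= sum_i u_il — assignments to l only if l opens
  (big-M linking; M = |I| is the tightest valid constant).
* ``open_link_lb``    x_l <= sum_i u_il — an opened market must serve someone.
* ``existing_range``  v_ij <= e_ij — assignment only within range.
* ``new_range``       u_il <= n_il.
* ``existing_cap``    sum_i a_i v_ij <= r_j       (capacity block)
* ``new_cap``         sum_i a_i u_il <= r_l       (capacity block)
* ``single_assign``   sum_j v_ij + sum_l u_il <= 1 (capacity block)
* ``budget``          sum_l c_l x_l <= p          (budget block)

Fast-food exposure ``w_ik`` is not a choice: it is fixed to the coverage
indicator f_ik and carried as a reported quantity only.  The fast-food-versus-
FV exposure differential R_i is likewise an accounting identity computed from
a solution (see :mod:`fvaccess.reporting`), never a constraint — imposing it
as an equality bound would make most instances infeasible.

The backend is HiGHS through :func:`scipy.optimize.milp`, run to proved
optimality (zero relative gap) and deterministic for a fixed instance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .community import Community, CoverageSets

__all__ = [
    "ScenarioConfig",
    "SolverOptions",
    "ModelSpec",
    "Solution",
    "Violation",
    "build_model",
    "solve_model",
    "check_feasibility",
]

SecondaryObjective = Literal["none", "min_new_markets", "min_ff_ratio"]


@dataclass(frozen=True)
class ScenarioConfig:
    """One intervention cell: threshold, budget, capacity level, model options.

    ``budget`` is the monthly funding p available to operate new markets; set
    ``budget_enabled=False`` for an unlimited budget.  ``new_market_capacity``
    uniformly overrides every candidate's service capacity (the grid's
    capacity factor applies to new markets only).  ``big_M`` defaults to the
    number of neighborhoods, the tightest valid linking constant.
    """

    S: float
    budget: int | None = None
    capacity_enabled: bool = True
    budget_enabled: bool = True
    new_market_capacity: int | None = None
    big_M: int | None = None
    secondary_objective: SecondaryObjective = "min_new_markets"

    def __post_init__(self):
        if not self.S > 0:
            raise ValueError("S must be positive")
        if self.budget_enabled:
            if self.budget is None:
                raise ValueError("budget_enabled requires a budget (p)")
            if self.budget < 0:
                raise ValueError("budget must be nonnegative")
        if self.secondary_objective not in ("none", "min_new_markets", "min_ff_ratio"):
            raise ValueError(f"unknown secondary objective {self.secondary_objective!r}")


@dataclass(frozen=True)
class SolverOptions:
    """Backend selection and limits for :func:`solve_model`."""

    name: str = "highs"
    max_seconds: float = 60.0
    seed: int = 0


@dataclass(frozen=True)
class ConstraintSpec:
    """One linear constraint row: lb <= coeffs . vars <= ub."""

    label: str  # e.g. "coverage_link[i=2]"
    block: str  # constraint-block name, e.g. "coverage_link"
    coeffs: dict[int, float]
    lb: float
    ub: float


@dataclass
class ModelSpec:
    """Solver-agnostic encoding of the integer program.

    ``var_names[k]`` documents column k; all variables are binary.  The
    objective is to maximize ``objective . vars``.
    """

    var_names: list[str]
    objective: np.ndarray
    constraints: list[ConstraintSpec]
    # index bookkeeping (column ranges of each variable family)
    nI: int
    nJ: int
    nL: int
    cfg: ScenarioConfig = field(repr=False, default=None)

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def block_count(self, block: str) -> int:
        return sum(1 for c in self.constraints if c.block == block)

    # column layout: x (nL) | y (nI) | u (nI*nL, i-major) | v (nI*nJ, i-major)
    def ix(self, l: int) -> int:
        return l

    def iy(self, i: int) -> int:
        return self.nL + i

    def iu(self, i: int, l: int) -> int:
        return self.nL + self.nI + i * self.nL + l

    def iv(self, i: int, j: int) -> int:
        return self.nL + self.nI + self.nI * self.nL + i * self.nJ + j


@dataclass(frozen=True)
class Solution:
    """An (attempted) solution of the siting model.

    ``objective`` is covered demand z in servings/month.  ``x``, ``y``, ``u``
    and ``v`` are 0/1 integer arrays with the shapes of the model instance.
    """

    status: Literal["optimal", "infeasible", "limit_reached"]
    objective: int
    x: np.ndarray  # |L|
    y: np.ndarray  # |I|
    u: np.ndarray  # |I| x |L|
    v: np.ndarray  # |I| x |J|

    @property
    def num_new_markets(self) -> int:
        return int(self.x.sum())

    def total_cost(self, community: Community) -> int:
        return int((community.candidate_costs * self.x).sum())

    def chosen_site_ids(self, community: Community) -> list[str]:
        return [c.id for c, open_ in zip(community.candidates, self.x) if open_]

    def to_dict(self, community: Community) -> dict:
        return {
            "status": self.status,
            "objective_servings": int(self.objective),
            "chosen_site_ids": self.chosen_site_ids(community),
            "coverage_flags": {
                n.id: int(yi) for n, yi in zip(community.neighborhoods, self.y)
            },
            "assignments": self.assignment_pairs(community),
            "num_new_markets": self.num_new_markets,
            "total_cost": self.total_cost(community),
        }

    def assignment_pairs(self, community: Community) -> list[dict]:
        pairs = []
        for i, n in enumerate(community.neighborhoods):
            for l, c in enumerate(community.candidates):
                if self.u[i, l]:
                    pairs.append({"neighborhood": n.id, "facility": c.id, "kind": "new"})
            for j, m in enumerate(community.markets):
                if self.v[i, j]:
                    pairs.append({"neighborhood": n.id, "facility": m.id, "kind": "existing"})
        return pairs


def _effective_candidate_capacities(community: Community, cfg: ScenarioConfig) -> np.ndarray:
    if cfg.new_market_capacity is not None:
        return np.full(len(community.candidates), int(cfg.new_market_capacity), dtype=np.int64)
    return community.candidate_capacities


def build_model(community: Community, cov: CoverageSets, cfg: ScenarioConfig) -> ModelSpec:
    """Assemble the integer program for a community, coverage sets and config.

    Raises a configuration error when the coverage sets were computed at a
    different threshold than the scenario asks for.
    """
    if cov.S != cfg.S:
        raise ValueError(
            f"coverage sets computed at S={cov.S} but scenario requires S={cfg.S}"
        )
    nI, nJ, nL = len(community.neighborhoods), len(community.markets), len(community.candidates)
    big_M = cfg.big_M if cfg.big_M is not None else nI
    if big_M < nI:
        raise ValueError(f"big_M={big_M} is smaller than the number of neighborhoods {nI}")

    a = community.demands
    r_existing = community.market_capacities
    r_new = _effective_candidate_capacities(community, cfg)
    costs = community.candidate_costs

    var_names = (
        [f"x[{c.id}]" for c in community.candidates]
        + [f"y[{n.id}]" for n in community.neighborhoods]
        + [f"u[{n.id},{c.id}]" for n in community.neighborhoods for c in community.candidates]
        + [f"v[{n.id},{m.id}]" for n in community.neighborhoods for m in community.markets]
    )
    spec = ModelSpec(
        var_names=var_names,
        objective=np.zeros(len(var_names)),
        constraints=[],
        nI=nI,
        nJ=nJ,
        nL=nL,
        cfg=cfg,
    )
    for i in range(nI):
        spec.objective[spec.iy(i)] = a[i]

    cons = spec.constraints
    # coverage definition: y_i - sum_l u_il - sum_j v_ij = 0
    for i in range(nI):
        coeffs = {spec.iy(i): 1.0}
        for l in range(nL):
            coeffs[spec.iu(i, l)] = -1.0
        for j in range(nJ):
            coeffs[spec.iv(i, j)] = -1.0
        cons.append(ConstraintSpec(f"coverage_link[i={i}]", "coverage_link", coeffs, 0.0, 0.0))
    # big-M linking: sum_i u_il - M x_l <= 0
    for l in range(nL):
        coeffs = {spec.iu(i, l): 1.0 for i in range(nI)}
        coeffs[spec.ix(l)] = -float(big_M)
        cons.append(ConstraintSpec(f"open_link_ub[l={l}]", "open_link_ub", coeffs, -np.inf, 0.0))
    # opened markets must serve someone: x_l - sum_i u_il <= 0
    for l in range(nL):
        coeffs = {spec.iu(i, l): -1.0 for i in range(nI)}
        coeffs[spec.ix(l)] = 1.0
        cons.append(ConstraintSpec(f"open_link_lb[l={l}]", "open_link_lb", coeffs, -np.inf, 0.0))
    # range restrictions: v_ij <= e_ij, u_il <= n_il
    for i in range(nI):
        for j in range(nJ):
            cons.append(
                ConstraintSpec(
                    f"existing_range[i={i},j={j}]", "existing_range",
                    {spec.iv(i, j): 1.0}, -np.inf, float(cov.e[i, j]),
                )
            )
    for i in range(nI):
        for l in range(nL):
            cons.append(
                ConstraintSpec(
                    f"new_range[i={i},l={l}]", "new_range",
                    {spec.iu(i, l): 1.0}, -np.inf, float(cov.n[i, l]),
                )
            )
    if cfg.capacity_enabled:
        for j in range(nJ):
            coeffs = {spec.iv(i, j): float(a[i]) for i in range(nI)}
            cons.append(
                ConstraintSpec(f"existing_cap[j={j}]", "existing_cap", coeffs, -np.inf, float(r_existing[j]))
            )
        for l in range(nL):
            coeffs = {spec.iu(i, l): float(a[i]) for i in range(nI)}
            cons.append(
                ConstraintSpec(f"new_cap[l={l}]", "new_cap", coeffs, -np.inf, float(r_new[l]))
            )
        for i in range(nI):
            coeffs = {spec.iv(i, j): 1.0 for j in range(nJ)}
            coeffs.update({spec.iu(i, l): 1.0 for l in range(nL)})
            cons.append(ConstraintSpec(f"single_assign[i={i}]", "single_assign", coeffs, -np.inf, 1.0))
    if cfg.budget_enabled:
        coeffs = {spec.ix(l): float(costs[l]) for l in range(nL)}
        cons.append(ConstraintSpec("budget", "budget", coeffs, -np.inf, float(cfg.budget)))
    return spec


def _constraints_to_sparse(spec: ModelSpec, extra: list[ConstraintSpec] = ()) -> LinearConstraint | None:
    rows, cols, vals, lbs, ubs = [], [], [], [], []
    all_cons = list(spec.constraints) + list(extra)
    if not all_cons:
        return None
    for r, con in enumerate(all_cons):
        for c, v in con.coeffs.items():
            rows.append(r)
            cols.append(c)
            vals.append(v)
        lbs.append(con.lb)
        ubs.append(con.ub)
    A = csr_matrix((vals, (rows, cols)), shape=(len(all_cons), spec.n_vars))
    return LinearConstraint(A, np.array(lbs), np.array(ubs))


_STATUS = {0: "optimal", 1: "limit_reached", 2: "infeasible"}


def _run_milp(spec: ModelSpec, objective: np.ndarray, sense: int,
              options: SolverOptions, extra: list[ConstraintSpec] = ()):
    """Run HiGHS on the model with the given objective (sense=-1: maximize)."""
    constraints = _constraints_to_sparse(spec, extra)
    with warnings.catch_warnings():
        # output_flag is passed through to HiGHS to keep its log off stdout;
        # scipy flags it as unrecognized
        warnings.filterwarnings("ignore", message="Unrecognized options", category=RuntimeWarning)
        res = milp(
            c=sense * objective,
            constraints=constraints,
            integrality=np.ones(spec.n_vars),
            bounds=Bounds(0, 1),
            options={"time_limit": options.max_seconds, "mip_rel_gap": 0.0, "output_flag": False},
        )
    status = _STATUS.get(res.status, "limit_reached")
    return res, status


def _extract(spec: ModelSpec, values: np.ndarray, status: str, demands: np.ndarray) -> Solution:
    vals = np.rint(values).astype(np.int8)
    x = np.array([vals[spec.ix(l)] for l in range(spec.nL)], dtype=np.int8)
    y = np.array([vals[spec.iy(i)] for i in range(spec.nI)], dtype=np.int8)
    u = np.array(
        [[vals[spec.iu(i, l)] for l in range(spec.nL)] for i in range(spec.nI)], dtype=np.int8
    ).reshape(spec.nI, spec.nL)
    v = np.array(
        [[vals[spec.iv(i, j)] for j in range(spec.nJ)] for i in range(spec.nI)], dtype=np.int8
    ).reshape(spec.nI, spec.nJ)
    return Solution(status=status, objective=int((demands * y).sum()), x=x, y=y, u=u, v=v)


def _do_nothing_solution(spec: ModelSpec) -> Solution:
    return Solution(
        status="optimal",
        objective=0,
        x=np.zeros(spec.nL, dtype=np.int8),
        y=np.zeros(spec.nI, dtype=np.int8),
        u=np.zeros((spec.nI, spec.nL), dtype=np.int8),
        v=np.zeros((spec.nI, spec.nJ), dtype=np.int8),
    )


def _mean_ff_ratio_for_open_set(community: Community, cov: CoverageSets, x: np.ndarray) -> float:
    """Unrounded mean fast-food-to-FV ratio for a given open set (see reporting)."""
    ff = cov.f.sum(axis=1)
    fv = cov.e.sum(axis=1) + cov.n @ x
    return float(np.mean(ff / np.maximum(fv, 1)))


def solve_model(
    community: Community,
    cov: CoverageSets,
    cfg: ScenarioConfig,
    options: SolverOptions = SolverOptions(),
) -> Solution:
    """Solve the siting model to proved optimality.

    When ``cfg.secondary_objective`` is set, optimal coverage is fixed first
    and the secondary criterion is optimized lexicographically:

    * ``min_new_markets`` — a second MILP minimizes the number of openings
      subject to coverage staying at its optimum (the deterministic default);
    * ``min_ff_ratio`` — candidate open-sets achieving optimal coverage are
      enumerated and the one minimizing the mean fast-food-to-FV ratio is
      kept (ties: fewer markets, then lexicographic site ids).  Exhaustive by
      design; refused above 12 candidate sites.

    A valid instance always admits the do-nothing solution, so ``infeasible``
    never occurs here; it would indicate an adapter bug and raises.
    """
    spec = build_model(community, cov, cfg)
    if spec.nL == 0 and spec.nJ == 0:
        return _do_nothing_solution(spec)
    res, status = _run_milp(spec, spec.objective, -1, options)
    if status == "infeasible":
        raise RuntimeError(
            "solver reported infeasible, but the do-nothing solution is always "
            "feasible: solver-adapter bug"
        )
    if status != "optimal":
        if res.x is None:
            return _do_nothing_solution(spec)
        sol = _extract(spec, res.x, "limit_reached", community.demands)
        return sol
    best = _extract(spec, res.x, "optimal", community.demands)
    z_star = best.objective

    if cfg.secondary_objective == "none" or spec.nL == 0:
        return best

    lock = ConstraintSpec(
        "lock_coverage", "lock_coverage",
        {spec.iy(i): float(community.demands[i]) for i in range(spec.nI)},
        float(z_star), np.inf,
    )
    if cfg.secondary_objective == "min_new_markets":
        count_obj = np.zeros(spec.n_vars)
        for l in range(spec.nL):
            count_obj[spec.ix(l)] = 1.0
        res2, status2 = _run_milp(spec, count_obj, +1, options, extra=[lock])
        if status2 == "optimal":
            return _extract(spec, res2.x, "optimal", community.demands)
        return best  # fall back to the coverage-optimal incumbent

    # min_ff_ratio: exhaustive search over open sets at optimal coverage
    if spec.nL > 12:
        raise ValueError("min_ff_ratio enumeration is limited to 12 candidate sites")
    costs = community.candidate_costs
    best_key = None
    best_sol = best
    for subset in itertools.product((0, 1), repeat=spec.nL):
        x_fixed = np.array(subset, dtype=np.int8)
        if cfg.budget_enabled and int((costs * x_fixed).sum()) > cfg.budget:
            continue
        fix_cons = [
            ConstraintSpec(f"fix_x[{l}]", "fix_x", {spec.ix(l): 1.0},
                           float(x_fixed[l]), float(x_fixed[l]))
            for l in range(spec.nL)
        ]
        res3, status3 = _run_milp(spec, spec.objective, -1, options, extra=fix_cons)
        if status3 != "optimal":
            continue
        cand = _extract(spec, res3.x, "optimal", community.demands)
        if cand.objective != z_star:
            continue
        key = (
            _mean_ff_ratio_for_open_set(community, cov, x_fixed),
            int(x_fixed.sum()),
            tuple(c.id for c, o in zip(community.candidates, x_fixed) if o),
        )
        if best_key is None or key < best_key:
            best_key, best_sol = key, cand
    return best_sol


@dataclass(frozen=True)
class Violation:
    """One constraint violation found by :func:`check_feasibility`."""

    equation: str
    index: str
    lhs: int
    rhs: int

    def __str__(self) -> str:
        return f"{self.equation}[{self.index}]: lhs={self.lhs} vs rhs={self.rhs}"


def check_feasibility(
    sol: Solution, community: Community, cov: CoverageSets, cfg: ScenarioConfig
) -> list[Violation]:
    """Audit a solution against every enabled constraint in exact integer arithmetic.

    Returns an empty list iff the solution is feasible; each violation names
    the constraint block, the index, and both sides of the inequality.
    """
    nI, nJ, nL = len(community.neighborhoods), len(community.markets), len(community.candidates)
    if sol.x.shape != (nL,) or sol.y.shape != (nI,) or sol.u.shape != (nI, nL) or sol.v.shape != (nI, nJ):
        raise ValueError("solution dimensions do not match the community instance")
    big_M = cfg.big_M if cfg.big_M is not None else nI
    a = community.demands
    x = sol.x.astype(np.int64)
    y = sol.y.astype(np.int64)
    u = sol.u.astype(np.int64)
    v = sol.v.astype(np.int64)
    out: list[Violation] = []

    for arr, name in ((x, "x"), (y, "y"), (u, "u"), (v, "v")):
        if ((arr != 0) & (arr != 1)).any():
            out.append(Violation("binary", name, int(arr.min()), 1))

    for i in range(nI):
        lhs = int(y[i] - u[i].sum() - v[i].sum())
        if lhs != 0:
            out.append(Violation("coverage_link", f"i={i}", lhs, 0))
    for l in range(nL):
        if int(u[:, l].sum()) > big_M * int(x[l]):
            out.append(Violation("open_link_ub", f"l={l}", int(u[:, l].sum()), big_M * int(x[l])))
        if int(x[l]) > int(u[:, l].sum()):
            out.append(Violation("open_link_lb", f"l={l}", int(x[l]), int(u[:, l].sum())))
    for i in range(nI):
        for j in range(nJ):
            if v[i, j] > cov.e[i, j]:
                out.append(Violation("existing_range", f"i={i},j={j}", int(v[i, j]), int(cov.e[i, j])))
        for l in range(nL):
            if u[i, l] > cov.n[i, l]:
                out.append(Violation("new_range", f"i={i},l={l}", int(u[i, l]), int(cov.n[i, l])))
    if cfg.capacity_enabled:
        r_existing = community.market_capacities
        r_new = _effective_candidate_capacities(community, cfg)
        for j in range(nJ):
            lhs = int((a * v[:, j]).sum())
            if lhs > r_existing[j]:
                out.append(Violation("existing_cap", f"j={j}", lhs, int(r_existing[j])))
        for l in range(nL):
            lhs = int((a * u[:, l]).sum())
            if lhs > r_new[l]:
                out.append(Violation("new_cap", f"l={l}", lhs, int(r_new[l])))
        for i in range(nI):
            lhs = int(v[i].sum() + u[i].sum())
            if lhs > 1:
                out.append(Violation("single_assign", f"i={i}", lhs, 1))
    if cfg.budget_enabled:
        lhs = int((community.candidate_costs * x).sum())
        if lhs > cfg.budget:
            out.append(Violation("budget", "", lhs, int(cfg.budget)))
    return out
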