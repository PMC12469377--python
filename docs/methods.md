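# Methods

## The siting model

`fvaccess` formulates produce-market placement as a capacitated, budgeted
maximal covering location problem (MCLP). A neighborhood counts as having
access when an FV market — existing or newly opened — lies within the
recommended driving distance S, and the model opens the set of new markets
that maximizes covered monthly FV demand. The formulation makes three
structural assumptions:

* **Threshold coverage.** Access is binary at the threshold: a market at
  distance S covers a neighborhood, one at S + 0.01 miles does not. The
  threshold is inclusive (d ≤ S) so boundary ties count as covered.
* **Single assignment.** Each covered neighborhood is served by exactly one
  market. In the base model (capacity block off) this follows from the
  coverage equality y_i = Σ u_iℓ + Σ v_ij with binary variables — the right
  side can only be 0 or 1 — so the equality must not be relaxed to ≤. With
  the capacity block on, an explicit Σ v + Σ u ≤ 1 row restates it.
* **Demand as servings.** Neighborhood demand a_i is monthly FV servings
  (population × per-capita rate), and market capacity is the monthly
  servings a market can supply. A market cannot serve more demand than its
  capacity, and a neighborhood's demand is not splittable across markets.

Two further modeling decisions were genuinely open and are resolved as
follows:

* **The exposure differential is accounting, not a constraint.** The
  quantity R_i = Σ_k f_ik − Σ_j e_ij − Σ_ℓ n_iℓ x_ℓ (in-range fast-food
  outlets in excess of in-range FV markets) is computed from every solution
  by `reporting.exposure_differential`. Imposing it as a hard equality or
  bound would make most instances infeasible — fast-food exposure is not a
  decision the siting model controls — so it is reported, never enforced.
  Likewise the fast-food exposure indicator w_ik is fixed to the coverage
  indicator f_ik and carried as a reported quantity.
* **Tie-breaking between alternate optima.** Coverage-optimal solutions are
  frequently non-unique. `solve_model` therefore applies a lexicographic
  secondary objective after fixing optimal coverage: `min_new_markets`
  (default — deterministic and parsimonious), `min_ff_ratio` (open
  additional affordable markets that reduce the mean fast-food-to-FV
  ratio), or `none` (solver-arbitrary). `min_ff_ratio` is implemented by
  exhaustive enumeration over candidate open-sets at optimal coverage
  (refused above 12 candidates): the mean-of-ratios objective is
  non-convex in the open-set because of the zero-denominator rule, and
  instances are desk-scale by design.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| S, driving distance | miles | 1 / 2.5 / 5 (grid); 5 = benchmark | 5 miles is a standard rural produce-access benchmark; 1 and 2.5 probe stricter standards |
| p, monthly budget | $/month | 15,000 / 20,000 / 25,000 | $20k/month matches federal farmers-market support programs (~$250k/year); ±$5k probes sensitivity |
| r_ℓ, new-market capacity | servings/month | 20,000 / 40,000 / 80,000 | low / normal / high service levels; at 60 servings/person/month, 40k serves ≈667 people |
| per-capita FV demand | servings/person/month | **60** | ≈2 servings/day; makes one normal-capacity market serve a small neighborhood. This is a documented assumption, configurable in `GeneratorConfig` and `demand_from_population` |
| big-M | — | \|I\| | tightest valid constant for the opening-link row, since Σ_i u_iℓ ≤ \|I\| |
| circuity | — | 1.3 | driving distance ≈ 1.3 × Euclidean on rural road networks; used only when distances are derived from coordinates |
| solver | — | HiGHS (scipy) | proved optimality (zero gap) required; deterministic for a fixed instance |

Monetary values, demands and capacities are integers (whole servings,
whole currency units); fractional inputs are rejected at parse time so the
feasibility audit can re-evaluate every constraint in exact integer
arithmetic.

## The synthetic generator

No real community instance is available, so `fvaccess.synthetic` generates
towns with the structure the model assumes. The default configuration
describes a small rural town: 12 neighborhoods and 8,000 residents on a
12-mile square, one established FV market, 8 fast-food outlets, 6 empty
commercial spaces renting at $8,000–14,000/month. Population is split by a
symmetric Dirichlet (concentration 2.0 — moderately uneven neighborhoods),
floored, with the residual added to the last neighborhood so the total is
exact.

The layout encodes the stylized facts of an underserved rural town:

* neighborhoods scatter isotropically around a town core (sd 15 % of the
  extent), so the town is compact relative to the 5-mile benchmark radius;
* fast-food outlets cluster on a short highway strip through the core —
  rural fast food concentrates near the main road, so essentially every
  neighborhood is exposed to the whole strip at 5 driving miles;
* the existing market sits well off-center (32 % of the extent from the
  population-weighted centroid, direction random), so only part of the
  population is within 5 driving miles of it;
* candidate sites are uniform over the town area.

This geometry makes the two benchmark statistics roughly independent: the
fast-food:FV ratio is near the outlet count (everyone sees the strip,
covered neighborhoods see one market) while coverage is set by how much
population falls on the market's side of town. `calibrate_to_benchmark`
then searches seeds until the do-nothing evaluation at 5 miles lands in
the coverage band [44, 49]% and ratio band [7, 9] — a band, not a point:
exact reproduction of any real community's figures from a random generator
would be false precision. The packaged fixture is the first accepted seed
(6) of the default search; tests verify it regenerates bit-identically.

The existing market's capacity defaults to total community demand: an
incumbent grocer's produce supply scales with its customer base, and the
service-capacity intervention factor concerns **new** markets only. This
also keeps the do-nothing benchmark (a purely geometric evaluation, no
optimization) consistent with a capacity-constrained scenario whose budget
admits no openings. Users modeling a supply-constrained incumbent can set
`existing_capacity` explicitly.

What the generator does **not** emulate: road-network routing (distances
are circuity-scaled Euclidean), within-neighborhood heterogeneity, store
choice behavior, affordability or acceptability of produce, and seasonal
demand. Passing tests on synthetic towns therefore validate the
optimization and reporting machinery, not any real community's outcomes;
conclusions about a real town require its own instance files.

## Outcome definitions and rounding

* **Coverage** is population-weighted in reports (percent of residents in
  covered neighborhoods) while the objective is demand-weighted; with
  demand proportional to population (the generator default) they coincide.
  Both are exposed (`coverage_percent`, `demand_coverage_percent`).
* **Fast-food:FV ratio** is computed per neighborhood as in-range fast-food
  outlets over in-range FV markets, with an FV-free neighborhood
  contributing its fast-food count over a denominator of 1, then aggregated
  by unweighted mean. The aggregation is configurable (`mean`,
  `population_weighted`, `citywide`) because non-integer published ratios
  identify a per-neighborhood aggregate but not the exact scheme.
* **Rounding** is half-up everywhere: 1 decimal for percentages and ratios,
  nearest integer for benchmark-relative improvement percentages; implemented
  with `decimal.Decimal` to avoid binary-float round-to-even surprises.
* **Improvements** are relative: coverage improvement
  100·(scenario − benchmark)/benchmark, ratio improvement
  100·(benchmark − scenario)/benchmark (improvement = reduction); both are
  undefined (an error) at a zero benchmark. Point differences are plain
  subtraction at 1 decimal.

## Verification strategy

The integer program is validated against an independent exhaustive oracle
(`enumerate_optimal`): every candidate open-set within budget, and per
open-set every assignment of neighborhoods to in-range facilities with
spare capacity, searched depth-first with remaining-demand pruning. The
oracle refuses instances beyond its caps (8 neighborhoods, 6 candidates) —
enforced, not advisory — and re-audits every assignment it produces with
`check_feasibility`, so an enumeration bug cannot silently corrupt ground
truth. The test suite checks exact objective agreement on 210 randomized
instances across base / +capacity / +capacity+budget configurations,
monotonicity of the optimum in S, p and r (50 fixtures each), and a clean
constraint-by-constraint audit of every solver solution. The acceptance
script (`scripts/acceptance.py`) re-runs these sweeps at 120 + 40
instances; problem sizes were chosen so the whole suite completes in well
under a minute on one CPU.

## Degenerate inputs and numerical edges

* A valid instance always admits the do-nothing solution, so an
  `infeasible` solver status is treated as an adapter bug and raised.
* An opened market must serve at least one neighborhood (x_ℓ ≤ Σ u_iℓ);
  candidate sites out of range of every neighborhood therefore stay closed.
* Zero-population or zero-market communities evaluate cleanly where
  defined (ratio uses the zero-denominator rule; coverage requires positive
  total population).
* Coverage matrices are recomputed from distances for each threshold; the
  model builder rejects coverage sets computed at a different S than the
  scenario's.

## Known limitations

* The mean-of-ratios exposure aggregate weights small and large
  neighborhoods equally; the population-weighted variant is provided but
  not the reported default.
* `min_ff_ratio` tie-breaking enumerates open-sets and is exponential in
  the candidate count (capped at 12).
* The model is single-period: no market entry/exit dynamics, no demand
  response to new supply.
* Distances are one-directional (neighborhood → facility) and assumed
  finite; travel time, transit and pedestrian access are out of scope.
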