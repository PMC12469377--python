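# fvaccess

Optimal placement of fruit-and-vegetable (FV) markets in rural communities.

Many rural towns have one produce market and a strip of fast-food outlets:
residents who live more than a few driving miles from the market have, in
practice, no convenient access to fresh produce. `fvaccess` is a
decision-support library for community food-environment planning. Given a
community — neighborhoods with monthly FV demand, existing FV markets,
empty commercial spaces that could host a new market, fast-food outlets,
and driving distances — it decides **how many new FV markets to open and
where**, maximizing the population with access within a recommended driving
distance, subject to market service capacity and a monthly operating
budget. A factorial scenario engine then compares interventions (distance
standard × budget × capacity) against the do-nothing benchmark.

## The model

A capacitated, budgeted variant of the maximal covering location problem
(MCLP), solved as an integer program. With neighborhoods *i ∈ I*, existing
markets *j ∈ J*, candidate sites *ℓ ∈ L* and fast-food outlets *k ∈ K*,
coverage indicators are derived from driving distances: *e<sub>ij</sub> = 1*
iff *d<sub>ij</sub> ≤ S* (inclusive; likewise *n<sub>iℓ</sub>*,
*f<sub>ik</sub>*). Binary decisions: open a site (*x<sub>ℓ</sub>*), cover a
neighborhood (*y<sub>i</sub>*), assign it to a new (*u<sub>iℓ</sub>*) or
existing (*v<sub>ij</sub>*) market.

    max  z = Σᵢ aᵢ yᵢ                                   covered demand (servings/month)
    s.t. yᵢ = Σₗ u_iℓ + Σⱼ v_ij            ∀i           coverage ⇔ one in-range assignment
         M·xₗ ≥ Σᵢ u_iℓ ;  xₗ ≤ Σᵢ u_iℓ    ∀ℓ           open ⇔ serves someone (M = |I|)
         v_ij ≤ e_ij ;  u_iℓ ≤ n_iℓ        ∀i,j,ℓ       in-range assignments only
         Σᵢ aᵢ v_ij ≤ rⱼ ;  Σᵢ aᵢ u_iℓ ≤ rₗ ∀j,ℓ        service capacity (optional block)
         Σⱼ v_ij + Σₗ u_iℓ ≤ 1             ∀i           single assignment (optional block)
         Σₗ cₗ xₗ ≤ p                                   monthly budget (optional block)

Reported outcomes per scenario: **population coverage** (% of residents in
covered neighborhoods), **number of new markets**, and the
**fast-food-to-FV ratio** (in-range fast-food outlets per in-range FV
market, averaged over neighborhoods). The per-neighborhood exposure
differential *Rᵢ = Σₖ f_ik − Σⱼ e_ij − Σₗ n_iℓ xₗ* is computed from every
solution as an accounting quantity.

The solver backend is HiGHS via `scipy.optimize.milp`, run to proved
optimality. Ties between equally-covering solutions are broken
lexicographically — by default the fewest new markets; optionally the
open-set that minimizes the fast-food ratio. An exhaustive enumeration
oracle (`fvaccess.oracle`) provides independent ground truth on small
instances, and `check_feasibility` re-audits any solution constraint by
constraint in exact integer arithmetic.

Because no real community instance is distributed, `fvaccess.synthetic`
generates random rural towns and calibrates them (by seed search) to a
benchmark band of 44–49 % do-nothing coverage and a fast-food:FV ratio of
7–9 at 5 driving miles. One calibrated instance ships with the package
(`load_calibrated_community()`).

## Worked example

```python
from fvaccess import (ScenarioConfig, load_calibrated_community,
                      run_benchmark, run_scenario)

community = load_calibrated_community()
bench = run_benchmark(community, S=5.0)
scenario = run_scenario(community, ScenarioConfig(S=5.0, budget=20_000,
                                                  new_market_capacity=40_000))
print(bench.coverage_pct, scenario.coverage_pct, scenario.chosen_site_ids)
```

prints (see `examples/02_solve_single_scenario.py`):

```
benchmark coverage : 45.6%  (no new markets)
scenario coverage  : 49.1%  (1 new market(s) at c03)
monthly cost       : $9,882 of the $20,000 budget
fast-food : FV     : 7.0 -> 5.7
```

45.6 % of the 8,000 residents start with an FV market within 5 driving
miles; opening one market at site c03 (cost $9,882/month) raises coverage
to 49.1 % — the 40,000 servings/month capacity, not the budget, is what
limits the gain — and cuts the mean fast-food-to-FV exposure from 7.0 to
5.7. `examples/03_factorial_grid.py` runs the full 27-scenario grid plus
the benchmark row and reports improvements relative to the benchmark.

The same pipeline is available from the shell:

```sh
fvaccess generate --seed 6 --out community.json
fvaccess solve --community community.json --distance 5 --budget 20000 --capacity 40000
fvaccess grid --community community.json --out results.csv
fvaccess report --results results.csv --out improvements.csv
```

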