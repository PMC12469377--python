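"""Solve one siting scenario on the packaged community.

Opens new FV markets at empty commercial sites to maximize the demand covered
within 5 driving miles, under a $20,000/month budget and a 40,000
servings/month service capacity per new market.
"""

from fvaccess import (
    ScenarioConfig,
    compute_coverage_sets,
    load_calibrated_community,
    run_benchmark,
    run_scenario,
)

community = load_calibrated_community()
cfg = ScenarioConfig(S=5.0, budget=20_000, new_market_capacity=40_000)

bench = run_benchmark(community, 5.0)
scenario = run_scenario(community, cfg)

print(f"benchmark coverage : {bench.coverage_pct}%  (no new markets)")
print(f"scenario coverage  : {scenario.coverage_pct}%  "
      f"({scenario.new_markets} new market(s) at {', '.join(scenario.chosen_site_ids)})")
print(f"monthly cost       : ${scenario.total_cost:,} of the ${cfg.budget:,} budget")
print(f"fast-food : FV     : {bench.ff_fv_ratio} -> {scenario.ff_fv_ratio}")
print()
print("The solver picks the site(s) whose 5-mile catchment adds the most")
print("residents, subject to each new market's service capacity and the budget.")
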