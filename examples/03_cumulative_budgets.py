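"""Grid alignment, trapezoid cumulation and Monte-Carlo uncertainty.

Runs the full pipeline on a default campaign and prints the cumulative
chase-window budgets per treatment group: respired CO2, absolute respired
tracer, and the fraction of assimilated label respired belowground.
"""

from pulsechase import RunConfig, SyntheticScenario, generate_scenario, run_pipeline

data = generate_scenario(SyntheticScenario(seed=1))
res = run_pipeline(data, RunConfig(seed=1))

s = res.summary
chase = s[s["window"] == "chase"]
units = {"co2": "mol CO2 m-2", "abs13c": "mg 13C m-2", "rel13c": "fraction"}
for var in ("co2", "abs13c", "rel13c"):
    print(f"\n{var} over the 120-h chase ({units[var]}):")
    sub = chase[chase["variable"] == var]
    for _, r in sub.iterrows():
        pc = "" if r.isna()["percent_change"] else \
            f"   drought vs control: {-r['percent_change']:+.1f}%"
        print(f"  {r['land_use']:>9} {r['treatment']:>8}: "
              f"{r['mean']:8.4f} ± {r['sd']:.4f} (n={int(r['n'])}){pc}")

one = next(c for c in res.cumulatives if c.variable == "co2")
print(f"\nexample Monte-Carlo uncertainty ({one.monolith_id}): "
      f"total={one.total:.4f}, mc_sd={one.mc_sd:.4f}, "
      f"95% interval=({one.mc_interval[0]:.4f}, {one.mc_interval[1]:.4f})")
# Between-replicate SDs exceed the per-monolith Monte-Carlo sd: biological
# variability dominates the methodological uncertainty.
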