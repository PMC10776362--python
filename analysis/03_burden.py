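#!/usr/bin/env python
"""Attributable mortality burden of the simulated scenario.

Central-estimate deaths, YLL, and per-capita LLE by year and pollutant,
plus crude vs age-standardised all-cause mortality (2013 reference
structure).  Writes results/burden_summary.csv.
"""

from pathlib import Path

import pandas as pd

from airburden import age_standardized_rate, compute_burden, read_inputs

bundle = read_inputs("scratch/bundle")
years = sorted(bundle.exposure)

res = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                     bundle.erf_set)

rows = []
for y in years:
    pop = bundle.population[y].total
    for pol in ("pm25", "o3"):
        d = res.national_total(y, pol, "deaths")
        yll = res.national_total(y, pol, "yll")
        rows.append((y, pol, d, yll, res.le0 * yll / pop))
burden = pd.DataFrame(rows, columns=["year", "pollutant", "deaths", "yll", "lle"])

# demography: crude rate rises with aging while age-standardised is flat
ref = bundle.population[years[0]].subgroup_totals()
ref_w = ref / ref.sum()
demo = []
for y in years:
    sub = bundle.population[y].subgroup_totals()
    crude = float((bundle.mortality.all_cause.reindex(sub.index) * sub).sum() / sub.sum())
    std = age_standardized_rate(bundle.mortality.all_cause.reindex(ref_w.index), ref_w)
    demo.append((y, 1000 * crude, 1000 * std))
demo = pd.DataFrame(demo, columns=["year", "crude_per_1000", "standardized_per_1000"])

Path("results").mkdir(exist_ok=True)
burden.to_csv("results/burden_summary.csv", index=False, float_format="%.6g")

print(burden.round(0).to_string(index=False))
print()
print(demo.round(2).to_string(index=False))
print("\nfinding: the fine-particle burden declines in both stages while the "
      "ozone burden rises then falls; population aging raises the crude "
      "mortality rate even though age-specific rates are constant.")
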