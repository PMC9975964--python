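"""Attributable mortality of the 2030 scenarios relative to the 2018 baseline.

Evaluates the three default exposure-response functions at the published
population-weighted annual means.  Positive excess deaths mean the scenario
is deadlier than the 2018 baseline; the mitigation+adaptation scenario comes
out slightly protective while business-as-usual adds >800 deaths per year.
"""

import numpy as np

from cobenefits import ahmedabad
from cobenefits.grids import AnnualSurface, GridSpec, PopulationSurface
from cobenefits.hia import DEFAULT_ERFS, cellwise_hia

grid = GridSpec(4, 4)
ages = ahmedabad.POPULATION["2030"]
pop = PopulationSurface(grid, np.full(grid.shape, ages.total_0_99 / grid.n_cells), ages)
y0 = ahmedabad.BASELINE_MORTALITY
PW = ahmedabad.POPULATION_WEIGHTED_MEAN


def surface(value):
    return AnnualSurface(grid, np.full(grid.shape, value))


baseline = surface(PW["baseline_2018"])
for scenario in ("bau_2030", "ma_2030"):
    print(f"\n{scenario} vs baseline_2018 (delta = {PW[scenario] - PW['baseline_2018']:+.2f} ug/m3)")
    for erf in DEFAULT_ERFS:
        res = cellwise_hia(baseline, surface(PW[scenario]), pop, y0, erf)
        lo, hi = res.ci
        print(
            f"  {erf.name:22s} excess deaths {res.excess_deaths:+8.0f}"
            f"  (95% CI {lo:+.0f}, {hi:+.0f})"
            f"  rate {res.scenario_rate:6.1f}/100k ({res.rate_pct_change:+.2f}%)"
        )

print(
    "\nEach row re-runs the full cellwise computation at the ERF's risk CI"
    "\nbounds; intervals bracket the central estimate."
)
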