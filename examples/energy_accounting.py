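"""Scenario energy and CO2 bookkeeping.

Prints the warming increment, the cooling-demand offset achieved by cool
roofs, the renewable substitution of the coal plant's supply, and the CO2
avoided by the mitigation and adaptation actions.
"""

from cobenefits import ahmedabad
from cobenefits.energy import (
    co2_avoided,
    cool_roof_savings,
    cooling_demand_delta,
    substitute_supply,
    warming_increment,
)

base, bau, ma = (
    ahmedabad.CLIMATE["baseline_2018"],
    ahmedabad.CLIMATE["bau_2030"],
    ahmedabad.CLIMATE["ma_2030"],
)
print(f"warming 2018 -> 2030:            {warming_increment(base, bau):+.2f} C")

delta = cooling_demand_delta(
    ahmedabad.ENERGY["bau_2030"].cooling_demand, ahmedabad.ENERGY["ma_2030"].cooling_demand
)
print(f"cool roofs cut cooling demand by {delta:.2f} TWh/yr")
print(f"  (gross savings from 20.60 km2:  {cool_roof_savings(20.60):.4f} TWh/yr)")

substituted = substitute_supply(ahmedabad.ENERGY["bau_2030"])
print(
    f"renewables replace the coal plant: {ahmedabad.ENERGY['bau_2030'].tpp_supply:.2f} TWh"
    f" -> renewable supply {substituted.renewable_supply:.2f} TWh"
)

lo, hi = co2_avoided(ahmedabad.ENERGY["bau_2030"].tpp_supply)
print(f"CO2 avoided by substitution:     {lo:.2f}-{hi:.2f} Mt/yr")
lo_cr, _ = co2_avoided(delta, (0.9095, 0.9095))
print(f"CO2 avoided by cool roofs:       {lo_cr:.3f} Mt/yr")
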