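"""Published Ahmedabad study inputs.

Scalar inputs of the Ahmedabad co-benefits study: monthly PM2.5 means and
standard deviations from the chemical-transport model for the three
scenarios, citywide populations and baseline mortality, the climate/energy
table, and the reported exposure and mortality aggregates used for
cross-checks.  Scenario keys are ``baseline_2018``, ``bau_2030``, ``ma_2030``
(business-as-usual and mitigation+adaptation).
"""

from __future__ import annotations

from .energy import ClimateSummary, EnergyScenario
from .grids import AgeStructure
from .hia import BaselineMortality

SCENARIOS = ("baseline_2018", "bau_2030", "ma_2030")

#: Monthly average PM2.5 (µg m⁻³) per representative month, per scenario.
MONTHLY_PM25 = {
    "baseline_2018": {"Jan": 74.46, "May": 69.72, "Jul": 38.95, "Oct": 86.20},
    "bau_2030": {"Jan": 92.83, "May": 66.51, "Jul": 39.52, "Oct": 75.15},
    "ma_2030": {"Jan": 92.42, "May": 66.37, "Jul": 38.13, "Oct": 74.95},
}

#: Spatial standard deviations of the monthly fields (µg m⁻³).
MONTHLY_PM25_SD = {
    "baseline_2018": {"Jan": 15.56, "May": 13.64, "Jul": 9.35, "Oct": 21.56},
    "bau_2030": {"Jan": 14.40, "May": 12.61, "Jul": 8.23, "Oct": 17.14},
    "ma_2030": {"Jan": 14.19, "May": 12.43, "Jul": 7.67, "Oct": 17.04},
}

#: Citywide populations by age band for the two analysis years.
POPULATION = {
    "2018": AgeStructure(8_459_139, 6_344_354, 5_921_397),
    "2030": AgeStructure(9_308_479, 7_488_672, 7_116_333),
}

#: All-cause baseline mortality rate, ages 30-99, per 100 000.
BASELINE_MORTALITY = BaselineMortality(684.21, age_band="30_99")

#: Reported seasonally ("manually") weighted annual city means (µg m⁻³).
MANUAL_ANNUAL_MEAN = {"baseline_2018": 63.40, "bau_2030": 65.50, "ma_2030": 64.90}

#: Reported population-weighted annual means (µg m⁻³).
POPULATION_WEIGHTED_MEAN = {
    "baseline_2018": 71.04,
    "bau_2030": 75.18,
    "ma_2030": 70.93,
}

#: Reported 2030-vs-2018 excess deaths (central, lo, hi) per ERF.
REPORTED_EXCESS_DEATHS = {
    "pope_all_cause": {"bau_2030": (1389, 1092, 1681), "ma_2030": (-25, -22, -28)},
    "turner_all_cause": {"bau_2030": (1193, 793, 1585), "ma_2030": (-23, -18, -27)},
    "gemm_non_accidental": {"bau_2030": (870, 648, 1088), "ma_2030": (-52, -38, -66)},
}

#: Climate summaries per scenario.
CLIMATE = {
    "baseline_2018": ClimateSummary(27.58, 3.58, 55.13),
    "bau_2030": ClimateSummary(28.39, 3.38, 53.10),
    "ma_2030": ClimateSummary(28.39, 3.38, 53.10),
}

#: Energy supply/demand per scenario (TWh; cool-roof area in km²).
ENERGY = {
    "baseline_2018": EnergyScenario(
        tpp_supply=1.70, surat_supply=4.43, renewable_supply=0.73,
        cooling_demand=1.46, added_cool_roof_area_km2=0.0,
        label="baseline_2018",
    ),
    "bau_2030": EnergyScenario(
        tpp_supply=2.10, surat_supply=5.26, renewable_supply=6.63,
        cooling_demand=4.22, added_cool_roof_area_km2=0.0,
        label="bau_2030",
    ),
    "ma_2030": EnergyScenario(
        tpp_supply=0.0, surat_supply=5.26, renewable_supply=8.73,
        cooling_demand=4.01, added_cool_roof_area_km2=20.60,
        label="ma_2030",
    ),
}
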