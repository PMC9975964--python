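"""Annual exposure metrics.

Four representative monthly fields are collapsed into one annual surface with
season-length weights (winter 3/12, pre-monsoon 3/12, monsoon 4/12,
post-monsoon 2/12).  The monsoon month therefore carries the largest weight.
From the annual surface the module derives the two citywide summaries used
throughout the analysis — the unweighted ("manually weighted" seasonal) city
mean and the population-weighted mean — plus scenario differences and the
seasonal model-vs-monitor bias diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import (
    MONTHS,
    AnnualSurface,
    ConcentrationField,
    GridError,
    PopulationSurface,
    SeasonalCalendar,
    default_calendar,
)

__all__ = [
    "annual_average",
    "city_mean",
    "population_weighted_mean",
    "delta_exposure",
    "seasonal_model_bias",
    "DeltaExposure",
    "SeasonalBiasReport",
]


def annual_average(
    monthly_fields: Mapping[str, ConcentrationField],
    calendar: SeasonalCalendar | None = None,
    scenario: str = "",
) -> AnnualSurface:
    """Seasonally weighted annual surface: per cell, Σ_s w_s · C_s.

    Requires exactly one field per representative month; weights come from
    the calendar (months represented / 12) and sum to one, so a year of
    identical fields maps to itself.
    """
    calendar = calendar or default_calendar()
    missing = [m for m in MONTHS if m not in monthly_fields]
    if missing:
        raise ValueError(f"missing representative months: {missing}")
    weights = calendar.weights
    grid = monthly_fields[MONTHS[0]].grid
    values = np.zeros(grid.shape)
    for month in MONTHS:
        field = monthly_fields[month]
        if field.grid.shape != grid.shape:
            raise GridError("monthly fields are on different grids")
        values += weights[month] * field.values
    return AnnualSurface(grid, values, scenario=scenario)


def city_mean(surface: AnnualSurface) -> float:
    """Unweighted arithmetic mean over all grid cells (µg m⁻³)."""
    return float(surface.values.mean())


def population_weighted_mean(
    surface: AnnualSurface, pop: PopulationSurface, band: str = "0_99"
) -> float:
    """Σ(C_i · P_i) / Σ P_i over cells, using the band's cell populations.

    Because the age structure is spatially uniform, every band yields the
    same weighted mean; the band argument documents which population the
    exposure is attached to.
    """
    if surface.grid.shape != pop.grid.shape:
        raise GridError("surface and population grids do not match")
    weights = pop.band_persons(band)
    total = weights.sum()
    if total <= 0:
        raise ZeroDivisionError(f"age band {band} has zero total population")
    return float((surface.values * weights).sum() / total)


@dataclass(frozen=True)
class DeltaExposure:
    """Scenario-minus-reference exposure change."""

    delta_cells: np.ndarray          # per-cell ΔC, µg m⁻³
    delta_pw_mean: float             # Δ population-weighted mean, µg m⁻³
    pct_change: float                # % relative to the reference pw mean
    reference_pw_mean: float
    scenario_pw_mean: float


def delta_exposure(
    scenario: AnnualSurface,
    reference: AnnualSurface,
    pop: PopulationSurface,
    band: str = "0_99",
) -> DeltaExposure:
    """Cellwise and aggregate exposure change of ``scenario`` vs ``reference``.

    The percent change is relative to the reference population-weighted mean,
    i.e. "% change from the later scenario to the baseline" as exposure
    tables report it.
    """
    if scenario.grid.shape != reference.grid.shape:
        raise GridError("scenario and reference grids do not match")
    ref_pw = population_weighted_mean(reference, pop, band)
    scen_pw = population_weighted_mean(scenario, pop, band)
    delta = scen_pw - ref_pw
    return DeltaExposure(
        delta_cells=scenario.values - reference.values,
        delta_pw_mean=delta,
        pct_change=100.0 * delta / ref_pw,
        reference_pw_mean=ref_pw,
        scenario_pw_mean=scen_pw,
    )


@dataclass(frozen=True)
class SeasonalBiasReport:
    """Per-season percent difference between monitored and modeled means.

    ``percent[season] = 100 · (monitored − modeled) / monitored``; positive
    values mean the model underestimates.  Seasons with no monitor data are
    absent from ``percent`` and listed in ``missing``.
    """

    percent: dict[str, float]
    n_days: dict[str, int]
    missing: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"season": s, "percent_difference": p, "n_days": self.n_days[s]}
            for s, p in self.percent.items()
        ]
        rows += [
            {"season": s, "percent_difference": float("nan"), "n_days": 0}
            for s in self.missing
        ]
        return pd.DataFrame(rows)


def seasonal_model_bias(
    modeled: Mapping[str, ConcentrationField],
    monitors: pd.DataFrame,
    calendar: SeasonalCalendar | None = None,
) -> SeasonalBiasReport:
    """Compare modeled fields with monitor observations season by season.

    For each season the modeled mean is taken at the monitor cells of the
    season's representative month and the monitored mean over the same
    monitor-days; the report gives 100·(monitored − modeled)/monitored.
    """
    calendar = calendar or default_calendar()
    percent: dict[str, float] = {}
    n_days: dict[str, int] = {}
    missing: list[str] = []
    for month in MONTHS:
        season = calendar.season_of(month)
        sub = monitors[monitors["season"] == season]
        if len(sub) == 0:
            missing.append(season)
            continue
        field = modeled[month]
        rows = sub["row"].to_numpy(dtype=int)
        cols = sub["col"].to_numpy(dtype=int)
        if rows.max() >= field.grid.n_rows or cols.max() >= field.grid.n_cols:
            raise IndexError("monitor cell outside the modeled grid")
        modeled_mean = float(field.values[rows, cols].mean())
        monitored_mean = float(sub["value"].mean())
        percent[season] = 100.0 * (monitored_mean - modeled_mean) / monitored_mean
        n_days[season] = int(sub["date"].nunique())
    return SeasonalBiasReport(percent=percent, n_days=n_days, missing=tuple(missing))
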