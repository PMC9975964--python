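"""Seeded synthetic inputs: gridded PM2.5 surfaces, a point-source plume,
population rasters, and monitor time series.

These generators emulate the statistical structure of a chemical-transport
model's monthly output and of a hybrid gridded population product, so the
whole exposure → health pipeline can be exercised end-to-end without any
external data.  They make no attempt at atmospheric chemistry: the background
is spatially correlated noise around configured seasonal means, and the
power-plant plume is an isotropic exponential kernel whose amplitude scales
with the scenario emission multiplier (1.0 baseline, 1.06 business-as-usual,
0.0 when the plant's emissions are removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (
    MONTH_NUMBER,
    MONTHS,
    AgeStructure,
    AnnualSurface,
    ConcentrationField,
    GridSpec,
    PopulationSurface,
    SeasonalCalendar,
    default_calendar,
)

__all__ = [
    "PointSource",
    "simulate_background",
    "apply_point_source",
    "simulate_population",
    "grow_population",
    "simulate_monitors",
    "largest_remainder_round",
]


@dataclass(frozen=True)
class PointSource:
    """A stationary emission source (the coal plant) seen by the grid.

    ``monthly_contribution`` is the concentration added at the source cell
    (µg m⁻³) for a given month, either one value for all months or a mapping
    per representative month.  The plume decays isotropically as
    ``exp(-d / decay_length)`` with ``d`` the Euclidean distance in cells.
    ``emission_scale`` multiplies the whole plume: 1.0 at baseline, 1.06 for
    the 6% generation growth scenario, 0.0 when emissions are eliminated.
    """

    location: tuple[int, int]
    monthly_contribution: float | Mapping[str, float]
    decay_length: float
    emission_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.emission_scale < 0:
            raise ValueError("emission_scale must be >= 0")

    def contribution_for(self, month: str) -> float:
        if isinstance(self.monthly_contribution, Mapping):
            return float(self.monthly_contribution[month])
        return float(self.monthly_contribution)


def simulate_background(
    grid: GridSpec,
    season_means: Mapping[str, float],
    spatial_sd: float | Mapping[str, float],
    correlation_length: float,
    seed: int,
) -> dict[str, ConcentrationField]:
    """Generate one spatially correlated field per representative month.

    Each field is Gaussian noise smoothed at ``correlation_length`` (cells),
    rescaled to the requested spatial standard deviation, shifted to the
    month's mean, and clipped at zero.  Identical arguments and seed give
    bit-identical output.

    Parameters
    ----------
    season_means
        Representative month -> target citywide mean (µg m⁻³).
    spatial_sd
        Cell-to-cell standard deviation (µg m⁻³), a scalar or per month.
    correlation_length
        Gaussian smoothing length in cells; 0 gives white noise.
    """
    missing = [m for m in MONTHS if m not in season_means]
    if missing:
        raise ValueError(f"season_means missing months: {missing}")
    if any(season_means[m] < 0 for m in MONTHS):
        raise ValueError("season_means must be >= 0")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")

    def sd_for(month: str) -> float:
        sd = spatial_sd[month] if isinstance(spatial_sd, Mapping) else spatial_sd
        if sd < 0:
            raise ValueError("spatial_sd must be >= 0")
        return float(sd)

    rng = np.random.default_rng(seed)
    fields: dict[str, ConcentrationField] = {}
    for month in MONTHS:  # fixed order keeps the stream reproducible
        sd = sd_for(month)
        values = np.full(grid.shape, float(season_means[month]))
        if sd > 0:
            noise = rng.standard_normal(grid.shape)
            if correlation_length > 0:
                noise = gaussian_filter(noise, sigma=correlation_length, mode="reflect")
            spread = noise.std()
            if spread > 0:
                noise = (noise - noise.mean()) * (sd / spread)
            values = values + noise
        values = np.clip(values, 0.0, None)
        fields[month] = ConcentrationField(grid, month, values)
    return fields


def _plume_kernel(grid: GridSpec, location: tuple[int, int], decay_length: float) -> np.ndarray:
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    d = np.hypot(rows - location[0], cols - location[1])
    return np.exp(-d / decay_length)


def apply_point_source(
    field: ConcentrationField, source: PointSource
) -> ConcentrationField:
    """Superimpose the source plume on a field (input left unmodified).

    The increment is ``emission_scale * contribution * exp(-d/decay_length)``
    with ``d`` the Euclidean cell distance to the source; the kernel is 1 at
    the source cell.  Plumes are additive, so applying two sources commutes.
    """
    row, col = source.location
    if not field.grid.contains(row, col):
        raise IndexError(
            f"source location {source.location} outside grid {field.grid.shape}"
        )
    amplitude = source.emission_scale * source.contribution_for(field.month)
    if amplitude == 0.0:
        return field.with_values(field.values)
    kernel = _plume_kernel(field.grid, source.location, source.decay_length)
    return field.with_values(field.values + amplitude * kernel)


def largest_remainder_round(shares: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real allocations to integers summing exactly to
    ``total`` (largest-remainder / Hamilton method; ties broken by index)."""
    shares = np.asarray(shares, dtype=float)
    if np.any(shares < 0):
        raise ValueError("shares must be non-negative")
    s = shares.sum()
    if s <= 0:
        raise ValueError("shares must have a positive sum")
    scaled = shares * (total / s)
    base = np.floor(scaled).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        remainders = scaled - base
        # stable argsort descending: ties go to the lower flat index
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def simulate_population(
    grid: GridSpec,
    age_structure: AgeStructure,
    concentration_gradient_weight: float = 0.0,
    seed: int = 0,
    reference_surface: AnnualSurface | ConcentrationField | None = None,
) -> PopulationSurface:
    """Allocate the citywide population over the grid.

    Cell weights are independent Gamma(2, 1) draws (a clumpy but everywhere
    positive density).  If ``concentration_gradient_weight`` w > 0 and a
    reference surface is supplied, weights are additionally multiplied by
    ``1 + w * C_norm`` with ``C_norm`` the min-max normalised concentration,
    so population co-locates with pollution and the population-weighted mean
    exceeds the unweighted mean — the structure the exposure tables show.

    Integer persons per cell sum exactly to ``age_structure.total_0_99``
    (largest-remainder rounding).
    """
    if concentration_gradient_weight < 0:
        raise ValueError("concentration_gradient_weight must be >= 0")
    rng = np.random.default_rng(seed)
    weights = rng.gamma(shape=2.0, scale=1.0, size=grid.shape)
    if concentration_gradient_weight > 0:
        if reference_surface is None:
            raise ValueError(
                "a reference_surface is required when "
                "concentration_gradient_weight > 0"
            )
        c = reference_surface.values
        span = c.max() - c.min()
        c_norm = (c - c.min()) / span if span > 0 else np.zeros_like(c)
        weights = weights * (1.0 + concentration_gradient_weight * c_norm)
    total = int(round(age_structure.total_0_99))
    persons = largest_remainder_round(weights.ravel(), total).reshape(grid.shape)
    return PopulationSurface(grid, persons.astype(float), age_structure)


def grow_population(
    pop: PopulationSurface, target: AgeStructure
) -> PopulationSurface:
    """Rescale a population surface to new citywide totals.

    Every cell is scaled by ``target.total_0_99 / current_total`` and
    re-rounded so the total matches exactly; the spatial pattern (cell
    shares) is preserved up to rounding.  Age-band totals follow the target
    structure's fractions.
    """
    current = pop.total()
    if current <= 0:
        raise ZeroDivisionError("cannot grow a population with zero total")
    total = int(round(target.total_0_99))
    persons = largest_remainder_round(pop.persons.ravel(), total).reshape(
        pop.grid.shape
    )
    return PopulationSurface(pop.grid, persons.astype(float), target)


def simulate_monitors(
    fields: Mapping[str, ConcentrationField],
    n_monitors: int,
    bias_by_season: Mapping[str, float],
    noise_sd: float,
    seed: int,
    days_per_month: int = 30,
    calendar: SeasonalCalendar | None = None,
) -> pd.DataFrame:
    """Simulate daily monitor observations with a known seasonal model bias.

    A model that under-reads the truth by fraction ``b`` satisfies
    ``modeled = (1 - b) * truth``; monitors observe the truth, so monitor
    values are generated as ``field / (1 - b) + noise``.  The injected bias
    is then recoverable by :func:`cobenefits.exposure.seasonal_model_bias`.

    Returns a long table with columns ``monitor_id, row, col, date, month,
    season, value`` — ``n_monitors`` distinct cells × ``days_per_month`` days
    for each representative month.
    """
    calendar = calendar or default_calendar()
    grid = next(iter(fields.values())).grid
    if not 1 <= n_monitors <= grid.n_cells:
        raise ValueError("n_monitors must be between 1 and the number of cells")
    for b in bias_by_season.values():
        if b >= 1.0:
            raise ValueError("bias must be < 1 (fractional underestimate)")
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_cells, size=n_monitors, replace=False)
    rows, cols = np.unravel_index(flat, grid.shape)

    records = []
    for month in MONTHS:
        field = fields[month]
        season = calendar.season_of(month)
        bias = float(bias_by_season.get(season, 0.0))
        base = field.values[rows, cols] / (1.0 - bias)
        for day in range(1, days_per_month + 1):
            noise = rng.normal(0.0, noise_sd, size=n_monitors) if noise_sd > 0 else 0.0
            values = base + noise
            for i in range(n_monitors):
                records.append(
                    {
                        "monitor_id": f"M{i:02d}",
                        "row": int(rows[i]),
                        "col": int(cols[i]),
                        "date": f"2018-{MONTH_NUMBER[month]:02d}-{day:02d}",
                        "month": month,
                        "season": season,
                        "value": float(values[i]) if noise_sd > 0 else float(base[i]),
                    }
                )
    return pd.DataFrame.from_records(records)
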