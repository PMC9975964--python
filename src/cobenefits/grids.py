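"""Core gridded domain types.

The study domain is a regular lon/lat grid of square cells (default
resolution 4.2 km²) covering a city and its surroundings.  Cell indexing is
row-major and 0-based with cell ``(0, 0)`` at the southwest corner, so row
index increases northward and column index increases eastward.

Concentrations are daily-average PM2.5 in µg m⁻³.  A year is represented by
four fields, one per representative month (Jan, May, Jul, Oct), each standing
in for a whole season of the Indian meteorological calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Representative months, in calendar order, one per season.
MONTHS = ("Jan", "May", "Jul", "Oct")

#: Age bands tracked by the population surface.
AGE_BANDS = ("0_99", "25_99", "30_99")


class GridError(ValueError):
    """Invalid grid geometry or a field/grid shape mismatch."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the study grid.

    Parameters
    ----------
    n_rows, n_cols
        Number of cells along latitude / longitude.
    cell_area_km2
        Area of one grid cell in km².
    origin_lon, origin_lat
        Coordinates of the southwest corner of cell ``(0, 0)`` in degrees.
    cell_size_deg
        Angular size of a cell edge in degrees.
    """

    n_rows: int
    n_cols: int
    cell_area_km2: float = 4.2
    origin_lon: float = 72.40
    origin_lat: float = 22.85
    cell_size_deg: float = 0.0185

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_area_km2 <= 0:
            raise GridError("cell_area_km2 must be positive")
        if self.cell_size_deg <= 0:
            raise GridError("cell_size_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center; row 0 is the southernmost row."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size_deg
        lat = self.origin_lat + (row + 0.5) * self.cell_size_deg
        return lon, lat

    def lon_lat_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell center coordinates as (n_rows, n_cols) arrays."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        lon = self.origin_lon + (cols + 0.5) * self.cell_size_deg
        lat = self.origin_lat + (rows + 0.5) * self.cell_size_deg
        return lon, lat

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def _validated_values(grid: GridSpec, values, *, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise GridError(
            f"{what} shape {arr.shape} does not match grid {grid.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{what} contains negative values")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class ConcentrationField:
    """One representative month's gridded daily-average PM2.5 (µg m⁻³)."""

    grid: GridSpec
    month: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.month not in MONTHS:
            raise ValueError(f"month must be one of {MONTHS}, got {self.month!r}")
        object.__setattr__(
            self, "values", _validated_values(self.grid, self.values, what="field")
        )

    def mean(self) -> float:
        """Unweighted spatial mean over all cells."""
        return float(self.values.mean())

    def with_values(self, values) -> "ConcentrationField":
        return replace(self, values=values)


@dataclass(frozen=True)
class AnnualSurface:
    """Seasonally weighted annual daily-average PM2.5 per cell (µg m⁻³)."""

    grid: GridSpec
    values: np.ndarray
    scenario: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _validated_values(self.grid, self.values, what="surface")
        )

    def mean(self) -> float:
        return float(self.values.mean())

    def with_values(self, values) -> "AnnualSurface":
        return replace(self, values=values)


@dataclass(frozen=True)
class AgeStructure:
    """Citywide population totals for the nested age bands used in the HIA."""

    total_0_99: float
    total_25_99: float
    total_30_99: float

    def __post_init__(self) -> None:
        if min(self.total_0_99, self.total_25_99, self.total_30_99) <= 0:
            raise ValueError("population totals must be positive")
        if not (self.total_30_99 <= self.total_25_99 <= self.total_0_99):
            raise ValueError(
                "age bands must nest: total_30_99 <= total_25_99 <= total_0_99"
            )

    def total(self, band: str) -> float:
        if band not in AGE_BANDS:
            raise ValueError(f"unknown age band {band!r}, expected one of {AGE_BANDS}")
        return getattr(self, f"total_{band}")

    def fraction(self, band: str) -> float:
        """Share of the all-age total in ``band`` (citywide, applied uniformly)."""
        return self.total(band) / self.total_0_99


@dataclass(frozen=True)
class PopulationSurface:
    """Gridded persons (all ages) with a citywide age structure.

    The age structure carries no spatial variation: the population of an age
    band in a cell is the cell total times the citywide band fraction.
    """

    grid: GridSpec
    persons: np.ndarray
    age_structure: AgeStructure

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "persons",
            _validated_values(self.grid, self.persons, what="population"),
        )

    def total(self) -> float:
        return float(self.persons.sum())

    def band_persons(self, band: str) -> np.ndarray:
        """Per-cell persons in an age band (cell total × citywide fraction)."""
        return self.persons * self.age_structure.fraction(band)

    def band_total(self, band: str) -> float:
        return self.total() * self.age_structure.fraction(band)


@dataclass(frozen=True)
class SeasonSpec:
    """One season: name, its representative month, and how many calendar
    months it stands for."""

    name: str
    representative_month: str
    months_represented: int

    def __post_init__(self) -> None:
        if self.representative_month not in MONTHS:
            raise ValueError(f"representative_month must be one of {MONTHS}")
        if self.months_represented < 1:
            raise ValueError("months_represented must be >= 1")


# calendar month number -> season name, Indian meteorological convention
_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "pre-monsoon", 4: "pre-monsoon", 5: "pre-monsoon",
    6: "monsoon", 7: "monsoon", 8: "monsoon", 9: "monsoon",
    10: "post-monsoon", 11: "post-monsoon",
}

#: Calendar month number of each representative month.
MONTH_NUMBER = {"Jan": 1, "May": 5, "Jul": 7, "Oct": 10}


def season_of_calendar_month(month_number: int) -> str:
    """Season name for a calendar month (1..12)."""
    return _MONTH_TO_SEASON[month_number]


@dataclass(frozen=True)
class SeasonalCalendar:
    """The four-season calendar used to weight representative months into an
    annual average.  Weight of a season = months it represents / 12."""

    seasons: tuple[SeasonSpec, ...]

    def __post_init__(self) -> None:
        if len(self.seasons) != 4:
            raise ValueError("calendar must have exactly four seasons")
        total = sum(s.months_represented for s in self.seasons)
        if total != 12:
            raise ValueError(f"months_represented must sum to 12, got {total}")
        months = [s.representative_month for s in self.seasons]
        if sorted(months) != sorted(MONTHS):
            raise ValueError("each representative month must appear exactly once")

    @property
    def weights(self) -> dict[str, float]:
        """Representative month -> annual weight; weights sum to 1."""
        return {
            s.representative_month: s.months_represented / 12.0 for s in self.seasons
        }

    def season_of(self, representative_month: str) -> str:
        for s in self.seasons:
            if s.representative_month == representative_month:
                return s.name
        raise KeyError(representative_month)

    @property
    def season_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.seasons)


def default_calendar() -> SeasonalCalendar:
    """Winter (Jan, 3 months), pre-monsoon (May, 3), monsoon (Jul, 4),
    post-monsoon (Oct, 2)."""
    return SeasonalCalendar(
        (
            SeasonSpec("winter", "Jan", 3),
            SeasonSpec("pre-monsoon", "May", 3),
            SeasonSpec("monsoon", "Jul", 4),
            SeasonSpec("post-monsoon", "Oct", 2),
        )
    )
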