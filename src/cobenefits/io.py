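"""Serialization of gridded fields, surfaces, and monitor series.

The interchange format is a long CSV with one row per cell:
``row, col, lon, lat, month, value`` for monthly fields (``month`` omitted
for annual surfaces).  Fields can also be exported as a NetCDF dataset with
dimensions (month, row, col) through xarray's scipy backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .grids import MONTHS, AnnualSurface, ConcentrationField, GridSpec

__all__ = [
    "fields_to_frame",
    "frame_to_fields",
    "write_fields_csv",
    "read_fields_csv",
    "surface_to_frame",
    "frame_to_surface",
    "fields_to_dataset",
    "write_fields_netcdf",
    "write_monitors_csv",
    "read_monitors_csv",
]


def _coords_frame(grid: GridSpec) -> pd.DataFrame:
    lon, lat = grid.lon_lat_arrays()
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lon": lon.ravel(),
            "lat": lat.ravel(),
        }
    )


def fields_to_frame(fields: Mapping[str, ConcentrationField]) -> pd.DataFrame:
    """Long-format table of monthly fields: row, col, lon, lat, month, value."""
    parts = []
    for month in MONTHS:
        if month not in fields:
            continue
        f = fields[month]
        df = _coords_frame(f.grid)
        df["month"] = month
        df["value"] = f.values.ravel()
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def _grid_from_frame(df: pd.DataFrame, grid: GridSpec | None) -> GridSpec:
    if grid is not None:
        return grid
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    # reconstruct geometry from two cell centers when possible
    kwargs = {}
    if "lon" in df.columns and n_cols > 1:
        c0 = df[(df["row"] == 0) & (df["col"] == 0)].iloc[0]
        c1 = df[(df["row"] == 0) & (df["col"] == 1)].iloc[0]
        step = float(c1["lon"] - c0["lon"])
        kwargs = {
            "cell_size_deg": step,
            "origin_lon": float(c0["lon"]) - 0.5 * step,
            "origin_lat": float(c0["lat"]) - 0.5 * step,
        }
    return GridSpec(n_rows, n_cols, **kwargs)


def frame_to_fields(
    df: pd.DataFrame, grid: GridSpec | None = None
) -> dict[str, ConcentrationField]:
    """Rebuild monthly fields from the long-format table."""
    grid = _grid_from_frame(df, grid)
    fields = {}
    for month, sub in df.groupby("month"):
        values = np.zeros(grid.shape)
        values[sub["row"].to_numpy(int), sub["col"].to_numpy(int)] = sub[
            "value"
        ].to_numpy(float)
        fields[str(month)] = ConcentrationField(grid, str(month), values)
    return fields


def write_fields_csv(fields: Mapping[str, ConcentrationField], path) -> None:
    fields_to_frame(fields).to_csv(path, index=False)


def read_fields_csv(path, grid: GridSpec | None = None) -> dict[str, ConcentrationField]:
    return frame_to_fields(pd.read_csv(path), grid)


def surface_to_frame(surface: AnnualSurface) -> pd.DataFrame:
    df = _coords_frame(surface.grid)
    df["value"] = surface.values.ravel()
    return df


def frame_to_surface(
    df: pd.DataFrame, grid: GridSpec | None = None, scenario: str = ""
) -> AnnualSurface:
    grid = _grid_from_frame(df, grid)
    values = np.zeros(grid.shape)
    values[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["value"].to_numpy(
        float
    )
    return AnnualSurface(grid, values, scenario=scenario)


def fields_to_dataset(fields: Mapping[str, ConcentrationField]) -> xr.Dataset:
    """Monthly fields as an xarray Dataset with dims (month, row, col)."""
    months = [m for m in MONTHS if m in fields]
    grid = fields[months[0]].grid
    lon, lat = grid.lon_lat_arrays()
    data = np.stack([fields[m].values for m in months])
    return xr.Dataset(
        {"pm25": (("month", "row", "col"), data)},
        coords={
            "month": list(months),
            "row": np.arange(grid.n_rows),
            "col": np.arange(grid.n_cols),
            "lon": (("row", "col"), lon),
            "lat": (("row", "col"), lat),
        },
        attrs={"units": "ug m-3", "cell_area_km2": grid.cell_area_km2},
    )


def write_fields_netcdf(fields: Mapping[str, ConcentrationField], path) -> None:
    # scipy backend writes classic NetCDF3 and needs no extra libraries
    fields_to_dataset(fields).to_netcdf(path, engine="scipy")


def write_monitors_csv(monitors: pd.DataFrame, path) -> None:
    monitors.to_csv(path, index=False)


def read_monitors_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
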