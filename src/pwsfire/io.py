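"""File I/O: NetCDF stacks, single-map TIFFs and CSV tables.

Epoch series travel as CF-style NetCDF (one variable, a time dimension
carrying epoch start dates, plus ``year``/``epoch_of_year`` coordinates),
written through xarray's scipy backend. Single maps are float32 TIFFs with
NaN nodata; tables are CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .grid import GridDef
from .preprocess import EpochCalendar, EpochSeries

__all__ = [
    "write_epoch_series",
    "read_epoch_series",
    "write_map",
    "read_map",
    "write_table",
    "read_table",
]

_GRID_ATTRS = ("n_rows", "n_cols", "pixel_area", "x_origin", "y_origin", "dx", "dy", "nodata")


def _grid_attrs(grid: GridDef) -> dict:
    return {f"grid_{k}": getattr(grid, k) for k in _GRID_ATTRS}


def _grid_from_attrs(attrs: dict) -> GridDef:
    kwargs = {k: attrs[f"grid_{k}"] for k in _GRID_ATTRS}
    for k in ("n_rows", "n_cols"):
        kwargs[k] = int(kwargs[k])
    return GridDef(**kwargs)


def write_epoch_series(series: EpochSeries, path: str | Path, name: str = "value") -> None:
    cal = series.calendar
    data = np.where(np.isfinite(series.data), series.data, series.grid.nodata)
    ds = xr.Dataset(
        {name: (("time", "y", "x"), data)},
        coords={
            "time": cal.frame["start"].to_numpy(),
            "year": ("time", cal.years.astype(np.int32)),
            "epoch_of_year": ("time", cal.eoy.astype(np.int32)),
        },
        attrs={"units": series.units, **_grid_attrs(series.grid)},
    )
    ds[name].attrs["units"] = series.units
    ds[name].attrs["_FillValue_sentinel"] = series.grid.nodata
    ds.to_netcdf(path, engine="scipy")


def read_epoch_series(path: str | Path, name: str = "value") -> EpochSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        grid = _grid_from_attrs(ds.attrs)
        years = sorted(set(int(y) for y in ds["year"].values))
        cal = EpochCalendar.from_years(years)
        data = ds[name].values.astype(float)
        units = ds.attrs.get("units", ds[name].attrs.get("units", "1"))
    data = np.where(data == grid.nodata, np.nan, data)
    if data.shape[0] != len(cal):
        raise ValueError(f"{path}: epoch axis does not cover whole years")
    return EpochSeries(data, cal, grid, units)


def write_map(arr: np.ndarray, grid: GridDef, path: str | Path, units: str = "1") -> None:
    """Single-band float TIFF; NaN marks nodata. float64 is kept so that
    resumed pipeline stages reproduce byte-identical results."""
    tifffile.imwrite(
        path,
        np.asarray(arr, dtype=np.float64),
        metadata={"units": units, **_grid_attrs(grid)},
    )


def read_map(path: str | Path) -> tuple[np.ndarray, GridDef]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(float)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    grid = _grid_from_attrs(meta) if "grid_n_rows" in meta else GridDef(*arr.shape)
    return arr, grid


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)
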