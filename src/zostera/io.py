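"""File interfaces: ESRI ASCII grids, observation CSVs, NetCDF field stacks.

Single gridded layers travel as plain-text ESRI ASCII grids; year-stacked
scenario forcing goes through xarray NetCDF (classic format via the scipy
engine); observations are CSV with columns row,col,presence.  No installed
package reads or writes the ASCII grid format, so the (trivial) parser lives
here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .domain import DepthGrid, ObservationSet, ScenarioFields

_NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, cell_size: float, nodata: float = _NODATA) -> None:
    """Write a 2-D field as an ESRI ASCII grid (NaN becomes ``nodata``)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("ASCII grids hold 2-D fields")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (values with NaN nodata, cell size)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if values.shape != expected:
        raise ValueError(f"grid body {values.shape} does not match header {expected}")
    nodata = header.get("nodata_value", _NODATA)
    values[values == nodata] = np.nan
    return values, header["cellsize"]


def write_depth_grid(path, grid: DepthGrid) -> None:
    write_ascii_grid(path, grid.depth, grid.cell_size)


def read_depth_grid(path, max_depth: float | None = None) -> DepthGrid:
    values, cell_size = read_ascii_grid(path)
    values = np.where(np.isfinite(values), values, 0.0)  # nodata -> land
    kwargs = {} if max_depth is None else {"max_depth": max_depth}
    return DepthGrid(depth=values, cell_size=cell_size, **kwargs)


def write_observations(path, obs: ObservationSet) -> None:
    obs.to_frame().to_csv(path, index=False)


def read_observations(path, survey_years: Sequence[int] = ()) -> ObservationSet:
    return ObservationSet.from_frame(pd.read_csv(path), survey_years=survey_years)


def scenario_to_dataset(fields: ScenarioFields) -> xr.Dataset:
    dims = ("year", "row", "col")
    return xr.Dataset(
        {
            "secchi": (dims, fields.secchi),
            "hm0": (dims, fields.hm0),
            "tm02": (dims, fields.tm02),
        },
        coords={"year": list(fields.years)},
        attrs={
            "nutrient_scenario": fields.nutrient_scenario,
            "wave_realization": fields.wave_realization,
        },
    )


def write_scenario_fields(path, fields: ScenarioFields) -> None:
    scenario_to_dataset(fields).to_netcdf(path, engine="scipy")


def read_scenario_fields(path) -> ScenarioFields:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ScenarioFields(
            years=tuple(int(y) for y in ds["year"].values),
            nutrient_scenario=str(ds.attrs["nutrient_scenario"]),
            wave_realization=str(ds.attrs["wave_realization"]),
            secchi=ds["secchi"].values.copy(),
            hm0=ds["hm0"].values.copy(),
            tm02=ds["tm02"].values.copy(),
        )


def scenario_path(outdir, nutrient: str, wave: str) -> Path:
    return Path(outdir) / f"forcing_{nutrient}_{wave}.nc"
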