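"""Gridded result I/O: self-describing array container round-trips.

Results are stored as an xarray Dataset with named dimensions
(scheme, lat, lon), per-variable units strings, and global provenance
attributes (package version, config hash, seed). Files use the classic
netCDF format via the scipy engine, which is lossless for float64.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from . import __version__
from .config import RunConfig, config_hash
from .experiments import RESULT_FIELDS, GriddedResult

UNITS = {f: "umol CO2 m-2 s-1" for f in RESULT_FIELDS} | {
    "gpp": "umol CO2 m-2 s-1"}


def to_dataset(result: GriddedResult, config: RunConfig | None = None,
               seed: int | None = None) -> xr.Dataset:
    schemes = list(result.schemes)
    data = {}
    for f in RESULT_FIELDS:
        stack = np.stack([result.data[s][f] for s in schemes])
        data[f] = xr.DataArray(stack, dims=("scheme", "lat", "lon"),
                               attrs={"units": UNITS[f]})
    data["gpp"] = xr.DataArray(result.gpp, dims=("lat", "lon"),
                               attrs={"units": UNITS["gpp"]})
    cfg = config if config is not None else RunConfig()
    ds = xr.Dataset(
        data,
        coords={"scheme": schemes, "lat": result.lat, "lon": result.lon},
        attrs={
            "package_version": __version__,
            "config_hash": config_hash(cfg),
            "seed": int(cfg.seed if seed is None else seed),
        },
    )
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    return ds


def write_gridded(result: GriddedResult, path: str | Path,
                  config: RunConfig | None = None,
                  seed: int | None = None) -> None:
    """Write a factorial result to a netCDF file (lossless round-trip)."""
    to_dataset(result, config=config, seed=seed).to_netcdf(path, engine="scipy")


def read_gridded(path: str | Path) -> GriddedResult:
    """Read a factorial result back; validates schema and units metadata."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    missing = [f for f in RESULT_FIELDS + ("gpp",) if f not in ds]
    if missing:
        raise ValueError(f"missing field(s) in {path}: {missing}")
    for f in RESULT_FIELDS + ("gpp",):
        if "units" not in ds[f].attrs:
            raise ValueError(f"field {f!r} has no units attribute")
    schemes = [str(s) for s in ds["scheme"].values]
    data = {s: {f: ds[f].values[i].astype(float) for f in RESULT_FIELDS}
            for i, s in enumerate(schemes)}
    return GriddedResult(lat=ds["lat"].values.astype(float),
                         lon=ds["lon"].values.astype(float),
                         data=data, gpp=ds["gpp"].values.astype(float))
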