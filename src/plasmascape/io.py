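"""File I/O helpers: CSV dialects, NetCDF grids, GeoJSON fronts.

Gridded fields and surfaces travel as CF-style NetCDF (lon/lat coordinate
axes, permil units, provenance attributes) written through xarray's scipy
backend; tabular artefacts are plain CSV in the dialects documented on the
readers.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec
from .isoscape import IsoscapeSurface
from .synth import BaselineField, SshField


def surface_to_dataset(surface: IsoscapeSurface, name: str = "value") -> xr.Dataset:
    vg = surface.provenance.get("variogram")
    attrs = {"units": "permil"}
    for k, v in surface.provenance.items():
        if isinstance(v, (str, int, float)):
            attrs[k] = v
    if vg is not None and not isinstance(vg, (str, int, float)):
        attrs["variogram"] = json.dumps({
            "model": vg.model, "nugget": vg.nugget, "psill": vg.psill,
            "range": vg.range_})
    return xr.Dataset(
        {name: (("lat", "lon"), surface.values, attrs)},
        coords={"lon": surface.grid.lon_centers(),
                "lat": surface.grid.lat_centers()})


def write_surface(surface: IsoscapeSurface, path, name: str = "value") -> None:
    surface_to_dataset(surface, name).to_netcdf(path, engine="scipy")


def read_surface(path, name: str = "value") -> IsoscapeSurface:
    ds = xr.open_dataset(path, engine="scipy")
    lon = ds["lon"].to_numpy()
    lat = ds["lat"].to_numpy()
    cs = float(lon[1] - lon[0]) if len(lon) > 1 else float(lat[1] - lat[0])
    grid = GridSpec(cs, float(lon[0]) - cs / 2, float(lat[0]) - cs / 2,
                    len(lon), len(lat))
    values = ds[name].to_numpy()
    prov = dict(ds[name].attrs)
    return IsoscapeSurface(grid, values, np.isfinite(values), prov)


def write_baseline_field(field: BaselineField, path) -> None:
    ds = xr.Dataset(
        {"d13c": (("lat", "lon"), field.d13c, {"units": "permil"}),
         "d15n": (("lat", "lon"), field.d15n, {"units": "permil"})},
        coords={"lon": field.grid.lon_centers(), "lat": field.grid.lat_centers()})
    ds.to_netcdf(path, engine="scipy")


def field_spec_sidecar(field: BaselineField, path) -> None:
    """JSON sidecar of the generating spec, for provenance."""
    out = {iso: dataclasses.asdict(spec) for iso, spec in field.spec.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=list)


def write_ssh_field(ssh: SshField, path) -> None:
    ds = xr.Dataset({"ssh": (("lat", "lon"), ssh.values, {"units": "m"})},
                    coords={"lon": ssh.grid.lon_centers(),
                            "lat": ssh.grid.lat_centers()})
    ds.to_netcdf(path, engine="scipy")


def read_ssh_field(path) -> SshField:
    ds = xr.open_dataset(path, engine="scipy")
    lon = ds["lon"].to_numpy()
    lat = ds["lat"].to_numpy()
    cs = float(lon[1] - lon[0]) if len(lon) > 1 else float(lat[1] - lat[0])
    grid = GridSpec(cs, float(lon[0]) - cs / 2, float(lat[0]) - cs / 2,
                    len(lon), len(lat))
    return SshField(grid, ds["ssh"].to_numpy())


def fronts_to_geojson(front_lines: dict, path) -> None:
    features = []
    for name, fl in front_lines.items():
        features.append({
            "type": "Feature",
            "properties": {"name": name, "ssh_level_m": fl.level},
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)]
                                         for x, y in fl.vertices]}})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def tracks_to_csv(tracks_df: pd.DataFrame, path) -> None:
    out = tracks_df.rename(columns={"time": "timestamp"})
    out.to_csv(path, index=False)


def norm_models_to_json(models: dict, path) -> None:
    out = {sp: dataclasses.asdict(m) for sp, m in models.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
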