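"""Readers and writers for every artifact the pipeline consumes or produces.

Time series, event lists and trajectories round-trip as CSV; reports as
JSON; gridded stacks as NetCDF (classic format via the scipy backend) and
2-D maps as single-band TIFF with a JSON sidecar carrying geometry and the
class vocabulary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .attribution import AnomalySeries
from .drivers import FactorSeries, WildfireEvent
from .spatial import PFT_CLASSES, GriddedSeries, GridField, PFTGrid


# ---------------------------------------------------------------------------
# CSV

def write_series_csv(series: FactorSeries, path) -> None:
    pd.DataFrame(
        {"date": series.timestamps, "value": series.values,
         "kind": series.kind, "units": series.units}
    ).to_csv(path, index=False)


def read_series_csv(path) -> FactorSeries:
    df = pd.read_csv(path)
    return FactorSeries(df["date"].to_numpy(), df["value"].to_numpy(),
                        str(df["kind"].iloc[0]), str(df["units"].iloc[0]))


def write_events_csv(events: Sequence[WildfireEvent], path) -> None:
    rows = []
    for e in events:
        rows.append({
            "year": e.year, "area_ha": e.area, "forest_fraction": e.forest_fraction,
            "green_biomass_density_t_ha": e.green_biomass_density,
            "emission_factors": json.dumps([list(p) for p in e.emission_factors]),
            "duration_days": e.duration,
        })
    pd.DataFrame(rows, columns=["year", "area_ha", "forest_fraction",
                                "green_biomass_density_t_ha", "emission_factors",
                                "duration_days"]).to_csv(path, index=False)


def read_events_csv(path) -> list[WildfireEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        events.append(WildfireEvent(
            area=float(row["area_ha"]),
            forest_fraction=float(row["forest_fraction"]),
            green_biomass_density=float(row["green_biomass_density_t_ha"]),
            emission_factors=tuple(tuple(p) for p in json.loads(row["emission_factors"])),
            duration=None if pd.isna(row["duration_days"]) else float(row["duration_days"]),
            year=None if pd.isna(row["year"]) else int(row["year"]),
        ))
    return events


def write_anomaly_csv(
    series: AnomalySeries, path, smoothed: Optional[Mapping[int, AnomalySeries]] = None
) -> None:
    """Anomaly series with optional smoothed companions (column per window)."""
    data = {"year": series.years, "anomaly_fraction": series.values}
    for window, s in (smoothed or {}).items():
        if not np.array_equal(s.years, series.years):
            raise ValueError(f"smoothed series for window {window} is not aligned")
        data[f"smoothed_{window}yr"] = s.values
    df = pd.DataFrame(data)
    df.attrs["reference_year"] = series.reference_year
    with open(path, "w") as fh:
        fh.write(f"# reference_year={series.reference_year}\n")
        df.to_csv(fh, index=False)


def read_anomaly_csv(path) -> AnomalySeries:
    ref = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# reference_year="):
            ref = int(first.split("=")[1])
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    return AnomalySeries(df["year"].to_numpy(), df["anomaly_fraction"].to_numpy(),
                         ref if ref is not None else int(df["year"].iloc[0]))


# ---------------------------------------------------------------------------
# JSON reports

def write_report_json(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# grids

def write_gridded_netcdf(stack: GriddedSeries, path) -> None:
    ny, nx = stack.grid.shape
    ds = xr.Dataset(
        {
            stack.kind: (("time", "y", "x"), stack.values),
            "pft": (("y", "x"), stack.grid.labels.astype(np.int32)),
        },
        coords={
            "time": stack.timestamps,
            "y": np.arange(ny) * stack.grid.pixel_size,
            "x": np.arange(nx) * stack.grid.pixel_size,
        },
        attrs={
            "pixel_size": stack.grid.pixel_size,
            "classes": ",".join(PFT_CLASSES),
            "kind": stack.kind,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_gridded_netcdf(path) -> GriddedSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        kind = str(ds.attrs["kind"])
        grid = PFTGrid(ds["pft"].values.astype(np.int8), float(ds.attrs["pixel_size"]))
        return GriddedSeries(ds["time"].values, ds[kind].values, grid, kind)


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_pft_tiff(grid: PFTGrid, path) -> None:
    tifffile.imwrite(path, grid.labels.astype(np.uint8))
    with open(_sidecar(path), "w") as fh:
        json.dump({"pixel_size": grid.pixel_size, "geotransform": list(grid.geotransform),
                   "classes": list(PFT_CLASSES)}, fh)


def read_pft_tiff(path) -> PFTGrid:
    labels = tifffile.imread(path).astype(np.int8)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    return PFTGrid(labels, float(meta["pixel_size"]), tuple(meta["geotransform"]))


def write_field_tiff(field: GridField, path) -> None:
    tifffile.imwrite(path, field.values.astype(np.float64))
    with open(_sidecar(path), "w") as fh:
        json.dump({"pixel_size": field.pixel_size, "geotransform": list(field.geotransform),
                   "units": field.units}, fh)


def read_field_tiff(path) -> GridField:
    values = tifffile.imread(path).astype(float)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    return GridField(values, float(meta["pixel_size"]), tuple(meta["geotransform"]),
                     str(meta["units"]))
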