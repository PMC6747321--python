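"""Readers and writers for the pipeline's CSV/GeoJSON interchange formats.

Numeric columns in the exposure table are written with at most five decimal
places, trailing zeros trimmed — the convention of the reference exposure
table, which the writer reproduces byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .exposure import ExposureRecord
from .geostat import PollutionMap
from .mobility import ActivitySegment, segments_to_frame
from .routes import RouteOption

__all__ = [
    "read_stations_csv",
    "read_monitor_csv",
    "read_pings_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_routes_csv",
    "read_routes_geojson",
    "write_exposure_csv",
    "read_exposure_csv",
    "write_map_csv",
    "write_map_geojson",
    "write_map_metadata",
    "fmt5",
]

TRACE_HEADERS = ["Start Time", "End Time", "Latitude", "Longitude", "Activity"]
EXPOSURE_HEADERS = [
    "Start", "End", "Latitude", "Longitude", "PM2.5",
    "Environment", "Activity", "VE", "Exposure",
]


def fmt5(x: float) -> str:
    """Format to 5 decimal places, trailing zeros (and a bare point) trimmed."""
    s = f"{float(x):.5f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def read_stations_csv(path) -> pd.DataFrame:
    """Outdoor station readings: station_id, lon, lat, datetime, pollutant,
    value. Timestamps are truncated to the hour into an ``hour`` column."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    df["hour"] = pd.to_datetime(df["datetime"]).dt.floor("h")
    df = df.drop(columns=["datetime"])
    if (df["value"] < 0).any():
        raise ValidationError("negative concentration in station readings")
    dup = df.duplicated(subset=["station_id", "hour", "pollutant"])
    if dup.any():
        raise ValidationError(
            f"duplicate (station, hour, pollutant) rows: {df.index[dup].tolist()}"
        )
    return df[["station_id", "lon", "lat", "hour", "pollutant", "value"]]


def read_monitor_csv(path) -> pd.DataFrame:
    """Indoor monitor stream, wide (datetime, pm25, co2, voc) or long
    (datetime, pollutant, value); returns wide form with a ``ts`` column."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = "datetime" if "datetime" in df.columns else "ts"
    df["ts"] = pd.to_datetime(df[tcol])
    if "pollutant" in df.columns:  # long form
        wide = df.pivot_table(index="ts", columns="pollutant", values="value")
        wide = wide.reset_index()
        wide.columns.name = None
    else:
        rename = {"pm25": "PM2.5", "pm2.5": "PM2.5", "co2": "CO2", "voc": "VOC"}
        wide = df.rename(columns=rename)[
            ["ts"] + [rename[c] for c in rename if c in df.columns]
        ]
    return wide.sort_values("ts").reset_index(drop=True)


def read_pings_csv(path) -> pd.DataFrame:
    """Beacon ping log: beacon_id, datetime — sorted ascending on ingestion."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = "datetime" if "datetime" in df.columns else "ts"
    df["ts"] = pd.to_datetime(df[tcol])
    if "beacon_id" not in df.columns:
        df["beacon_id"] = "B1"
    return df[["beacon_id", "ts"]].sort_values("ts").reset_index(drop=True)


def read_trace_csv(path) -> pd.DataFrame:
    """Activity trace in the tracking-app export layout (Start Time, End Time,
    Latitude, Longitude, Activity); lowercase variants accepted."""
    df = pd.read_csv(path)
    lower = {c.strip().lower(): c for c in df.columns}
    mapping = {}
    for want, alts in {
        "start": ("start time", "start"),
        "end": ("end time", "end"),
        "lat": ("latitude", "lat"),
        "lon": ("longitude", "lon"),
        "activity": ("activity",),
    }.items():
        for a in alts:
            if a in lower:
                mapping[lower[a]] = want
                break
        else:
            raise ValidationError(f"trace CSV missing a column for {want!r}")
    return df.rename(columns=mapping)[["start", "end", "lat", "lon", "activity"]]


def write_trace_csv(segments: Sequence[ActivitySegment], path) -> None:
    df = segments_to_frame(list(segments))
    out = pd.DataFrame(
        {
            "Start Time": df["start"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "End Time": df["end"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "Latitude": df["lat"],
            "Longitude": df["lon"],
            "Activity": df["activity"].str.capitalize(),
            "Provenance": df["provenance"],
        }
    )
    out.to_csv(path, index=False)


def read_routes_csv(path) -> list[RouteOption]:
    """Routes as (label, seq, lat, lon, datetime) rows, one row per waypoint."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    df["ts"] = pd.to_datetime(df["datetime"])
    options = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("seq")
        options.append(
            RouteOption(
                label=str(label),
                waypoints=list(zip(grp["lat"], grp["lon"], grp["ts"])),
            )
        )
    return options


def read_routes_geojson(path) -> list[RouteOption]:
    """Routes as GeoJSON LineStrings with a per-point ``times`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    options = []
    for feat in gj["features"]:
        coords = feat["geometry"]["coordinates"]  # [lon, lat] order
        times = feat["properties"]["times"]
        options.append(
            RouteOption(
                label=feat["properties"].get("label", f"route{len(options)}"),
                waypoints=[
                    (lat, lon, pd.Timestamp(t))
                    for (lon, lat), t in zip(coords, times)
                ],
            )
        )
    return options


def write_exposure_csv(records: Sequence[ExposureRecord], path) -> None:
    """Exposure timeline in the canonical column order (Start, End, Latitude,
    Longitude, PM2.5, Environment, Activity, VE, Exposure), minute-resolution
    times and 5-d.p.-trimmed numbers."""
    lines = [",".join(EXPOSURE_HEADERS)]
    for r in records:
        lines.append(
            ",".join(
                [
                    r.start.strftime("%Y-%m-%d %H:%M"),
                    r.end.strftime("%Y-%m-%d %H:%M"),
                    fmt5(r.lat),
                    fmt5(r.lon),
                    fmt5(r.sz),
                    r.environment.capitalize(),
                    r.activity.capitalize(),
                    fmt5(r.ve),
                    fmt5(r.exposure),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_exposure_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["Start"] = pd.to_datetime(df["Start"])
    df["End"] = pd.to_datetime(df["End"])
    return df


def write_map_csv(pmap: PollutionMap, path) -> None:
    """Flat (lon, lat, value) export of a map's grid nodes."""
    glon, glat = np.meshgrid(pmap.grid_lons, pmap.grid_lats)
    pd.DataFrame(
        {"lon": glon.ravel(), "lat": glat.ravel(), "value": pmap.values.ravel()}
    ).to_csv(path, index=False)


def write_map_geojson(pmap: PollutionMap, path) -> None:
    """Grid cells as GeoJSON polygons with the node value as a property."""
    xs, ys = pmap.grid_lons, pmap.grid_lats
    feats = []
    for j in range(len(ys) - 1):
        for i in range(len(xs) - 1):
            ring = [
                [xs[i], ys[j]], [xs[i + 1], ys[j]],
                [xs[i + 1], ys[j + 1]], [xs[i], ys[j + 1]], [xs[i], ys[j]],
            ]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"value": float(pmap.values[j, i])},
                }
            )
    gj = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {
            "hour": str(pmap.hour),
            "pollutant": pmap.pollutant,
        },
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _spec_to_dict(spec) -> dict:
    d = {"technique": spec.technique}
    if spec.idp is not None:
        d["idp"] = spec.idp
    if spec.variogram is not None:
        d["variogram"] = {
            "model": spec.variogram.model,
            "nugget": spec.variogram.nugget,
            "partial_sill": spec.variogram.partial_sill,
            "range": spec.variogram.range,
        }
    if spec.beta is not None:
        d["beta"] = spec.beta
    if spec.secondary_pollutant is not None:
        d["secondary_pollutant"] = spec.secondary_pollutant
    return d


def write_map_metadata(pmap: PollutionMap, path) -> None:
    """Sidecar metadata (selected model + CV RMSE) as YAML or JSON by
    extension."""
    meta = {
        "hour": str(pmap.hour),
        "pollutant": pmap.pollutant,
        "cv_rmse": None if np.isnan(pmap.cv_rmse) else float(pmap.cv_rmse),
        "model": _spec_to_dict(pmap.model),
        "grid": {
            "n_lon": int(pmap.grid_lons.size),
            "n_lat": int(pmap.grid_lats.size),
            "lon_range": [float(pmap.grid_lons[0]), float(pmap.grid_lons[-1])],
            "lat_range": [float(pmap.grid_lats[0]), float(pmap.grid_lats[-1])],
        },
    }
    p = Path(path)
    if p.suffix in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(meta, sort_keys=False))
    else:
        p.write_text(json.dumps(meta, indent=2))
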