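"""Ranking candidate travel routes by predicted exposure.

A route is an ordered list of timestamped waypoints. Per leg, the
concentration is the mean of the interpolated map values at the two
endpoints (a trapezoid in space–time) and contributes concentration × leg
minutes to the route's SZ; exposure is SZ × VE of the travel activity.
Ranking a set of same-activity routes is therefore independent of the VE
value itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .exposure import VETable, compute_exposure, lookup_ve
from .geostat import PollutionMap, map_lookup, pairwise_distances

__all__ = [
    "RouteOption",
    "route_sz",
    "evaluate_routes",
    "rank_routes",
    "constant_speed_timestamps",
]


@dataclass
class RouteOption:
    """A candidate path: label, waypoints [(lat, lon, timestamp), ...]."""

    label: str
    waypoints: list[tuple[float, float, pd.Timestamp]]
    activity: str = "transport"
    total_sz: float = float("nan")
    total_exposure: float = float("nan")

    def __post_init__(self) -> None:
        self.waypoints = [
            (float(lat), float(lon), pd.Timestamp(ts))
            for lat, lon, ts in self.waypoints
        ]
        times = [ts for _, _, ts in self.waypoints]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"route {self.label!r}: waypoint timestamps must be nondecreasing"
            )


def _hour_floor(ts: pd.Timestamp) -> pd.Timestamp:
    return pd.Timestamp(ts).floor("h")


def _lookup_at(maps: dict[pd.Timestamp, PollutionMap], lat: float, lon: float,
               ts: pd.Timestamp) -> float:
    from .errors import CoverageError

    h = _hour_floor(ts)
    if h not in maps:
        raise CoverageError(f"no pollution map for hour {h}")
    return map_lookup(maps[h], lon, lat)


def route_sz(route: RouteOption, maps: dict[pd.Timestamp, PollutionMap]) -> float:
    """Time-integrated concentration along the route, μg/m³·min."""
    if len(route.waypoints) < 2:
        raise ValidationError("a route needs at least 2 waypoints")
    total = 0.0
    for (lat0, lon0, t0), (lat1, lon1, t1) in zip(
        route.waypoints, route.waypoints[1:]
    ):
        minutes = (t1 - t0).total_seconds() / 60.0
        if minutes == 0:
            continue
        c = 0.5 * (_lookup_at(maps, lat0, lon0, t0) + _lookup_at(maps, lat1, lon1, t1))
        total += c * minutes
    return total


def evaluate_routes(
    options: list[RouteOption],
    maps: dict[pd.Timestamp, PollutionMap],
    ve_table: VETable | None = None,
) -> list[RouteOption]:
    """Fill in total_sz and total_exposure for every option (in place)."""
    for opt in options:
        opt.total_sz = route_sz(opt, maps)
        opt.total_exposure = compute_exposure(
            opt.total_sz, lookup_ve(opt.activity, ve_table)
        )
    return options


def rank_routes(
    options: list[RouteOption],
    ve_table: VETable | None = None,
    baseline: str = "Actual",
) -> pd.DataFrame:
    """Rank evaluated routes ascending by exposure.

    ``pct_vs_baseline`` is (baseline − option)/baseline × 100: how much less
    a route exposes its user than the designated baseline (the route the
    person actually takes). Options with precomputed ``total_sz`` are used
    as-is; exposure is (re)derived from SZ and the VE table. Equal exposures
    keep input order (stable sort).
    """
    if not options:
        raise ConfigurationError("rank_routes needs at least one option")
    for opt in options:
        if not np.isfinite(opt.total_sz):
            raise ConfigurationError(
                f"route {opt.label!r} has no SZ; run evaluate_routes first"
            )
        opt.total_exposure = compute_exposure(
            opt.total_sz, lookup_ve(opt.activity, ve_table)
        )
    labels = [o.label for o in options]
    if baseline not in labels:
        raise ConfigurationError(f"baseline route {baseline!r} not among options")
    base = next(o for o in options if o.label == baseline).total_exposure
    ordered = sorted(options, key=lambda o: o.total_exposure)
    return pd.DataFrame(
        {
            "route": [o.label for o in ordered],
            "sz": [o.total_sz for o in ordered],
            "exposure": [o.total_exposure for o in ordered],
            "pct_vs_baseline": [
                (base - o.total_exposure) / base * 100.0 for o in ordered
            ],
        }
    )


def constant_speed_timestamps(
    latlons: list[tuple[float, float]],
    start: pd.Timestamp,
    end: pd.Timestamp,
    metric: str = "euclidean",
) -> list[tuple[float, float, pd.Timestamp]]:
    """Spread timestamps over waypoints proportionally to cumulative
    along-path distance (constant travel speed)."""
    if len(latlons) < 2:
        raise ValidationError("need at least 2 waypoints")
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    lats = np.array([p[0] for p in latlons])
    lons = np.array([p[1] for p in latlons])
    legs = np.array(
        [
            pairwise_distances(lons[i], lats[i], lons[i + 1], lats[i + 1], metric)[0, 0]
            for i in range(len(latlons) - 1)
        ]
    )
    cum = np.concatenate([[0.0], np.cumsum(legs)])
    frac = cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(latlons))
    span = end - start
    return [
        (float(lat), float(lon), (start + frac[i] * span).round("s"))
        for i, (lat, lon) in enumerate(latlons)
    ]
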