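"""Synthetic scenarios with known ground truth.

Emulates the five input streams of a case-study day in a Madrid-like bounding
box: (1) hourly readings of a smooth latent pollution field at ~24 fixed
stations, (2) a minute-cadence indoor monitor stream, (3) a beacon ping log
with dropout and guaranteed >10-min silences between occupancy windows,
(4) a daily activity trace templated on a real tracked day, and (5) candidate
routes. The latent field and the analytic indoor signal are returned alongside
the data so every pipeline stage can be checked against truth.

The outdoor field is a Gaussian random field realised by covariance-matrix
factorisation at the sampled sites (exact at these problem sizes), with AR(1)
correlation between consecutive hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .geostat import VariogramSpec, covariance, pairwise_distances
from .microenv import DEFAULT_GAP_MINUTES
from .mobility import ActivitySegment, load_trace

__all__ = [
    "FieldSpec",
    "IndoorSpec",
    "ScenarioSpec",
    "TruthField",
    "gen_outdoor",
    "gen_indoor",
    "indoor_integral",
    "gen_pings",
    "gen_trace",
    "MADRID_BBOX",
]

#: lon_min, lon_max, lat_min, lat_max — roughly the Madrid municipal area.
MADRID_BBOX = (-3.85, -3.55, 40.33, 40.55)


@dataclass(frozen=True)
class FieldSpec:
    """Latent outdoor field: PM2.5-like levels around 10 μg/m³ with smooth
    degree-scale spatial structure and hour-to-hour persistence."""

    mean: float = 10.0
    variance: float = 4.0
    corr_length: float = 0.08  # degrees
    model: str = "gaussian"
    nugget: float = 0.0
    temporal_rho: float = 0.8

    def variogram(self) -> VariogramSpec:
        return VariogramSpec(
            model=self.model,
            nugget=self.nugget,
            partial_sill=self.variance,
            range=self.corr_length,
        )


@dataclass(frozen=True)
class IndoorSpec:
    """Indoor PM2.5 signal: baseline plus one diurnal sinusoid plus noise."""

    base: float = 12.0
    amplitude: float = 5.0
    noise_sd: float = 1.0
    cadence_seconds: float = 300.0
    period_hours: float = 24.0


@dataclass(frozen=True)
class ScenarioSpec:
    seed: int = 0
    n_stations: int = 24
    hours: int = 24
    day: str = "2017-03-24"
    bbox: tuple[float, float, float, float] = MADRID_BBOX
    field: FieldSpec = dc_field(default_factory=FieldSpec)
    indoor: IndoorSpec = dc_field(default_factory=IndoorSpec)
    beacon_cadence_seconds: float = 60.0
    dropout: float = 0.1
    pollutant: str = "PM2.5"

    def __post_init__(self) -> None:
        if self.field.variance < 0 or self.indoor.noise_sd < 0:
            raise ConfigurationError("variances must be >= 0")
        if self.beacon_cadence_seconds <= 0 or self.indoor.cadence_seconds <= 0:
            raise ConfigurationError("cadences must be > 0")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")

    @property
    def day_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.day)


@dataclass
class TruthField:
    """Latent hourly field values at every simulated site."""

    lons: np.ndarray
    lats: np.ndarray
    hours: pd.DatetimeIndex
    values: np.ndarray  # (n_hours, n_points)

    def value_at(self, hour: pd.Timestamp, lon: float, lat: float) -> float:
        """Truth at a simulated site (nearest site within 1e-9°)."""
        hi = self.hours.get_loc(pd.Timestamp(hour))
        d = np.hypot(self.lons - lon, self.lats - lat)
        j = int(np.argmin(d))
        if d[j] > 1e-9:
            raise ValidationError(
                f"({lon}, {lat}) was not among the simulated truth sites"
            )
        return float(self.values[hi, j])


def gen_outdoor(
    spec: ScenarioSpec,
    extra_points: Sequence[tuple[float, float]] = (),
) -> tuple[pd.DataFrame, TruthField]:
    """Hourly station readings plus the latent truth.

    ``extra_points`` — (lon, lat) pairs (e.g. trace locations) — are included
    in the joint simulation so the truth is known exactly there too; they do
    not appear in the returned readings.
    """
    rng = np.random.default_rng(spec.seed)
    lon0, lon1, lat0, lat1 = spec.bbox
    st_lon = rng.uniform(lon0, lon1, spec.n_stations)
    st_lat = rng.uniform(lat0, lat1, spec.n_stations)
    ex = np.asarray(list(extra_points), dtype=float).reshape(-1, 2)
    all_lon = np.concatenate([st_lon, ex[:, 0]])
    all_lat = np.concatenate([st_lat, ex[:, 1]])
    n = all_lon.size

    hours = pd.date_range(spec.day_start, periods=spec.hours, freq="h")
    if spec.field.variance == 0:
        z = np.zeros((spec.hours, n))
    else:
        vg = spec.field.variogram()
        cov = covariance(vg, pairwise_distances(all_lon, all_lat, all_lon, all_lat))
        cov += 1e-9 * np.eye(n)
        chol = np.linalg.cholesky(cov)
        rho = spec.field.temporal_rho
        z = np.empty((spec.hours, n))
        z[0] = chol @ rng.standard_normal(n)
        for h in range(1, spec.hours):
            z[h] = rho * z[h - 1] + np.sqrt(1 - rho**2) * (
                chol @ rng.standard_normal(n)
            )
    values = np.maximum(spec.field.mean + z, 0.0)
    truth = TruthField(lons=all_lon, lats=all_lat, hours=hours, values=values)

    rows = []
    for hi, hour in enumerate(hours):
        for si in range(spec.n_stations):
            rows.append(
                (
                    f"S{si:02d}",
                    st_lon[si],
                    st_lat[si],
                    hour,
                    spec.pollutant,
                    values[hi, si],
                )
            )
    readings = pd.DataFrame(
        rows, columns=["station_id", "lon", "lat", "hour", "pollutant", "value"]
    )
    return readings, truth


def _omega(spec: IndoorSpec) -> float:
    """Angular frequency in rad/minute."""
    return 2 * np.pi / (spec.period_hours * 60.0)


def gen_indoor(spec: ScenarioSpec) -> pd.DataFrame:
    """Wide-form monitor stream over the scenario day: ts, PM2.5, CO2, VOC.

    PM2.5 follows the analytic sinusoid (+noise, clipped at 0); CO2 and VOC
    are scaled companions so multi-pollutant plumbing can be exercised.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ind = spec.indoor
    ts = pd.date_range(
        spec.day_start,
        spec.day_start + pd.Timedelta(hours=spec.hours),
        freq=pd.Timedelta(seconds=ind.cadence_seconds),
        inclusive="left",
    )
    minutes = (ts - spec.day_start).total_seconds() / 60.0
    clean = ind.base + ind.amplitude * np.sin(_omega(ind) * np.asarray(minutes))
    noise = rng.normal(0, ind.noise_sd, len(ts)) if ind.noise_sd > 0 else 0.0
    pm = np.maximum(clean + noise, 0.0)
    return pd.DataFrame(
        {
            "ts": ts,
            "PM2.5": pm,
            "CO2": 400.0 + 20.0 * (pm - ind.base),
            "VOC": 120.0 + 5.0 * (pm - ind.base),
        }
    )


def indoor_integral(spec: IndoorSpec, day_start: pd.Timestamp,
                    t0: pd.Timestamp, t1: pd.Timestamp) -> float:
    """Closed-form ∫ Z dt (in unit·minutes) of the noise-free indoor signal."""
    w = _omega(spec)
    m0 = (pd.Timestamp(t0) - day_start).total_seconds() / 60.0
    m1 = (pd.Timestamp(t1) - day_start).total_seconds() / 60.0
    return spec.base * (m1 - m0) - spec.amplitude / w * (
        np.cos(w * m1) - np.cos(w * m0)
    )


def gen_pings(
    spec: ScenarioSpec,
    occupancy_windows: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    beacon_id: str = "B1",
    gap_threshold_minutes: float = DEFAULT_GAP_MINUTES,
) -> pd.DataFrame:
    """Beacon ping log: cadence pings inside each occupancy window with i.i.d.
    dropout of interior pings (first and last ping of each window are kept so
    window edges survive any dropout level).

    Windows must be non-overlapping and separated by more than the gap
    threshold, so each window maps to exactly one indoor period.
    """
    windows = sorted(
        (pd.Timestamp(a), pd.Timestamp(b)) for a, b in occupancy_windows
    )
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ConfigurationError("occupancy windows overlap")
        if (b0 - a1).total_seconds() / 60.0 <= gap_threshold_minutes:
            raise ConfigurationError(
                "occupancy windows must be separated by more than the gap "
                f"threshold ({gap_threshold_minutes} min)"
            )
    rng = np.random.default_rng(spec.seed + 2)
    out = []
    for a, b in windows:
        ts = pd.date_range(a, b, freq=pd.Timedelta(seconds=spec.beacon_cadence_seconds))
        ts = ts.union(pd.DatetimeIndex([a, b]))
        keep = np.ones(len(ts), dtype=bool)
        if spec.dropout > 0 and len(ts) > 2:
            keep[1:-1] = rng.random(len(ts) - 2) >= spec.dropout
        out.extend(ts[keep])
    return pd.DataFrame({"beacon_id": beacon_id, "ts": pd.DatetimeIndex(out)})


def gen_trace(
    spec: ScenarioSpec, template: pd.DataFrame | None = None
) -> list[ActivitySegment]:
    """Activity trace from a template table (defaults to the packaged
    case-study day), validated through the standard loader."""
    if template is None:
        from .fixtures import load_table4_trace

        template = load_table4_trace()
    return load_trace(template)
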