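"""Indoor presence and dose aggregation.

A BLE beacon placed next to the indoor air monitor broadcasts pings that a
phone logs whenever its carrier is nearby. Runs of pings whose inter-ping gaps
never exceed a threshold (10 minutes by default) delimit *indoor periods*;
a strictly longer silence means the person left and a new period starts later.

Each ping is matched to the nearest-in-time monitor reading, and the matched
samples are integrated over the period with the trapezoidal rule to give the
time-integrated intensity

    SZ(p) = Σ ½ (Z_{i+1} + Z_i) (t_{i+1} − t_i)      [μg/m³·min]

which, multiplied by minute ventilation, yields inhaled mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoDataError, ValidationError

__all__ = [
    "DEFAULT_GAP_MINUTES",
    "IndoorPeriod",
    "segment_periods",
    "match_nearest",
    "aggregate_sz",
    "build_indoor_periods",
]

DEFAULT_GAP_MINUTES = 10.0

#: Species the indoor monitor reports (units: μg/m³, ppm, ppb respectively).
INDOOR_POLLUTANTS = ("PM2.5", "CO2", "VOC")


@dataclass
class IndoorPeriod:
    """A maximal run of beacon pings and its aggregated intensity.

    ``samples`` holds the de-duplicated matched monitor readings (one row per
    distinct monitor timestamp, columns ``ts`` plus one per pollutant);
    ``sz`` maps pollutant name to SZ(p) in the pollutant's unit × minutes.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    samples: pd.DataFrame = field(repr=False, default=None)
    sz: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("indoor period start after end")

    def sz_between(self, t0: pd.Timestamp, t1: pd.Timestamp,
                   pollutant: str = "PM2.5") -> float:
        """SZ over the sub-window [t0, t1] of this period.

        The signal is linearly interpolated at the cut points, so splitting a
        period at any instant and summing the pieces reproduces the total.
        """
        if self.samples is None or len(self.samples) == 0:
            return 0.0
        t = _minutes(self.samples["ts"])
        z = np.asarray(self.samples[pollutant], dtype=float)
        ref = self.samples["ts"].iloc[0]
        lo = max((t0 - ref).total_seconds() / 60.0, t[0])
        hi = min((t1 - ref).total_seconds() / 60.0, t[-1])
        if hi <= lo:
            return 0.0
        grid = np.unique(np.concatenate([[lo], t[(t > lo) & (t < hi)], [hi]]))
        return float(np.trapezoid(np.interp(grid, t, z), grid))


def _minutes(ts: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(ts)
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 60.0


def segment_periods(
    pings: pd.DataFrame | pd.Series,
    gap_threshold_minutes: float = DEFAULT_GAP_MINUTES,
) -> list[pd.Series]:
    """Split a ping log into maximal runs with inter-ping gaps ≤ threshold.

    The boundary is strict: a gap of exactly the threshold stays in one
    period; one second longer starts a new one. Returns a list of sorted
    timestamp Series (a single ping makes a zero-length period).
    """
    if isinstance(pings, pd.DataFrame):
        ts = pd.to_datetime(pings["ts"])
    else:
        ts = pd.to_datetime(pings)
    ts = ts.sort_values().reset_index(drop=True)
    if len(ts) == 0:
        return []
    gaps = ts.diff().dt.total_seconds().fillna(0.0) / 60.0
    run_id = (gaps > gap_threshold_minutes).cumsum()
    return [grp.reset_index(drop=True) for _, grp in ts.groupby(run_id)]


def match_nearest(ts: pd.Timestamp, stream: pd.DataFrame) -> pd.Series:
    """The monitor reading whose timestamp is closest to ``ts``.

    Ties (``ts`` exactly midway) break toward the earlier reading. The stream
    must be sorted by ``ts``.
    """
    if stream is None or len(stream) == 0:
        raise NoDataError("monitor stream is empty")
    times = pd.to_datetime(stream["ts"]).to_numpy()
    t = np.datetime64(pd.Timestamp(ts))
    i = int(np.searchsorted(times, t))
    if i == 0:
        return stream.iloc[0]
    if i == len(times):
        return stream.iloc[-1]
    before, after = times[i - 1], times[i]
    if (t - before) <= (after - t):
        return stream.iloc[i - 1]
    return stream.iloc[i]


def aggregate_sz(times, values) -> float:
    """Trapezoidal SZ of an ordered (t, Z) sequence; Δt in minutes.

    Exact for piecewise-linear signals; a single sample integrates to 0.
    """
    t = pd.to_datetime(pd.Series(times))
    z = np.asarray(values, dtype=float)
    if len(t) != len(z):
        raise ValidationError("times and values differ in length")
    if len(t) == 0:
        raise ValidationError("aggregate_sz needs at least one sample")
    minutes = (t - t.iloc[0]).dt.total_seconds().to_numpy() / 60.0
    if np.any(np.diff(minutes) < 0):
        raise ValidationError("samples must be sorted by time")
    if len(t) == 1:
        return 0.0
    return float(np.trapezoid(z, minutes))


def build_indoor_periods(
    pings: pd.DataFrame,
    stream: pd.DataFrame,
    gap_threshold_minutes: float = DEFAULT_GAP_MINUTES,
    pollutants: tuple[str, ...] | None = None,
) -> list[IndoorPeriod]:
    """Full indoor chain: segment pings, match each to its nearest monitor
    reading, collapse duplicate matches, and integrate SZ per pollutant.

    ``stream`` is wide-form: a ``ts`` column plus one column per pollutant.
    """
    if stream is None or len(stream) == 0:
        raise NoDataError("monitor stream is empty; cannot aggregate indoor periods")
    stream = stream.sort_values("ts").reset_index(drop=True)
    if pollutants is None:
        pollutants = tuple(c for c in stream.columns if c != "ts")
    periods: list[IndoorPeriod] = []
    for run in segment_periods(pings, gap_threshold_minutes):
        matched = pd.concat(
            [match_nearest(t, stream).to_frame().T for t in run], ignore_index=True
        )
        matched["ts"] = pd.to_datetime(matched["ts"])
        samples = (
            matched.drop_duplicates(subset="ts")
            .sort_values("ts")
            .reset_index(drop=True)
        )
        for p in pollutants:
            samples[p] = pd.to_numeric(samples[p])
        sz = {
            p: aggregate_sz(samples["ts"], samples[p]) if len(samples) > 1 else 0.0
            for p in pollutants
        }
        periods.append(
            IndoorPeriod(
                start=run.iloc[0], end=run.iloc[-1], samples=samples, sz=sz
            )
        )
    return periods
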