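"""Activity/location traces from a phone tracking app.

Each row gives a time interval, a representative coordinate and an activity
label (rest, walk, run, cycle, transport). Tracked data rarely tiles a whole
day; untracked intervals are assumed to be "rest" at the location where the
person was last seen, so that after gap filling the trace partitions the day
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .errors import ValidationError

__all__ = ["ACTIVITIES", "ActivitySegment", "load_trace", "fill_rest_gaps",
           "segments_to_frame"]

ACTIVITIES = ("rest", "walk", "run", "cycle", "transport")


@dataclass(frozen=True)
class ActivitySegment:
    start: pd.Timestamp
    end: pd.Timestamp
    lat: float
    lon: float
    activity: str
    provenance: str = "tracked"  # or "gap_filled"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment start {self.start} not before end {self.end}"
            )
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def load_trace(rows: pd.DataFrame) -> list[ActivitySegment]:
    """Validate and sort a raw trace table into segments.

    Expects columns ``start``, ``end``, ``lat``, ``lon``, ``activity``
    (activity labels are case-insensitive). Zero-duration rows are dropped
    with a warning; overlapping rows, out-of-range coordinates and unknown
    activities raise :class:`ValidationError` naming the offending rows.
    """
    if rows is None or len(rows) == 0:
        return []
    df = rows.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    segments: list[ActivitySegment] = []
    for idx, row in df.iterrows():
        lat, lon = float(row["lat"]), float(row["lon"])
        if not -90 <= lat <= 90 or not -180 <= lon <= 180:
            raise ValidationError(f"row {idx}: coordinates ({lat}, {lon}) out of range")
        activity = str(row["activity"]).strip().lower()
        if activity not in ACTIVITIES:
            raise ValidationError(f"row {idx}: unknown activity {row['activity']!r}")
        if row["start"] == row["end"]:
            warnings.warn(f"row {idx}: zero-duration segment dropped")
            continue
        if row["start"] > row["end"]:
            raise ValidationError(f"row {idx}: start after end")
        segments.append(
            ActivitySegment(
                start=row["start"], end=row["end"], lat=lat, lon=lon,
                activity=activity,
            )
        )
    segments.sort(key=lambda s: (s.start, s.end))
    for a, b in zip(segments, segments[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"overlapping segments: [{a.start} – {a.end}] and "
                f"[{b.start} – {b.end}]"
            )
    return segments


def fill_rest_gaps(
    segments: list[ActivitySegment],
    day_bounds: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> list[ActivitySegment]:
    """Tile the day: every untracked interval becomes a "rest" segment.

    Gap segments take the coordinates of the preceding segment (a leading gap
    takes the following segment's). Day bounds default to midnight-to-midnight
    of the first segment's calendar day. Idempotent.
    """
    if day_bounds is None:
        if not segments:
            raise ValidationError("empty trace needs explicit day bounds")
        d0 = segments[0].start.normalize()
        day_bounds = (d0, d0 + pd.Timedelta(days=1))
    lo, hi = pd.Timestamp(day_bounds[0]), pd.Timestamp(day_bounds[1])
    if not segments:
        return [
            ActivitySegment(lo, hi, lat=float("nan"), lon=float("nan"),
                            activity="rest", provenance="gap_filled")
        ]

    def gap(a: pd.Timestamp, b: pd.Timestamp, ref: ActivitySegment) -> ActivitySegment:
        return ActivitySegment(a, b, lat=ref.lat, lon=ref.lon,
                               activity="rest", provenance="gap_filled")

    out: list[ActivitySegment] = []
    if segments[0].start > lo:
        out.append(gap(lo, segments[0].start, segments[0]))
    for a, b in zip(segments, segments[1:]):
        out.append(a)
        if b.start > a.end:
            out.append(gap(a.end, b.start, a))
    out.append(segments[-1])
    if segments[-1].end < hi:
        out.append(gap(segments[-1].end, hi, segments[-1]))
    return out


def segments_to_frame(segments: list[ActivitySegment]) -> pd.DataFrame:
    """Tabular view of a segment list (column order mirrors the tracking-app
    export)."""
    return pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "lat": [s.lat for s in segments],
            "lon": [s.lon for s in segments],
            "activity": [s.activity for s in segments],
            "provenance": [s.provenance for s in segments],
        }
    )
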