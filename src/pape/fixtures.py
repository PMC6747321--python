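"""Packaged case-study fixtures.

Small CSV tables from the Madrid case-study day (2017-03-24): the available
pollutants per device, the tracked activity trace, the integrated exposure
timeline, the route-comparison totals, and the worked beacon-gap example
(pings through 14:44:59, then silence until 14:59:00). A SHA-256 manifest
guards against accidental edits.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "fixture_path",
    "load_table1_pollutants",
    "load_table4_trace",
    "load_table5_exposure",
    "load_table6_routes",
    "load_beacon_example",
    "verify_manifest",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(resources.files(__package__) / "fixtures" / name)


def load_table1_pollutants() -> pd.DataFrame:
    """Pollutants and units available per data source."""
    return pd.read_csv(fixture_path("table1_pollutants.csv"))


def load_table4_trace() -> pd.DataFrame:
    """The tracked day's activity trace in loader-ready column names."""
    from .io import read_trace_csv

    return read_trace_csv(fixture_path("table4_trace.csv"))


def load_table5_exposure() -> pd.DataFrame:
    """The integrated indoor/outdoor exposure timeline (verbatim values)."""
    from .io import read_exposure_csv

    return read_exposure_csv(fixture_path("table5_exposure.csv"))


def load_table6_routes() -> pd.DataFrame:
    """Per-route SZ and exposure totals for the route-comparison example."""
    return pd.read_csv(fixture_path("table6_routes.csv"))


def load_beacon_example() -> pd.DataFrame:
    """The worked ping log whose >10-min silence splits two indoor periods."""
    from .io import read_pings_csv

    return read_pings_csv(fixture_path("beacon_gap_example.csv"))


def verify_manifest() -> None:
    """Raise if any packaged fixture's SHA-256 differs from the manifest."""
    manifest = json.loads(fixture_path("manifest.json").read_text())
    for name, digest in manifest.items():
        actual = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        if actual != digest:
            raise ValidationError(f"fixture {name} checksum mismatch")
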