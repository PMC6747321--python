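import numpy as np
import pandas as pd
import pytest

from pape.geostat import InterpolatorSpec, PollutionMap, VariogramSpec


def make_stations(seed: int = 0, n: int = 24, values=None) -> pd.DataFrame:
    """Random station layout in a Madrid-like box with uniform values unless
    given."""
    rng = np.random.default_rng(seed)
    if values is None:
        values = rng.uniform(5, 15, n)
    return pd.DataFrame(
        {
            "station_id": [f"S{i:02d}" for i in range(n)],
            "lon": rng.uniform(-3.85, -3.55, n),
            "lat": rng.uniform(40.33, 40.55, n),
            "hour": pd.Timestamp("2017-03-24 10:00"),
            "pollutant": "PM2.5",
            "value": np.asarray(values, dtype=float),
        }
    )


def smooth_field_stations(seed: int = 0, n: int = 25,
                          corr_length: float = 0.1) -> pd.DataFrame:
    """Stations sampling one draw of a gaussian-covariance random field."""
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-3.85, -3.55, n)
    lat = rng.uniform(40.33, 40.55, n)
    d = np.hypot(lon[:, None] - lon[None, :], lat[:, None] - lat[None, :])
    cov = 4.0 * np.exp(-(d**2) / corr_length**2) + 1e-9 * np.eye(n)
    values = 10.0 + np.linalg.cholesky(cov) @ rng.standard_normal(n)
    df = make_stations(seed, n)
    df["value"] = values
    return df


def constant_map(value: float, hour="2017-03-24 10:00") -> PollutionMap:
    return PollutionMap(
        hour=pd.Timestamp(hour),
        pollutant="PM2.5",
        grid_lons=np.linspace(-3.85, -3.55, 20),
        grid_lats=np.linspace(40.33, 40.55, 20),
        values=np.full((20, 20), float(value)),
        model=InterpolatorSpec("IDW", idp=2.0),
    )


def hourly_constant_maps(day="2017-03-24", values=10.0) -> dict:
    """24 flat hourly maps; ``values`` may be a scalar or a 24-vector."""
    vals = np.broadcast_to(np.asarray(values, dtype=float), (24,))
    return {
        pd.Timestamp(day) + pd.Timedelta(hours=h): constant_map(vals[h])
        for h in range(24)
    }


@pytest.fixture
def gauss_variogram():
    return VariogramSpec("gaussian", nugget=1e-5, partial_sill=1.0, range=0.1)


@pytest.fixture
def table4_trace():
    from pape.fixtures import load_table4_trace

    return load_table4_trace()
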