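"""Geostatistical interpolation of fixed-site outdoor monitor readings.

Builds hourly pollution surfaces from a sparse network of stations (the Madrid
open-data network has 24) using inverse-distance weighting, simple kriging,
ordinary kriging or collocated co-kriging, with model and parameters chosen by
k-fold cross-validated grid search on RMSE.

Concentrations are in μg/m³ throughout; coordinates are WGS84 degrees and the
default distance metric is planar Euclidean distance on raw degrees (the study
area spans < 0.3°, and the range grid 0.1–80 is degree-scaled), switchable to
haversine kilometres.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    IllConditionedError,
    InsufficientDataError,
)

__all__ = [
    "VariogramSpec",
    "InterpolatorSpec",
    "PollutionMap",
    "semivariance",
    "empirical_variogram",
    "idw_predict",
    "kriging_predict",
    "cokriging_predict",
    "cv_select_model",
    "build_pollution_map",
    "map_lookup",
    "DEFAULT_GRIDS",
]

#: Outdoor pollutants carried by the hourly open-data feed.
OUTDOOR_POLLUTANTS = ("PM2.5", "PM10", "CO", "NO2", "SO2", "O3", "NOx")

VARIOGRAM_MODELS = ("circular", "spherical", "exponential", "gaussian")
TECHNIQUES = ("IDW", "simple_kriging", "ordinary_kriging", "cokriging")

#: Added to the kriging matrix diagonal before factorization; the nugget grid
#: reaches 1e-5, so near-singular systems do occur.
_DIAG_REG = 1e-10

#: A target closer than this (in the active distance unit) to a station is
#: treated as coincident with it.
COINCIDENCE_TOL = 1e-9

#: Default cross-validation grids: IDW power, variogram sill/range/nugget,
#: the β grid (co-kriging weight; doubles as the simple-kriging known mean),
#: and the variogram model family.
DEFAULT_GRIDS: dict[str, tuple] = {
    "idp": (0.1, 0.3, 0.5, 0.8, 2, 5),
    "sill": (1, 10, 100, 250, 500, 600, 700, 800, 900),
    "range": (0.1, 0.5, 1, 10, 20, 50, 80),
    "nugget": (0.00001, 0.0001, 0.001, 0.01, 0.1, 1, 10, 100, 200, 50),
    "beta": (0.05, 0.12, 0.2, 0.5, 0.9, 1.5, 3, 1),
    "variogram_model": ("gaussian", "circular", "exponential"),
}

DEFAULT_CV_SEED = 20170324


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class VariogramSpec:
    """An isotropic variogram: nugget c0, partial sill c and range α (also
    written r for the exponential/gaussian families)."""

    model: str
    nugget: float = 0.0
    partial_sill: float = 1.0
    range: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in VARIOGRAM_MODELS:
            raise ConfigurationError(
                f"unknown variogram model {self.model!r}; "
                f"expected one of {VARIOGRAM_MODELS}"
            )
        if self.nugget < 0 or self.partial_sill < 0:
            raise ConfigurationError("nugget and partial sill must be >= 0")
        if self.range <= 0:
            raise ConfigurationError("range must be > 0")

    @property
    def sill(self) -> float:
        """Total sill c0 + c, the plateau variance."""
        return self.nugget + self.partial_sill


@dataclass(frozen=True)
class InterpolatorSpec:
    """A fully parameterised interpolation technique.

    Exactly the parameters relevant to ``technique`` are meaningful: ``idp``
    for IDW; ``variogram`` for the kriging family; ``beta`` is the known mean
    for simple kriging and the collocated-secondary weight (in [0, 1] per its
    definition) for co-kriging; ``secondary_pollutant`` only for co-kriging.
    """

    technique: str
    idp: float | None = None
    variogram: VariogramSpec | None = None
    beta: float | None = None
    secondary_pollutant: str | None = None

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ConfigurationError(
                f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}"
            )
        if self.technique == "IDW":
            if self.idp is None or self.idp <= 0:
                raise ConfigurationError("IDW requires a positive idp")
        else:
            if self.variogram is None:
                raise ConfigurationError(f"{self.technique} requires a variogram")
        if self.technique == "cokriging" and self.beta is not None:
            if not 0 <= self.beta <= 1:
                raise ConfigurationError("co-kriging beta must lie in [0, 1]")


@dataclass
class PollutionMap:
    """One hourly interpolated surface with the model that produced it.

    ``values`` is indexed ``[i_lat, i_lon]`` over the ordered axes
    ``grid_lats`` × ``grid_lons``.
    """

    hour: pd.Timestamp
    pollutant: str
    grid_lons: np.ndarray
    grid_lats: np.ndarray
    values: np.ndarray
    model: InterpolatorSpec
    cv_rmse: float = float("nan")

    def __post_init__(self) -> None:
        self.grid_lons = np.asarray(self.grid_lons, dtype=float)
        self.grid_lats = np.asarray(self.grid_lats, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid_lats.size, self.grid_lons.size)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pollution map contains non-finite values")


# ---------------------------------------------------------------------------
# distances


def pairwise_distances(
    lon_a: np.ndarray,
    lat_a: np.ndarray,
    lon_b: np.ndarray,
    lat_b: np.ndarray,
    metric: str = "euclidean",
) -> np.ndarray:
    """Distance matrix between point sets A (rows) and B (columns).

    ``euclidean`` works on raw degrees; ``haversine_km`` returns great-circle
    kilometres.
    """
    lon_a = np.atleast_1d(np.asarray(lon_a, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat_a, dtype=float))
    lon_b = np.atleast_1d(np.asarray(lon_b, dtype=float))
    lat_b = np.atleast_1d(np.asarray(lat_b, dtype=float))
    if metric == "euclidean":
        dlon = lon_a[:, None] - lon_b[None, :]
        dlat = lat_a[:, None] - lat_b[None, :]
        return np.hypot(dlon, dlat)
    if metric == "haversine_km":
        r = 6371.0088
        pa, pb = np.radians(lat_a), np.radians(lat_b)
        dphi = pa[:, None] - pb[None, :]
        dlam = np.radians(lon_a)[:, None] - np.radians(lon_b)[None, :]
        h = (
            np.sin(dphi / 2) ** 2
            + np.cos(pa)[:, None] * np.cos(pb)[None, :] * np.sin(dlam / 2) ** 2
        )
        return 2 * r * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    raise ConfigurationError(f"unknown distance metric {metric!r}")


# ---------------------------------------------------------------------------
# variograms


def semivariance(spec: VariogramSpec, d) -> np.ndarray | float:
    """Evaluate the variogram γ(d).

    All four families satisfy γ(0) = 0 (the nugget appears only for d > 0) and
    the circular/spherical families plateau at c0 + c beyond the range.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be nonnegative")
    c0, c, a = spec.nugget, spec.partial_sill, spec.range
    out = np.zeros_like(d_arr)
    pos = d_arr > 0
    dp = d_arr[pos]
    if spec.model == "circular":
        x = np.clip(dp / a, 0.0, 1.0)
        inside = c0 + c * (2 / np.pi) * (np.arcsin(x) + x * np.sqrt(1 - x**2))
        out[pos] = np.where(dp <= a, inside, c0 + c)
    elif spec.model == "spherical":
        x = np.clip(dp / a, 0.0, 1.0)
        inside = c0 + c * (1.5 * x - 0.5 * x**3)
        out[pos] = np.where(dp <= a, inside, c0 + c)
    elif spec.model == "exponential":
        out[pos] = c0 + c * (1 - np.exp(-dp / a))
    else:  # gaussian
        out[pos] = c0 + c * (1 - np.exp(-(dp**2) / a**2))
    if np.isscalar(d):
        return float(out)
    return out


def covariance(spec: VariogramSpec, d) -> np.ndarray | float:
    """Stationary covariance C(d) = (c0 + c) − γ(d); C(0) = c0 + c."""
    return spec.sill - semivariance(spec, d)


def empirical_variogram(
    readings: pd.DataFrame,
    n_bins: int = 12,
    max_dist: float | None = None,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Classical (Matheron) empirical variogram of one hour's readings.

    For each distance bin, ½ · mean (X_i − X_j)² over the station pairs whose
    separation falls in the bin; empty bins are dropped.

    Returns a frame with columns ``distance`` (bin centre), ``semivariance``
    and ``n_pairs``.
    """
    lon, lat, val = _station_arrays(readings)
    if lon.size < 2:
        raise InsufficientDataError("empirical variogram needs >= 2 stations")
    dmat = pairwise_distances(lon, lat, lon, lat, metric)
    iu = np.triu_indices(lon.size, k=1)
    d = dmat[iu]
    sq = 0.5 * (val[iu[0]] - val[iu[1]]) ** 2
    if max_dist is None:
        max_dist = float(d.max())
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    keep = d <= max_dist
    rows = []
    for b in range(n_bins):
        sel = keep & (idx == b)
        if not sel.any():
            continue
        rows.append(
            (0.5 * (edges[b] + edges[b + 1]), float(sq[sel].mean()), int(sel.sum()))
        )
    return pd.DataFrame(rows, columns=["distance", "semivariance", "n_pairs"])


# ---------------------------------------------------------------------------
# interpolators


def _station_arrays(readings: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lon = np.asarray(readings["lon"], dtype=float)
    lat = np.asarray(readings["lat"], dtype=float)
    val = np.asarray(readings["value"], dtype=float)
    return lon, lat, val


def _dedupe_stations(
    lon: np.ndarray, lat: np.ndarray, *value_sets: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Average readings at duplicated coordinates (warns once)."""
    coords = np.round(np.column_stack([lon, lat]) / COINCIDENCE_TOL).astype(np.int64)
    _, inv, counts = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if counts.max() == 1:
        return (lon, lat, *value_sets)
    warnings.warn(
        "duplicate station coordinates: averaging colocated readings",
        stacklevel=3,
    )
    n = counts.size
    out_lon = np.bincount(inv, weights=lon, minlength=n) / counts
    out_lat = np.bincount(inv, weights=lat, minlength=n) / counts
    outs = tuple(
        np.bincount(inv, weights=v, minlength=n) / counts for v in value_sets
    )
    return (out_lon, out_lat, *outs)


def idw_predict(
    readings: pd.DataFrame,
    target_lon,
    target_lat,
    idp: float,
    metric: str = "euclidean",
) -> np.ndarray | float:
    """Inverse-distance-weighted prediction ẑ0 = Σ λi·Xi, λi ∝ d_i^(−idp).

    A target within :data:`COINCIDENCE_TOL` of a station returns that
    station's value. Predictions are convex combinations of the data, hence
    bounded by min/max of the readings.
    """
    if idp <= 0:
        raise ConfigurationError("IDW power must be > 0")
    lon, lat, val = _station_arrays(readings)
    if lon.size == 0:
        raise InsufficientDataError("IDW needs at least one reading")
    scalar = np.isscalar(target_lon)
    d = pairwise_distances(target_lon, target_lat, lon, lat, metric)
    with np.errstate(divide="ignore", over="ignore"):
        w = d ** (-idp)
    coincident = d < COINCIDENCE_TOL
    hit = coincident.any(axis=1)
    w[hit] = coincident[hit].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    pred = w @ val
    return float(pred[0]) if scalar else pred


def _kriging_weights(
    spec: VariogramSpec,
    lon: np.ndarray,
    lat: np.ndarray,
    tlon: np.ndarray,
    tlat: np.ndarray,
    ordinary: bool,
    metric: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the kriging system in covariance form.

    Returns (weights [n_stations × n_targets], cov vectors, lagrange row —
    zeros for simple kriging).
    """
    n = lon.size
    d_ss = pairwise_distances(lon, lat, lon, lat, metric)
    d_st = pairwise_distances(lon, lat, tlon, tlat, metric)
    big_c = covariance(spec, d_ss) + _DIAG_REG * np.eye(n)
    c_vec = covariance(spec, d_st)
    try:
        if ordinary:
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = big_c
            aug[n, :n] = 1.0
            aug[:n, n] = 1.0
            rhs = np.vstack([c_vec, np.ones((1, c_vec.shape[1]))])
            sol = np.linalg.solve(aug, rhs)
            return sol[:n], c_vec, sol[n]
        sol = np.linalg.solve(big_c, c_vec)
        return sol, c_vec, np.zeros(c_vec.shape[1])
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError(
            f"kriging system singular after {_DIAG_REG} diagonal regularization"
        ) from exc


def kriging_predict(
    readings: pd.DataFrame,
    target_lon,
    target_lat,
    spec: InterpolatorSpec,
    metric: str = "euclidean",
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Simple or ordinary kriging prediction with its kriging variance.

    Simple kriging assumes a known constant mean — ``spec.beta`` when given,
    else the sample mean of the hour's readings; ordinary kriging estimates
    the mean implicitly through the Σλ=1 constraint (Lagrange multiplier).
    Both are exact interpolators: a target at a station reproduces the
    station value with zero variance.
    """
    if spec.technique not in ("simple_kriging", "ordinary_kriging"):
        raise ConfigurationError(f"not a kriging technique: {spec.technique}")
    vspec = spec.variogram
    lon, lat, val = _station_arrays(readings)
    if lon.size < 2:
        raise InsufficientDataError("kriging needs >= 2 readings")
    lon, lat, val = _dedupe_stations(lon, lat, val)
    scalar = np.isscalar(target_lon)
    tlon = np.atleast_1d(np.asarray(target_lon, dtype=float))
    tlat = np.atleast_1d(np.asarray(target_lat, dtype=float))
    ordinary = spec.technique == "ordinary_kriging"
    lam, c_vec, mu = _kriging_weights(vspec, lon, lat, tlon, tlat, ordinary, metric)
    if ordinary:
        pred = lam.T @ val
        var = vspec.sill - np.einsum("ij,ij->j", lam, c_vec) - mu
    else:
        mean = spec.beta if spec.beta is not None else float(val.mean())
        pred = mean + lam.T @ (val - mean)
        var = vspec.sill - np.einsum("ij,ij->j", lam, c_vec)
    var = np.maximum(var, 0.0)
    # exact-hit override guards against regularization-induced drift
    d_st = pairwise_distances(lon, lat, tlon, tlat, metric)
    j, t = np.nonzero(d_st < COINCIDENCE_TOL)
    pred[t] = val[j]
    var[t] = 0.0
    if scalar:
        return float(pred[0]), float(var[0])
    return pred, var


def cokriging_predict(
    readings: pd.DataFrame,
    secondary_readings: pd.DataFrame,
    target_lon,
    target_lat,
    spec: InterpolatorSpec,
    metric: str = "euclidean",
) -> np.ndarray | float:
    """Collocated co-kriging: ordinary kriging of the primary pollutant plus
    β times the mean-centred secondary variable at the target.

    The secondary pollutant is only measured at the stations, so its value at
    the target is itself ordinary-kriged (same variogram) before centring.
    With β = 0, or with a constant secondary field, this reduces exactly to
    ordinary kriging. Missing secondary data falls back to ordinary kriging
    with a warning.
    """
    ok_spec = replace(spec, technique="ordinary_kriging", beta=None,
                      secondary_pollutant=None)
    if secondary_readings is None or len(secondary_readings) == 0:
        warnings.warn("no secondary readings: falling back to ordinary kriging")
        pred, _ = kriging_predict(readings, target_lon, target_lat, ok_spec, metric)
        return pred
    beta = spec.beta if spec.beta is not None else 0.0
    merged = readings.merge(
        secondary_readings[["station_id", "value"]].rename(
            columns={"value": "secondary"}
        ),
        on="station_id",
        how="inner",
    )
    if len(merged) < 2:
        warnings.warn(
            "secondary readings not collocated with primary stations: "
            "falling back to ordinary kriging"
        )
        pred, _ = kriging_predict(readings, target_lon, target_lat, ok_spec, metric)
        return pred
    lon = np.asarray(merged["lon"], dtype=float)
    lat = np.asarray(merged["lat"], dtype=float)
    val = np.asarray(merged["value"], dtype=float)
    sec = np.asarray(merged["secondary"], dtype=float)
    lon, lat, val, sec = _dedupe_stations(lon, lat, val, sec)
    scalar = np.isscalar(target_lon)
    tlon = np.atleast_1d(np.asarray(target_lon, dtype=float))
    tlat = np.atleast_1d(np.asarray(target_lat, dtype=float))
    lam, _, _ = _kriging_weights(
        spec.variogram, lon, lat, tlon, tlat, True, metric
    )
    pred = lam.T @ val + beta * (lam.T @ sec - sec.mean())
    d_st = pairwise_distances(lon, lat, tlon, tlat, metric)
    j, t = np.nonzero(d_st < COINCIDENCE_TOL)
    pred[t] = val[j] + beta * (sec[j] - sec.mean())
    return float(pred[0]) if scalar else pred


# ---------------------------------------------------------------------------
# cross-validated model selection


def _make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Fold label per station: a seeded uniform permutation cut into k
    near-equal blocks."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, s in enumerate(sizes):
        labels[perm[start : start + s]] = f
        start += s
    return labels


def _variogram_combos(grids: dict) -> list[VariogramSpec]:
    return [
        VariogramSpec(model=m, nugget=n, partial_sill=s, range=r)
        for m in sorted(grids["variogram_model"])
        for s in sorted(grids["sill"])
        for r in sorted(grids["range"])
        for n in sorted(grids["nugget"])
    ]


def cv_select_model(
    readings: pd.DataFrame,
    grids: dict | None = None,
    k: int = 5,
    seed: int = DEFAULT_CV_SEED,
    secondary_readings: pd.DataFrame | None = None,
    metric: str = "euclidean",
    techniques: Sequence[str] | None = None,
) -> tuple[InterpolatorSpec, pd.DataFrame]:
    """Grid-search every technique/parameter combination with k-fold CV.

    Stations are split into k near-equal folds by a seeded permutation; for
    each candidate, held-out squared errors are pooled over folds into one
    RMSE. The least-RMSE spec wins; exact ties break by technique order
    IDW < simple < ordinary < co-kriging, then by ascending parameter order.

    Returns the winning :class:`InterpolatorSpec` and the full RMSE table.
    Co-kriging candidates are only evaluated when ``secondary_readings`` is
    given.
    """
    if grids is None:
        grids = DEFAULT_GRIDS
    grids = {**DEFAULT_GRIDS, **grids}
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    lon, lat, val = _station_arrays(readings)
    n = lon.size
    if n < k:
        raise ConfigurationError(f"k={k} folds need at least {k} stations, got {n}")
    if techniques is None:
        techniques = ["IDW", "simple_kriging", "ordinary_kriging"]
        if secondary_readings is not None:
            techniques.append("cokriging")
    folds = _make_folds(n, k, seed)

    sec = None
    if "cokriging" in techniques:
        merged = readings.merge(
            secondary_readings[["station_id", "value"]].rename(
                columns={"value": "secondary"}
            ),
            on="station_id",
            how="left",
        )
        sec = np.asarray(merged["secondary"], dtype=float)
        if np.isnan(sec).any():
            raise ConfigurationError(
                "secondary readings must cover every primary station"
            )

    idps = sorted(grids["idp"])
    betas = sorted(grids["beta"])
    vspecs = _variogram_combos(grids)

    sse_idw = np.zeros(len(idps))
    sse_sk = np.zeros((len(vspecs), len(betas)))
    sse_ok = np.zeros(len(vspecs))
    sse_cok = np.zeros((len(vspecs), len(betas)))

    tmp = pd.DataFrame({"lon": lon, "lat": lat, "value": val})
    for f in range(k):
        test = folds == f
        train = ~test
        tr = tmp[train]
        tlon, tlat, tval = lon[test], lat[test], val[test]
        if "IDW" in techniques:
            for i, idp in enumerate(idps):
                pred = idw_predict(tr, tlon, tlat, idp, metric)
                sse_idw[i] += np.sum((pred - tval) ** 2)
        if {"simple_kriging", "ordinary_kriging", "cokriging"} & set(techniques):
            trlon, trlat, trval = lon[train], lat[train], val[train]
            for vi, vs in enumerate(vspecs):
                lam_ok, c_vec, mu = _kriging_weights(
                    vs, trlon, trlat, tlon, tlat, True, metric
                )
                if "ordinary_kriging" in techniques:
                    pred = lam_ok.T @ trval
                    sse_ok[vi] += np.sum((pred - tval) ** 2)
                if "simple_kriging" in techniques:
                    lam_sk, _, _ = _kriging_weights(
                        vs, trlon, trlat, tlon, tlat, False, metric
                    )
                    proj = lam_sk.T @ trval
                    wsum = lam_sk.sum(axis=0)
                    for bi, b in enumerate(betas):
                        pred = b * (1 - wsum) + proj
                        sse_sk[vi, bi] += np.sum((pred - tval) ** 2)
                if "cokriging" in techniques:
                    base = lam_ok.T @ trval
                    shift = lam_ok.T @ sec[train] - sec[train].mean()
                    for bi, b in enumerate(betas):
                        if not 0 <= b <= 1:
                            sse_cok[vi, bi] = np.inf
                            continue
                        pred = base + b * shift
                        sse_cok[vi, bi] += np.sum((pred - tval) ** 2)

    rows: list[tuple[InterpolatorSpec, float]] = []
    if "IDW" in techniques:
        for i, idp in enumerate(idps):
            rows.append((InterpolatorSpec("IDW", idp=idp), np.sqrt(sse_idw[i] / n)))
    if "simple_kriging" in techniques:
        for vi, vs in enumerate(vspecs):
            for bi, b in enumerate(betas):
                rows.append(
                    (
                        InterpolatorSpec("simple_kriging", variogram=vs, beta=b),
                        np.sqrt(sse_sk[vi, bi] / n),
                    )
                )
    if "ordinary_kriging" in techniques:
        for vi, vs in enumerate(vspecs):
            rows.append(
                (
                    InterpolatorSpec("ordinary_kriging", variogram=vs),
                    np.sqrt(sse_ok[vi] / n),
                )
            )
    if "cokriging" in techniques:
        for vi, vs in enumerate(vspecs):
            for bi, b in enumerate(betas):
                if not 0 <= b <= 1:
                    continue
                rows.append(
                    (
                        InterpolatorSpec("cokriging", variogram=vs, beta=b),
                        np.sqrt(sse_cok[vi, bi] / n),
                    )
                )

    best_spec, best_rmse = rows[0]
    for s, r in rows[1:]:
        if r < best_rmse:
            best_spec, best_rmse = s, r

    table = pd.DataFrame(
        {
            "technique": [s.technique for s, _ in rows],
            "idp": [s.idp for s, _ in rows],
            "variogram_model": [
                s.variogram.model if s.variogram else None for s, _ in rows
            ],
            "sill": [s.variogram.partial_sill if s.variogram else None for s, _ in rows],
            "range": [s.variogram.range if s.variogram else None for s, _ in rows],
            "nugget": [s.variogram.nugget if s.variogram else None for s, _ in rows],
            "beta": [s.beta for s, _ in rows],
            "rmse": [r for _, r in rows],
        }
    )
    return best_spec, table


# ---------------------------------------------------------------------------
# maps


def predict(
    readings: pd.DataFrame,
    target_lon,
    target_lat,
    spec: InterpolatorSpec,
    secondary_readings: pd.DataFrame | None = None,
    metric: str = "euclidean",
):
    """Dispatch a prediction to the technique named in ``spec``."""
    if spec.technique == "IDW":
        return idw_predict(readings, target_lon, target_lat, spec.idp, metric)
    if spec.technique in ("simple_kriging", "ordinary_kriging"):
        pred, _ = kriging_predict(readings, target_lon, target_lat, spec, metric)
        return pred
    return cokriging_predict(
        readings, secondary_readings, target_lon, target_lat, spec, metric
    )


def default_grid_axes(
    readings: pd.DataFrame, n_lon: int = 100, n_lat: int = 100, pad: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Regular grid over the station bounding box, padded by ``pad`` of the
    box's span on each side."""
    lon, lat, _ = _station_arrays(readings)
    lo_x, hi_x = lon.min(), lon.max()
    lo_y, hi_y = lat.min(), lat.max()
    mx = (hi_x - lo_x) * pad or pad
    my = (hi_y - lo_y) * pad or pad
    return (
        np.linspace(lo_x - mx, hi_x + mx, n_lon),
        np.linspace(lo_y - my, hi_y + my, n_lat),
    )


def build_pollution_map(
    readings: pd.DataFrame,
    spec: InterpolatorSpec,
    grid_lons: np.ndarray | None = None,
    grid_lats: np.ndarray | None = None,
    secondary_readings: pd.DataFrame | None = None,
    cv_rmse: float = float("nan"),
    metric: str = "euclidean",
    n_grid: int = 100,
) -> PollutionMap:
    """Interpolate one hour's readings of one pollutant onto a regular grid."""
    if len(readings) == 0:
        raise InsufficientDataError("no readings for this hour")
    hours = pd.to_datetime(readings["hour"]).unique()
    polls = readings["pollutant"].unique()
    if len(hours) != 1 or len(polls) != 1:
        raise ValueError("readings must share a single hour and pollutant")
    if grid_lons is None or grid_lats is None:
        grid_lons, grid_lats = default_grid_axes(readings, n_grid, n_grid)
    glon, glat = np.meshgrid(grid_lons, grid_lats)
    pred = predict(
        readings, glon.ravel(), glat.ravel(), spec, secondary_readings, metric
    )
    return PollutionMap(
        hour=pd.Timestamp(hours[0]),
        pollutant=str(polls[0]),
        grid_lons=np.asarray(grid_lons),
        grid_lats=np.asarray(grid_lats),
        values=np.asarray(pred).reshape(glat.shape),
        model=spec,
        cv_rmse=cv_rmse,
    )


def map_lookup(pmap: PollutionMap, lon: float, lat: float) -> float:
    """Bilinear interpolation of a map at (lon, lat).

    Points outside the grid bounding box are clamped to the nearest edge with
    a warning.
    """
    xs, ys = pmap.grid_lons, pmap.grid_lats
    if not (xs[0] <= lon <= xs[-1]) or not (ys[0] <= lat <= ys[-1]):
        warnings.warn(
            f"point ({lon:.5f}, {lat:.5f}) outside map bounds; clamping to edge"
        )
        lon = float(np.clip(lon, xs[0], xs[-1]))
        lat = float(np.clip(lat, ys[0], ys[-1]))
    i = int(np.clip(np.searchsorted(xs, lon) - 1, 0, xs.size - 2))
    j = int(np.clip(np.searchsorted(ys, lat) - 1, 0, ys.size - 2))
    x0, x1 = xs[i], xs[i + 1]
    y0, y1 = ys[j], ys[j + 1]
    tx = 0.0 if x1 == x0 else (lon - x0) / (x1 - x0)
    ty = 0.0 if y1 == y0 else (lat - y0) / (y1 - y0)
    v = pmap.values
    return float(
        v[j, i] * (1 - tx) * (1 - ty)
        + v[j, i + 1] * tx * (1 - ty)
        + v[j + 1, i] * (1 - tx) * ty
        + v[j + 1, i + 1] * tx * ty
    )
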