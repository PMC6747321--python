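"""End-to-end orchestration: hourly maps → indoor periods → gap-filled trace
→ integrated exposure timeline → optional route ranking.

Stages run in a fixed order and every intermediate artifact is written to the
output directory; identical config + seed gives identical outputs. A missing
indoor stream degrades to an outdoor-only run with a warning (the documented
fallback when no monitor covers an indoor space).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import geostat, io, microenv, mobility, routes as routes_mod
from .errors import ConfigurationError, PapeError
from .exposure import VETable, integrate, records_to_frame, summarize
from .geostat import DEFAULT_CV_SEED, DEFAULT_GRIDS

logger = logging.getLogger("pape")

__all__ = ["RunConfig", "run_pipeline", "build_hourly_maps"]


@dataclass
class RunConfig:
    stations: str | Path
    trace: str | Path
    out_dir: str | Path
    monitor: str | Path | None = None
    pings: str | Path | None = None
    routes: str | Path | None = None
    pollutant: str = "PM2.5"
    secondary_pollutant: str | None = None
    grids: dict = field(default_factory=dict)
    k: int = 5
    seed: int = DEFAULT_CV_SEED
    gap_minutes: float = microenv.DEFAULT_GAP_MINUTES
    ve: VETable = field(default_factory=VETable)
    n_grid: int = 100
    metric: str = "euclidean"
    baseline_route: str = "Actual"
    indoor_coords: tuple[float, float] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ve = VETable(**raw.pop("ve", {}))
        indoor = raw.pop("indoor_coords", None)
        return cls(
            **raw, ve=ve,
            indoor_coords=tuple(indoor) if indoor is not None else None,
        )

    def __post_init__(self) -> None:
        for name in ("stations", "trace"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} file not found: {p}")


def build_hourly_maps(
    readings: pd.DataFrame,
    pollutant: str = "PM2.5",
    secondary_pollutant: str | None = None,
    grids: dict | None = None,
    k: int = 5,
    seed: int = DEFAULT_CV_SEED,
    n_grid: int = 100,
    metric: str = "euclidean",
) -> dict[pd.Timestamp, geostat.PollutionMap]:
    """Per hour: grid-searched CV model selection, then a gridded map.

    All hourly maps share the grid axes of the full station set so lookups
    are comparable across hours.
    """
    sel = readings[readings["pollutant"] == pollutant]
    if sel.empty:
        raise ConfigurationError(f"no readings for pollutant {pollutant!r}")
    grid_lons, grid_lats = geostat.default_grid_axes(sel, n_grid, n_grid)
    maps: dict[pd.Timestamp, geostat.PollutionMap] = {}
    for hour, grp in sel.groupby("hour"):
        secondary = None
        if secondary_pollutant is not None:
            secondary = readings[
                (readings["pollutant"] == secondary_pollutant)
                & (readings["hour"] == hour)
            ]
        spec, table = geostat.cv_select_model(
            grp, grids=grids, k=k, seed=seed,
            secondary_readings=secondary, metric=metric,
        )
        maps[pd.Timestamp(hour)] = geostat.build_pollution_map(
            grp, spec, grid_lons, grid_lats,
            secondary_readings=secondary,
            cv_rmse=float(table["rmse"].min()), metric=metric,
        )
        logger.info("hour %s: selected %s (rmse=%.4g)", hour, spec.technique,
                    table["rmse"].min())
    return maps


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return a JSON-serialisable run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **info
            }
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)

        return done

    # --- geostat ------------------------------------------------------
    done = stage("geostat")
    readings = io.read_stations_csv(config.stations)
    maps = build_hourly_maps(
        readings,
        pollutant=config.pollutant,
        secondary_pollutant=config.secondary_pollutant,
        grids=config.grids or None,
        k=config.k,
        seed=config.seed,
        n_grid=config.n_grid,
        metric=config.metric,
    )
    selected = {
        str(h): m.model.technique for h, m in sorted(maps.items())
    }
    for h, m in maps.items():
        io.write_map_metadata(m, out / f"map_{h:%Y%m%d%H}.meta.json")
    done(hours=len(maps), selected_models=selected)

    # --- microenv -----------------------------------------------------
    done = stage("microenv")
    periods = []
    if config.monitor is not None and config.pings is not None:
        stream = io.read_monitor_csv(config.monitor)
        pings = io.read_pings_csv(config.pings)
        periods = microenv.build_indoor_periods(
            pings, stream, config.gap_minutes
        )
    else:
        warnings.warn(
            "no indoor monitor/ping inputs: outdoor-only run "
            "(outdoor maps used for the whole day)"
        )
    done(indoor_periods=len(periods))

    # --- mobility -----------------------------------------------------
    done = stage("mobility")
    trace = mobility.load_trace(io.read_trace_csv(config.trace))
    trace = mobility.fill_rest_gaps(trace)
    io.write_trace_csv(trace, out / "trace_filled.csv")
    done(segments=len(trace))

    # --- exposure -----------------------------------------------------
    done = stage("exposure")
    records = integrate(
        trace, periods, maps, config.ve, config.pollutant,
        indoor_coords=config.indoor_coords,
    )
    io.write_exposure_csv(records, out / "exposure.csv")
    by_act = summarize(records, by="activity")
    by_env = summarize(records, by="environment_location")
    by_act.to_csv(out / "summary_by_activity.csv", index=False)
    by_env.to_csv(out / "summary_by_environment.csv", index=False)
    total = float(records_to_frame(records)["exposure"].sum())
    done(records=len(records), total_exposure_ug=round(total, 5))

    # --- routes -------------------------------------------------------
    if config.routes is not None:
        done = stage("routes")
        opts = io.read_routes_csv(config.routes)
        routes_mod.evaluate_routes(opts, maps, config.ve)
        ranked = routes_mod.rank_routes(opts, config.ve, config.baseline_route)
        ranked.to_csv(out / "routes_ranked.csv", index=False)
        done(n_routes=len(opts), best=str(ranked.iloc[0]["route"]))

    report["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
    }
    report["total_exposure_ug"] = total
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
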