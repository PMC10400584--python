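"""Readers, writers, configuration, and the end-to-end pipeline.

Formats
-------
* Gridded hourly ozone: CF-style NetCDF with dimensions time/y/x, a
  mandatory ``units`` attribute ("ppmV" or "ppbV"; ppbV is divided by
  1000 on read), time encoded as hours since a stated epoch.
* Counties: GeoJSON FeatureCollection with properties ``county_id``,
  ``region`` and ``production_bu`` (null marks a combined/withheld
  record).
* Tabular outputs: UTF-8 CSV with a header row, ``county_id`` first.
* Configuration: YAML, validated up front; unknown keys are rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import mapping, shape

from .aggregation import (
    County,
    CountySet,
    aggregate_concentration_first,
    aggregate_exposure,
    compute_area_weights,
)
from .dose_response import DoseResponseParams, compute_impacts
from .exposure import (
    DEFAULT_THRESHOLD_PPMV,
    ExposureGrid,
    ExposureWindow,
    HourlyO3Grid,
    aot40_grid,
)
from .grid import GridSpec, make_grid
from .scenarios import ScenarioReport, build_report
from .synthetic import CountyLayout, ScenarioFieldConfig, generate_scenario_fields, make_counties

logger = logging.getLogger(__name__)

_NC_ENGINE = "scipy"  # NETCDF3 classic


# ---------------------------------------------------------------- NetCDF

def write_o3_cube(cube: HourlyO3Grid, path) -> None:
    """Write an hourly ozone cube as CF-style NetCDF (dims time/y/x)."""
    g = cube.grid
    ds = xr.Dataset(
        {"o3": (("time", "y", "x"), cube.values, {"units": cube.units_tag,
                                                  "long_name": "hourly mean surface ozone"})},
        coords={"time": cube.times, "y": g.y_centers, "x": g.x_centers},
        attrs={
            "cell_size": g.cell_size,
            "origin_x": g.origin[0],
            "origin_y": g.origin[1],
            "crs_note": g.crs_note,
        },
    )
    ds.to_netcdf(path, engine=_NC_ENGINE)


def read_o3_cube(path, units_tag: str | None = None) -> HourlyO3Grid:
    """Read a NetCDF ozone cube into the canonical ppmV container.

    ``units_tag`` overrides the file's ``units`` attribute; one of the
    two must be present.  Non-hourly cadence, missing units and negative
    values are rejected naming the file.
    """
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        if "o3" not in ds:
            raise ValueError(f"{path}: no 'o3' variable")
        var = ds["o3"]
        if var.dims != ("time", "y", "x"):
            raise ValueError(f"{path}: 'o3' dims must be (time, y, x), got {var.dims}")
        units = units_tag or var.attrs.get("units")
        if units is None:
            raise ValueError(f"{path}: variable 'o3' has no units attribute")
        if units not in ("ppmV", "ppbV"):
            raise ValueError(f"{path}: unrecognised units {units!r}")
        values = var.values.astype(float)
        times = pd.DatetimeIndex(ds["time"].values)
        if units == "ppbV":
            values = values / 1000.0
        x = ds["x"].values
        y = ds["y"].values
        cell = float(ds.attrs.get("cell_size", x[1] - x[0] if len(x) > 1 else 1.0))
        ox = float(ds.attrs.get("origin_x", x[0] - cell / 2))
        oy = float(ds.attrs.get("origin_y", y[0] - cell / 2))
        grid = make_grid(len(x), len(y), cell, origin=(ox, oy),
                         crs_note=str(ds.attrs.get("crs_note", "planar")))
    steps = np.diff(times.asi8)
    if len(times) > 1 and not np.all(steps == 3_600_000_000_000):
        raise ValueError(f"{path}: time cadence is not exactly hourly")
    if (values < 0).any():
        raise ValueError(f"{path}: variable 'o3' contains negative concentrations")
    return HourlyO3Grid(values=values, times=times, grid=grid)


def write_exposure(exposure: ExposureGrid, path) -> None:
    """Write a per-cell AOT40 field as NetCDF with window metadata."""
    g = exposure.grid
    ds = xr.Dataset(
        {"aot40": (("y", "x"), exposure.aot40, {"units": "ppmV hr"})},
        coords={"y": g.y_centers, "x": g.x_centers},
        attrs={
            "window_start": str(exposure.window.start),
            "window_end": str(exposure.window.end),
            "hours_of_day": ",".join(str(h) for h in sorted(exposure.window.hours_of_day)),
            "threshold_ppmv": exposure.threshold,
            "cell_size": g.cell_size,
            "origin_x": g.origin[0],
            "origin_y": g.origin[1],
            "crs_note": g.crs_note,
        },
    )
    ds.to_netcdf(path, engine=_NC_ENGINE)


def read_exposure(path) -> ExposureGrid:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        window = ExposureWindow(
            start=pd.Timestamp(ds.attrs["window_start"]),
            end=pd.Timestamp(ds.attrs["window_end"]),
            hours_of_day=frozenset(int(h) for h in str(ds.attrs["hours_of_day"]).split(",")),
        )
        x, y = ds["x"].values, ds["y"].values
        cell = float(ds.attrs["cell_size"])
        grid = make_grid(len(x), len(y), cell,
                         origin=(float(ds.attrs["origin_x"]), float(ds.attrs["origin_y"])),
                         crs_note=str(ds.attrs.get("crs_note", "planar")))
        return ExposureGrid(aot40=ds["aot40"].values.astype(float), window=window,
                            threshold=float(ds.attrs["threshold_ppmv"]), grid=grid)


# ---------------------------------------------------------------- GeoJSON

def write_counties(counties: CountySet, path) -> None:
    """Write counties as a GeoJSON FeatureCollection."""
    features = []
    for c in counties:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(c.polygon),
                "properties": {
                    "county_id": c.county_id,
                    "region": c.region,
                    "production_bu": c.production_bu,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}), encoding="utf-8"
    )


def read_counties(path) -> CountySet:
    """Read and validate a county GeoJSON file.

    Features with ``production_bu`` null/absent are kept and flagged as
    combined/withheld (excluded from impact totals downstream) with a
    logged count.  Malformed geometry and duplicate IDs are rejected.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    counties = []
    n_withheld = 0
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        if "county_id" not in props or "region" not in props:
            raise ValueError(f"{path}: feature missing county_id/region properties")
        prod = props.get("production_bu")
        if prod is None:
            n_withheld += 1
        counties.append(
            County(
                county_id=str(props["county_id"]),
                polygon=shape(feat["geometry"]),
                region=str(props["region"]),
                production_bu=None if prod is None else float(prod),
            )
        )
    if n_withheld:
        logger.warning("%s: %d county(ies) with withheld/combined production", path, n_withheld)
    return CountySet(counties)


# ---------------------------------------------------------------- Config

_KNOWN_KEYS = {
    "output_dir", "cube_paths", "counties_path", "synthetic",
    "window", "threshold_ppmv", "dose_response", "aggregation_mode",
    "reference_production_bu", "scenario_labels", "seed", "log_level",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Inputs come either from files (``cube_paths`` + ``counties_path``)
    or from the synthetic generator (``synthetic: true``, driven by
    ``seed``).  All thresholds, windows and dose-response parameters are
    explicit here.
    """

    output_dir: Path = Path("ozcrop_out")
    cube_paths: tuple[str, str] | None = None
    counties_path: str | None = None
    synthetic: bool = True
    window: ExposureWindow | None = None
    threshold_ppmv: float = DEFAULT_THRESHOLD_PPMV
    dose_response: DoseResponseParams = dc_field(default_factory=DoseResponseParams)
    aggregation_mode: str = "exposure_first"
    reference_production_bu: float | None = None
    scenario_labels: tuple[str, str] = ("BAU", "C19")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.aggregation_mode not in ("exposure_first", "concentration_first"):
            raise ValueError(
                f"aggregation_mode must be 'exposure_first' or 'concentration_first', "
                f"got {self.aggregation_mode!r}"
            )
        if not self.threshold_ppmv > 0:
            raise ValueError("threshold_ppmv must be > 0")
        if not self.synthetic and (self.cube_paths is None or self.counties_path is None):
            raise ValueError("non-synthetic mode requires cube_paths and counties_path")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("output_dir", "counties_path", "synthetic", "threshold_ppmv",
                    "aggregation_mode", "reference_production_bu", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cube_paths" in raw:
            kwargs["cube_paths"] = tuple(raw["cube_paths"])
        if "scenario_labels" in raw:
            kwargs["scenario_labels"] = tuple(raw["scenario_labels"])
        if "window" in raw:
            w = raw["window"]
            kwargs["window"] = ExposureWindow(
                start=pd.Timestamp(w["start"]),
                end=pd.Timestamp(w["end"]),
                hours_of_day=frozenset(w.get("hours_of_day", range(24))),
            )
        if "dose_response" in raw:
            kwargs["dose_response"] = DoseResponseParams(**raw["dose_response"])
        if seed_override is not None:
            kwargs["seed"] = seed_override
        return cls(**kwargs)


# ---------------------------------------------------------------- Pipeline

def _load_inputs(config: PipelineConfig):
    """Resolve config to (cube_ref, cube_pert, counties, window)."""
    if config.synthetic:
        from .synthetic import default_study

        grid, counties, cfg = default_study(seed=config.seed)
        cfg.scenario_labels = config.scenario_labels
        cube_ref, cube_pert = generate_scenario_fields(grid, cfg)
    else:
        cube_ref = read_o3_cube(config.cube_paths[0])
        cube_pert = read_o3_cube(config.cube_paths[1])
        counties = read_counties(config.counties_path)
    window = config.window
    if window is None:
        t0 = cube_ref.times[0]
        window = ExposureWindow(start=t0, end=cube_ref.times[-1] + pd.Timedelta(hours=1))
    return cube_ref, cube_pert, counties, window


def run_pipeline(config: PipelineConfig) -> ScenarioReport:
    """End-to-end run: inputs -> exposures -> county impacts -> report.

    Writes, under ``config.output_dir``: one per-county impact CSV per
    scenario, a per-county delta CSV, a regional min/max summary CSV,
    and a totals CSV.  Deterministic given the config (including seed in
    synthetic mode).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        cube_ref, cube_pert, counties, window = _load_inputs(config)

        stage = "area weights"
        weights = compute_area_weights(cube_ref.grid, counties)

        tables = {}
        for label, cube in zip(config.scenario_labels, (cube_ref, cube_pert)):
            stage = f"exposure ({label})"
            if config.aggregation_mode == "exposure_first":
                exp = aot40_grid(cube, window, config.threshold_ppmv)
                county_exp = aggregate_exposure(exp, weights)
            else:
                county_exp = aggregate_concentration_first(
                    cube, weights, window, config.threshold_ppmv
                )
            stage = f"impacts ({label})"
            tables[label] = compute_impacts(county_exp, counties, config.dose_response)

        stage = "report"
        ref, pert = config.scenario_labels
        report = build_report(
            tables[ref], tables[pert], labels=config.scenario_labels,
            price_usd_per_bu=config.dose_response.price_usd_per_bu,
            reference_production_bu=config.reference_production_bu,
        )

        stage = "write outputs"
        for label, table in tables.items():
            _write_csv(table, out / f"impacts_{label}.csv")
        _write_csv(report.deltas, out / "deltas.csv")
        _write_csv(report.regional, out / "regional_summary.csv", index_col=None)
        _write_csv(report.totals_frame(), out / "totals.csv", index_col=None)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return report


def _write_csv(df: pd.DataFrame, path, index_col: str | None = "county_id") -> None:
    cols = list(df.columns)
    if index_col and index_col in cols:
        cols = [index_col] + [c for c in cols if c != index_col]
    df[cols].to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def write_synthetic_inputs(output_dir, seed: int = 0, n_days: int = 92) -> dict:
    """Generate and write the reference synthetic study to disk.

    Produces two NetCDF cubes, a county GeoJSON and a YAML config that
    reads them back; returns the paths.
    """
    from .synthetic import default_study

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid, counties, cfg = default_study(seed=seed, n_days=n_days)
    cube_ref, cube_pert = generate_scenario_fields(grid, cfg)
    paths = {
        "cube_bau": out / "o3_bau.nc",
        "cube_c19": out / "o3_c19.nc",
        "counties": out / "counties.geojson",
        "config": out / "config.yaml",
    }
    write_o3_cube(cube_ref, paths["cube_bau"])
    write_o3_cube(cube_pert, paths["cube_c19"])
    write_counties(counties, paths["counties"])
    cfg_yaml = {
        "synthetic": False,
        "cube_paths": [str(paths["cube_bau"]), str(paths["cube_c19"])],
        "counties_path": str(paths["counties"]),
        "output_dir": str(out / "results"),
        "seed": seed,
    }
    paths["config"].write_text(yaml.safe_dump(cfg_yaml), encoding="utf-8")
    return paths
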