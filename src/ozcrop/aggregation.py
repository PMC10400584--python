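"""Area-weighted aggregation of gridded exposures to county polygons.

Crop production is tallied per county, so per-cell exposures are
converted to county values as an area-weighted mean: each cell's weight
is the fraction of the county's in-domain area that falls in that cell.
Counties partially outside the grid are renormalised over the covered
part and flagged via ``coverage_fraction`` (mirroring edge-of-domain
counties); counties wholly outside get an empty weight row.

Because AOT40 is a thresholded (nonlinear) function of concentration,
averaging AOT40 over cells and computing AOT40 of the county-average
concentration differ.  The default aggregates per-cell AOT40; the
``concentration_first`` path county-averages the hourly concentrations
and then applies the accumulation, so both readings are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.validation import explain_validity

from .exposure import (
    DEFAULT_THRESHOLD_PPMV,
    ExposureGrid,
    ExposureWindow,
    HourlyO3Grid,
    aot40_grid,
    aot40_series,
)
from .grid import GridSpec

logger = logging.getLogger(__name__)

#: The five reporting regions used for regional summaries.
REGIONS = ("Northeast", "Midwest", "Southeast", "Southwest", "West")


@dataclass
class County:
    """One county: ID, polygon (planar, grid coordinates), region label,
    and crop production in bushels.  ``production_bu=None`` marks a
    "combined/withheld" record whose production cannot be attributed to
    the county individually; such counties are excluded from impact
    totals (with a logged count) but still receive an exposure."""

    county_id: str
    polygon: object
    region: str
    production_bu: float | None = 0.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"county {self.county_id}: unknown region {self.region!r}")
        if self.production_bu is not None:
            p = float(self.production_bu)
            if not np.isfinite(p) or p < 0:
                raise ValueError(f"county {self.county_id}: invalid production {p}")
            self.production_bu = p


@dataclass
class CountySet:
    counties: list[County]

    def __post_init__(self) -> None:
        ids = [c.county_id for c in self.counties]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate county IDs: {sorted(dupes)}")
        for c in self.counties:
            if c.polygon.area == 0:
                raise ValueError(f"county {c.county_id}: zero-area polygon")
            if not c.polygon.is_valid:
                raise ValueError(
                    f"county {c.county_id}: invalid polygon "
                    f"({explain_validity(c.polygon)})"
                )

    def __iter__(self):
        return iter(self.counties)

    def __len__(self) -> int:
        return len(self.counties)

    def __getitem__(self, county_id: str) -> County:
        for c in self.counties:
            if c.county_id == county_id:
                return c
        raise KeyError(county_id)

    @property
    def ids(self) -> list[str]:
        return [c.county_id for c in self.counties]

    def production_frame(self) -> pd.DataFrame:
        """county_id, region, production_bu (NaN when withheld)."""
        return pd.DataFrame(
            {
                "county_id": self.ids,
                "region": [c.region for c in self.counties],
                "production_bu": [
                    np.nan if c.production_bu is None else c.production_bu
                    for c in self.counties
                ],
            }
        )


@dataclass
class AreaWeightMatrix:
    """Sparse county -> cell weights.

    ``entries[county_id]`` maps a flat cell index ``j * n_x + i`` to a
    weight in [0, 1]; weights of a county with any overlap sum to 1.
    ``coverage_fraction[county_id]`` is the fraction of the county's area
    inside the grid domain; counties fully outside have an empty row.
    """

    grid: GridSpec
    entries: dict[str, dict[int, float]]
    coverage_fraction: dict[str, float] = field(default_factory=dict)

    def weight_row(self, county_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(flat cell indices, weights) arrays for one county."""
        row = self.entries[county_id]
        idx = np.fromiter(row.keys(), dtype=int, count=len(row))
        w = np.fromiter(row.values(), dtype=float, count=len(row))
        return idx, w


def compute_area_weights(grid: GridSpec, counties: CountySet) -> AreaWeightMatrix:
    """Exact polygon-cell intersection-area weights.

    weight(c, cell) = area(polygon_c ∩ cell) / area(polygon_c ∩ domain).
    """
    domain = grid.domain_polygon()
    xe, ye = grid.x_edges, grid.y_edges
    entries: dict[str, dict[int, float]] = {}
    coverage: dict[str, float] = {}

    for county in counties:
        poly = county.polygon
        clipped = poly.intersection(domain)
        coverage[county.county_id] = clipped.area / poly.area
        row: dict[int, float] = {}
        if clipped.area > 0:
            minx, miny, maxx, maxy = clipped.bounds
            # restrict the double loop to cells the bounding box can touch
            i0 = max(int(np.searchsorted(xe, minx, side="right")) - 1, 0)
            i1 = min(int(np.searchsorted(xe, maxx, side="left")), grid.n_x)
            j0 = max(int(np.searchsorted(ye, miny, side="right")) - 1, 0)
            j1 = min(int(np.searchsorted(ye, maxy, side="left")), grid.n_y)
            total = clipped.area
            for j in range(j0, j1):
                for i in range(i0, i1):
                    a = clipped.intersection(grid.cell_polygon(j, i)).area
                    if a > 0:
                        row[j * grid.n_x + i] = a / total
        else:
            logger.warning(
                "county %s lies entirely outside the grid domain; empty weight row",
                county.county_id,
            )
        entries[county.county_id] = row

    return AreaWeightMatrix(grid=grid, entries=entries, coverage_fraction=coverage)


def aggregate_exposure(exposure: ExposureGrid, weights: AreaWeightMatrix) -> pd.DataFrame:
    """Area-weighted county mean of per-cell AOT40.

    Returns a CountyExposureTable: columns ``county_id``, ``aot40``
    (ppmV hr) and ``coverage_fraction``.  Counties with an empty weight
    row (no domain overlap) are excluded with a logged count.
    """
    if exposure.grid != weights.grid:
        raise ValueError("exposure and weights were built on different grids")
    flat = exposure.aot40.ravel()
    rows = []
    n_skipped = 0
    for county_id, row in weights.entries.items():
        if not row:
            n_skipped += 1
            continue
        idx, w = weights.weight_row(county_id)
        rows.append(
            {
                "county_id": county_id,
                "aot40": float(np.dot(flat[idx], w)),
                "coverage_fraction": weights.coverage_fraction[county_id],
            }
        )
    if n_skipped:
        logger.warning("excluded %d county(ies) with no grid-domain overlap", n_skipped)
    return pd.DataFrame(rows, columns=["county_id", "aot40", "coverage_fraction"])


def aggregate_concentration_first(
    cube: HourlyO3Grid,
    weights: AreaWeightMatrix,
    window: ExposureWindow,
    threshold: float = DEFAULT_THRESHOLD_PPMV,
) -> pd.DataFrame:
    """Alternative reading: county-average the hourly concentrations by
    area, then apply the AOT40 accumulation to the county series."""
    # reuse aot40_grid's window validation by running it once on the cube
    aot40_grid(cube, window, threshold)
    t = cube.times
    sel = (t >= window.start) & (t < window.end) & np.isin(t.hour, list(window.hours_of_day))
    vals = cube.values[sel].reshape(int(sel.sum()), -1)
    rows = []
    for county_id, row in weights.entries.items():
        if not row:
            continue
        idx, w = weights.weight_row(county_id)
        series = vals[:, idx] @ w
        rows.append(
            {
                "county_id": county_id,
                "aot40": aot40_series(series, threshold),
                "coverage_fraction": weights.coverage_fraction[county_id],
            }
        )
    return pd.DataFrame(rows, columns=["county_id", "aot40", "coverage_fraction"])
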