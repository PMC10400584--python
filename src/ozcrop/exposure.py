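"""AOT40 cumulative ozone-exposure index.

AOT40 (Accumulated Ozone exposure over a Threshold of 40 ppb) is the sum,
over the hours of a growing-season window, of the positive part of the
hourly-mean ozone concentration minus 0.04 ppmV:

    AOT40 = sum_i max(C_i - 0.04, 0)   [ppmV hr]

The 40 ppb cutoff reflects the anthropogenic component of the exposure,
not a biological damage threshold.  The canonical internal unit is ppmV
throughout; ppbV appears only at I/O boundaries.

An hour exactly at the threshold contributes zero either way, so the
positive-part form makes the ">= threshold" and "> threshold" readings of
the accumulation condition identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger(__name__)

#: Default accumulation threshold, ppmV (i.e. 40 ppb).
DEFAULT_THRESHOLD_PPMV = 0.04

#: Conversion factor ppbV -> ppmV.
PPB_PER_PPM = 1000.0


@dataclass
class HourlyO3Grid:
    """Hourly surface-ozone concentration cube on a regular grid.

    ``values`` has shape (time, y, x) in ppmV; ``times`` is a strictly
    increasing hourly :class:`pandas.DatetimeIndex`.
    """

    values: np.ndarray
    times: pd.DatetimeIndex
    grid: GridSpec
    units_tag: str = "ppmV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (time, y, x), got shape {self.values.shape}")
        nt, ny, nx = self.values.shape
        if (ny, nx) != (self.grid.n_y, self.grid.n_x):
            raise ValueError(
                f"values shape {(ny, nx)} does not match grid ({self.grid.n_y}, {self.grid.n_x})"
            )
        if len(self.times) != nt:
            raise ValueError(f"{len(self.times)} timestamps for {nt} time slices")
        if self.units_tag != "ppmV":
            raise ValueError(f"internal cubes must be ppmV, got {self.units_tag!r}")
        steps = np.diff(self.times.asi8)
        if nt > 1 and not np.all(steps == 3_600_000_000_000):
            raise ValueError("time step must be exactly 1 hour and strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("NaN concentrations in cube")
        if (self.values < 0).any():
            raise ValueError("negative concentrations in cube")

    @property
    def n_hours(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ExposureWindow:
    """Accumulation window: [start, end) plus the hours of day to count.

    The default mirrors the May-June-July growing season with all 24
    hours accumulated.  The conventional daylight-only AOT40 is obtained
    with e.g. ``hours_of_day=range(8, 20)``.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    hours_of_day: frozenset = field(default_factory=lambda: frozenset(range(24)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        object.__setattr__(self, "hours_of_day", frozenset(int(h) for h in self.hours_of_day))
        if not self.end > self.start:
            raise ValueError(f"window end {self.end} must be after start {self.start}")
        if not self.hours_of_day:
            raise ValueError("hours_of_day must be non-empty")
        if not self.hours_of_day <= set(range(24)):
            raise ValueError("hours_of_day must be a subset of 0..23")


def mjj_window(year: int = 2020, hours_of_day=range(24)) -> ExposureWindow:
    """May 1 -- Aug 1 (exclusive) window for ``year``: the MJJ season."""
    return ExposureWindow(
        start=pd.Timestamp(year=year, month=5, day=1),
        end=pd.Timestamp(year=year, month=8, day=1),
        hours_of_day=frozenset(hours_of_day),
    )


@dataclass
class ExposureGrid:
    """Per-cell AOT40 (ppmV hr) for a stated window and threshold."""

    aot40: np.ndarray
    window: ExposureWindow
    threshold: float
    grid: GridSpec

    def __post_init__(self) -> None:
        self.aot40 = np.asarray(self.aot40, dtype=float)
        if self.aot40.shape != (self.grid.n_y, self.grid.n_x):
            raise ValueError("aot40 shape does not match grid")
        if (self.aot40 < 0).any():
            raise ValueError("AOT40 must be non-negative")


def aot40_series(
    concentrations,
    threshold: float = DEFAULT_THRESHOLD_PPMV,
    *,
    skip_missing: bool = False,
) -> float:
    """AOT40 of one hourly concentration series, in ppmV hr.

    Parameters
    ----------
    concentrations
        Hourly-mean ozone values in ppmV; all must be >= 0.
    threshold
        Accumulation cutoff in ppmV (default 0.04).
    skip_missing
        If False (default), any NaN is rejected.  If True, NaN hours are
        dropped with a logged count and the remaining hours are summed
        with no rescaling -- AOT40 is a sum, not a mean, so gaps bias the
        exposure low; the policy makes that bias explicit.
    """
    c = np.asarray(concentrations, dtype=float)
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    nan_mask = np.isnan(c)
    if nan_mask.any():
        if not skip_missing:
            raise ValueError(
                f"{int(nan_mask.sum())} NaN hour(s) in series; pass skip_missing=True "
                "to drop them (no rescaling is applied)"
            )
        logger.warning("AOT40: skipping %d missing hour(s) of %d", int(nan_mask.sum()), c.size)
        c = c[~nan_mask]
    if (c < 0).any():
        raise ValueError("negative concentrations in series")
    return float(np.maximum(c - threshold, 0.0).sum())


def aot40_grid(
    cube: HourlyO3Grid,
    window: ExposureWindow,
    threshold: float = DEFAULT_THRESHOLD_PPMV,
) -> ExposureGrid:
    """Apply the AOT40 accumulation per grid cell over ``window``.

    Every calendar hour of ``[window.start, window.end)`` whose hour of
    day is in ``window.hours_of_day`` must be present in the cube;
    otherwise the missing span is named in the error.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    t = cube.times
    in_span = (t >= window.start) & (t < window.end)
    in_hours = np.isin(t.hour, list(window.hours_of_day))
    sel = in_span & in_hours

    expected = pd.date_range(window.start, window.end, freq="h", inclusive="left")
    expected = expected[np.isin(expected.hour, list(window.hours_of_day))]
    missing = expected.difference(t[sel])
    if len(missing) > 0:
        raise ValueError(
            f"window not covered by cube: {len(missing)} hour(s) missing, "
            f"first {missing[0]}, last {missing[-1]}"
        )

    vals = cube.values[sel]
    aot = np.maximum(vals - threshold, 0.0).sum(axis=0)
    return ExposureGrid(aot40=aot, window=window, threshold=float(threshold), grid=cube.grid)


def convert_units(values, from_tag: str, times: pd.DatetimeIndex, grid: GridSpec) -> HourlyO3Grid:
    """Build a canonical-ppmV cube from an array tagged ppmV or ppbV."""
    arr = np.asarray(values, dtype=float)
    if from_tag == "ppmV":
        pass
    elif from_tag == "ppbV":
        arr = arr / PPB_PER_PPM
    else:
        raise ValueError(f"unknown units tag {from_tag!r}; expected 'ppmV' or 'ppbV'")
    return HourlyO3Grid(values=arr, times=times, grid=grid)


def ppb_to_ppm(x):
    """Scalar/array ppbV -> ppmV conversion."""
    return np.asarray(x, dtype=float) / PPB_PER_PPM
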