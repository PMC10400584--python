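"""Regular planar grid geometry.

The analysis operates on a rectangular, axis-aligned grid of square cells
(the synthetic stand-in for a 12 x 12 km air-quality model domain).  Cells
are half-open intervals ``[x, x + cell_size)`` so they tile the domain
exactly with no overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid of square cells.

    Parameters
    ----------
    n_x, n_y
        Number of cells along x and y.  Must be >= 1.
    cell_size
        Edge length of each (square) cell, in the planar length unit of
        the coordinate frame.
    origin
        ``(x0, y0)`` coordinates of the lower-left corner of cell (0, 0).
    crs_note
        Free-text tag describing the coordinate frame; synthetic grids
        use ``"planar"``.  Geographic inputs must be projected to an
        equal-area planar frame before area weighting.
    """

    n_x: int
    n_y: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_note: str = "planar"

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got n_x={self.n_x}, n_y={self.n_y}"
            )
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def x_edges(self) -> np.ndarray:
        """Cell edge x-coordinates, length ``n_x + 1``."""
        return self.origin[0] + self.cell_size * np.arange(self.n_x + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.origin[1] + self.cell_size * np.arange(self.n_y + 1)

    @property
    def x_centers(self) -> np.ndarray:
        """Cell centre x-coordinates, ``origin_x + (i + 0.5) * cell_size``."""
        return self.origin[0] + self.cell_size * (np.arange(self.n_x) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.cell_size * (np.arange(self.n_y) + 0.5)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Domain bounds ``(x_min, y_min, x_max, y_max)``."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_x * self.cell_size, y0 + self.n_y * self.cell_size)

    def domain_polygon(self):
        """Whole domain as a shapely box."""
        return box(*self.extent)

    def cell_polygon(self, j: int, i: int):
        """Polygon of cell at row ``j`` (y index), column ``i`` (x index)."""
        x0 = self.origin[0] + i * self.cell_size
        y0 = self.origin[1] + j * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def center_mask(self, polygon) -> np.ndarray:
        """Boolean (n_y, n_x) mask of cells whose centre lies in ``polygon``.

        Uses shapely ``covers`` so centres on the polygon boundary count
        as inside.
        """
        from shapely import points as _points
        from shapely import covers as _covers

        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        pts = _points(np.column_stack([xx.ravel(), yy.ravel()]))
        return _covers(polygon, pts).reshape(self.n_y, self.n_x)


def make_grid(
    n_x: int,
    n_y: int,
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    crs_note: str = "planar",
) -> GridSpec:
    """Build a :class:`GridSpec`, validating dimensions."""
    return GridSpec(n_x=int(n_x), n_y=int(n_y), cell_size=float(cell_size),
                    origin=(float(origin[0]), float(origin[1])), crs_note=crs_note)
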