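"""Aggregate a per-cell exposure field to counties by intersection area.

County AOT40 is the area-weighted mean of the cells the county polygon
overlaps; weights are exact polygon-cell intersection areas normalised
over the county's in-domain area.
"""

import numpy as np
from shapely.geometry import Polygon, box

from ozcrop import (
    County,
    CountySet,
    ExposureWindow,
    aggregate_exposure,
    compute_area_weights,
    make_grid,
)
from ozcrop.exposure import ExposureGrid

grid = make_grid(3, 3, 1.0)
counties = CountySet(
    [
        County("ONE_CELL", box(1, 1, 2, 2), "Midwest", 1000.0),
        County("L_SHAPE", Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 3), (0, 3)]),
               "Southeast", 2500.0),
    ]
)
weights = compute_area_weights(grid, counties)
for cid, row in weights.entries.items():
    pretty = {k: round(v, 3) for k, v in sorted(row.items())}
    print(f"{cid}: cell weights {pretty}")

field = np.arange(9.0).reshape(3, 3)  # cell AOT40 0..8 by flat index
exposure = ExposureGrid(field, ExposureWindow("2020-05-01", "2020-05-02"), 0.04, grid)
table = aggregate_exposure(exposure, weights)
print(table.to_string(index=False))
# ONE_CELL takes exactly its single cell's value; L_SHAPE is the
# area-weighted mean of the four cells it covers.
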