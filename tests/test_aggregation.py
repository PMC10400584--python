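"""Area-weighted grid-to-county aggregation, with a Monte-Carlo oracle."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from ozcrop import (
    AreaWeightMatrix,
    County,
    CountySet,
    ExposureGrid,
    ExposureWindow,
    HourlyO3Grid,
    aggregate_concentration_first,
    aggregate_exposure,
    aot40_series,
    compute_area_weights,
    make_grid,
)
from conftest import hourly_times


def mc_weights(polygon, grid, n_points=100_000, seed=7):
    """Monte-Carlo point-in-polygon estimate of cell weights."""
    from shapely import contains_xy

    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    inside = contains_xy(polygon, xs, ys)
    xs, ys = xs[inside], ys[inside]
    i = np.floor((xs - grid.origin[0]) / grid.cell_size).astype(int)
    j = np.floor((ys - grid.origin[1]) / grid.cell_size).astype(int)
    ok = (i >= 0) & (i < grid.n_x) & (j >= 0) & (j < grid.n_y)
    flat = j[ok] * grid.n_x + i[ok]
    counts = np.bincount(flat, minlength=grid.n_cells).astype(float)
    return counts / counts.sum()


def exposure_of(grid, field):
    return ExposureGrid(
        aot40=np.asarray(field, dtype=float),
        window=ExposureWindow("2020-05-01", "2020-05-02"),
        threshold=0.04,
        grid=grid,
    )


class TestWeights:
    def test_county_equal_to_one_cell(self, grid3):
        cs = CountySet([County("A", box(1, 1, 2, 2), "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        assert w.entries["A"] == {1 * 3 + 1: pytest.approx(1.0)}
        assert w.coverage_fraction["A"] == pytest.approx(1.0)

    def test_two_cell_symmetric_split(self, grid3):
        cs = CountySet([County("A", box(0, 0, 2, 1), "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        assert w.entries["A"][0] == pytest.approx(0.5)
        assert w.entries["A"][1] == pytest.approx(0.5)

    def test_weights_sum_to_one(self, grid3, rng):
        polys = [box(0.3, 0.2, 2.7, 1.9), Polygon([(0, 0), (3, 0), (0, 3)])]
        cs = CountySet([County(f"P{k}", p, "Midwest", 1.0) for k, p in enumerate(polys)])
        w = compute_area_weights(grid3, cs)
        for cid in cs.ids:
            _, weights = w.weight_row(cid)
            assert weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_l_shaped_county_matches_monte_carlo(self, grid3):
        lshape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 3), (0, 3)])
        cs = CountySet([County("L", lshape, "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        exact = np.zeros(9)
        for idx, wt in w.entries["L"].items():
            exact[idx] = wt
        np.testing.assert_allclose(exact, mc_weights(lshape, grid3), atol=0.005)

    def test_county_outside_domain_flagged_empty(self, grid3):
        cs = CountySet([County("OUT", box(10, 10, 11, 11), "West", 0.0)])
        w = compute_area_weights(grid3, cs)
        assert w.entries["OUT"] == {}
        assert w.coverage_fraction["OUT"] == 0.0

    def test_partial_coverage_renormalized(self, grid3):
        # half of the county hangs off the left edge of the domain
        cs = CountySet([County("EDGE", box(-1, 0, 1, 1), "West", 0.0)])
        w = compute_area_weights(grid3, cs)
        assert w.coverage_fraction["EDGE"] == pytest.approx(0.5)
        _, weights = w.weight_row("EDGE")
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_area_polygon_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            CountySet([County("Z", box(0, 0, 0, 0), "West", 0.0)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountySet(
                [
                    County("A", box(0, 0, 1, 1), "West", 0.0),
                    County("A", box(1, 0, 2, 1), "West", 0.0),
                ]
            )


class TestAggregation:
    def test_uniform_field_returns_constant(self, grid3):
        cs = CountySet([County("A", box(0.2, 0.3, 2.5, 2.9), "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        table = aggregate_exposure(exposure_of(grid3, np.full((3, 3), 7.25)), w)
        assert table.loc[0, "aot40"] == pytest.approx(7.25, abs=1e-12)

    def test_single_cell_county_takes_cell_value(self, grid3):
        cs = CountySet([County("A", box(2, 0, 3, 1), "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        field = np.arange(9.0).reshape(3, 3)
        table = aggregate_exposure(exposure_of(grid3, field), w)
        assert table.loc[0, "aot40"] == pytest.approx(field[0, 2])

    def test_hand_weighted_mean(self):
        grid = make_grid(2, 1, 1.0)
        w = AreaWeightMatrix(grid=grid, entries={"A": {0: 0.25, 1: 0.75}},
                             coverage_fraction={"A": 1.0})
        table = aggregate_exposure(exposure_of(grid, [[4.0, 8.0]]), w)
        assert table.loc[0, "aot40"] == pytest.approx(7.0)

    def test_convexity(self, grid3, rng):
        field = rng.uniform(0, 30, (3, 3))
        cs = CountySet([County("A", box(0.4, 0.1, 2.8, 2.3), "Midwest", 1.0)])
        w = compute_area_weights(grid3, cs)
        v = aggregate_exposure(exposure_of(grid3, field), w).loc[0, "aot40"]
        idx, _ = w.weight_row("A")
        touched = field.ravel()[idx]
        assert touched.min() - 1e-12 <= v <= touched.max() + 1e-12

    def test_partition_mean_consistency(self, rng):
        """Equal-area counties tiling the domain: unweighted mean of
        county values equals the domain cell mean."""
        grid = make_grid(4, 4, 1.0)
        field = rng.uniform(0, 10, (4, 4))
        counties = CountySet(
            [
                County(f"C{r}{c}", box(2 * c, 2 * r, 2 * c + 2, 2 * r + 2), "Midwest", 1.0)
                for r in range(2)
                for c in range(2)
            ]
        )
        w = compute_area_weights(grid, counties)
        table = aggregate_exposure(exposure_of(grid, field), w)
        assert table["aot40"].mean() == pytest.approx(field.mean(), abs=1e-9)

    def test_out_of_domain_county_excluded_from_table(self, grid3):
        cs = CountySet(
            [
                County("IN", box(0, 0, 1, 1), "Midwest", 1.0),
                County("OUT", box(10, 10, 11, 11), "West", 0.0),
            ]
        )
        w = compute_area_weights(grid3, cs)
        table = aggregate_exposure(exposure_of(grid3, np.ones((3, 3))), w)
        assert table["county_id"].tolist() == ["IN"]


class TestConcentrationFirstMode:
    def test_single_cell_county_modes_agree(self, random_cube, window48):
        """For a one-cell county the two aggregation orders coincide."""
        cs = CountySet([County("A", box(1, 1, 2, 2), "Midwest", 1.0)])
        w = compute_area_weights(random_cube.grid, cs)
        from ozcrop import aot40_grid

        t1 = aggregate_exposure(aot40_grid(random_cube, window48), w)
        t2 = aggregate_concentration_first(random_cube, w, window48)
        assert t1.loc[0, "aot40"] == pytest.approx(t2.loc[0, "aot40"], abs=1e-12)

    def test_concentration_first_never_exceeds_exposure_first(self, random_cube, window48):
        """Thresholding is convex, so AOT40 of the mean series is at most
        the mean of per-cell AOT40 (Jensen)."""
        cs = CountySet([County("A", box(0, 0, 3, 3), "Midwest", 1.0)])
        w = compute_area_weights(random_cube.grid, cs)
        from ozcrop import aot40_grid

        expo_first = aggregate_exposure(aot40_grid(random_cube, window48), w).loc[0, "aot40"]
        conc_first = aggregate_concentration_first(random_cube, w, window48).loc[0, "aot40"]
        assert conc_first <= expo_first + 1e-12

    def test_matches_series_oracle(self, random_cube, window48):
        """County-average series then accumulate, done by hand."""
        cs = CountySet([County("A", box(0, 0, 3, 1.5), "Midwest", 1.0)])
        w = compute_area_weights(random_cube.grid, cs)
        idx, wt = w.weight_row("A")
        series = random_cube.values.reshape(48, -1)[:, idx] @ wt
        expected = aot40_series(series)
        got = aggregate_concentration_first(random_cube, w, window48).loc[0, "aot40"]
        assert got == pytest.approx(expected, abs=1e-12)
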