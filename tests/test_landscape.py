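"""Grid algebra: NDVI derivatives, ruggedness, resampling, extraction."""
import numpy as np
import pandas as pd
import pytest

from stepsel import landscape as land
from stepsel.errors import DataError


def grid(values, cell=500.0, x0=0.0):
    values = np.asarray(values, dtype=float)
    return land.Grid(values, x0=x0, y0=values.shape[0] * cell, cell=cell)


def series(dates, arrays):
    return land.GridSeries(dates=[pd.Timestamp(d) for d in dates],
                           grids=[grid(a) for a in arrays])


class TestDndvi:
    def test_formula(self):
        s = series(["2019-01-01", "2019-01-17"],
                   [np.full((2, 2), 0.20), np.full((2, 2), 0.30)])
        out = land.compute_dndvi(s)
        assert len(out) == 1
        assert out.dates == [pd.Timestamp("2019-01-17")]
        np.testing.assert_allclose(out.grids[0].values, 0.10)

    def test_identical_composites_give_zero(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        out = land.compute_dndvi(series(["2019-01-01", "2019-01-17"], [a, a]))
        np.testing.assert_allclose(out.grids[0].values, 0.0)

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.uniform(0, 1, (5, 6)), rng.uniform(0, 1, (5, 6))
        out = land.compute_dndvi(series(["2019-01-01", "2019-01-17"], [a, b]))
        for i in range(5):
            for j in range(6):
                assert out.grids[0].values[i, j] == b[i, j] - a[i, j]

    def test_needs_two_composites(self):
        with pytest.raises(DataError):
            land.compute_dndvi(series(["2019-01-01"], [np.zeros((2, 2))]))


class TestAndvi:
    def test_constant_series_gives_zero_anomaly(self):
        dates = ["2016-01-01", "2017-01-01", "2018-01-01", "2019-01-01"]
        s = series(dates, [np.full((3, 3), 0.2)] * 4)
        out = land.compute_andvi(s, "2016-01-01", "2019-12-31")
        for g in out.grids:
            np.testing.assert_allclose(g.values, 0.0)

    def test_slot_mean_arithmetic(self):
        # same slot (1 Jan) in three baseline years, mean 0.20; current 0.25
        dates = ["2016-01-01", "2017-01-01", "2018-01-01", "2019-01-01"]
        s = series(dates, [np.full((2, 2), v) for v in (0.15, 0.20, 0.25, 0.25)])
        out = land.compute_andvi(s, "2016-01-01", "2018-12-31")
        np.testing.assert_allclose(out.grids[-1].values, 0.25 - 0.20)

    def test_planted_offset_year_recovered(self, rng):
        # seasonal cycle identical across years; one year carries an offset
        base = rng.uniform(0.1, 0.3, (4, 4))
        offset = 0.07
        dates, arrays = [], []
        for year in (2016, 2017, 2018, 2019):
            for doy0, day in ((1, "01-01"), (17, "01-17")):
                seasonal = base + 0.05 * np.sin(doy0)
                arrays.append(seasonal + (offset if year == 2019 else 0.0))
                dates.append(f"{year}-{day}")
        s = series(sorted(dates), arrays)
        out = land.compute_andvi(s, "2016-01-01", "2018-12-31")
        for d, g in zip(out.dates, out.grids):
            expected = offset if d.year == 2019 else 0.0
            np.testing.assert_allclose(g.values, expected, atol=1e-12)

    def test_grand_mean_mode(self):
        dates = ["2016-01-01", "2016-01-17"]
        s = series(dates, [np.full((2, 2), 0.1), np.full((2, 2), 0.3)])
        out = land.compute_andvi(s, "2016-01-01", "2016-12-31", mode="grand")
        np.testing.assert_allclose(out.grids[0].values, -0.1)
        np.testing.assert_allclose(out.grids[1].values, 0.1)

    def test_scaling_linearity(self, rng):
        arrays = [rng.uniform(0, 1, (3, 3)) for _ in range(4)]
        dates = ["2016-01-01", "2017-01-01", "2018-01-01", "2019-01-01"]
        out1 = land.compute_andvi(series(dates, arrays), "2016-01-01", "2019-12-31")
        out2 = land.compute_andvi(series(dates, [3.0 * a for a in arrays]),
                                  "2016-01-01", "2019-12-31")
        for g1, g2 in zip(out1.grids, out2.grids):
            np.testing.assert_allclose(g2.values, 3.0 * g1.values, atol=1e-12)


class TestTri:
    def test_flat_grid_is_zero(self):
        out = land.compute_tri(grid(np.full((5, 5), 321.0)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_hand_computed_center(self):
        z = np.full((3, 3), 11.0)
        z[1, 1] = 10.0
        out = land.compute_tri(grid(z))
        assert out.values[1, 1] == pytest.approx(np.sqrt(8.0))

    def test_matches_neighborhood_oracle_on_ramp(self, rng):
        z = np.add.outer(np.arange(6) * 2.0, np.arange(7) * 3.0) + rng.uniform(0, 1, (6, 7))
        out = land.compute_tri(grid(z))
        for i in range(6):
            for j in range(7):
                sq = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        if 0 <= i + di < 6 and 0 <= j + dj < 7:
                            sq += (z[i + di, j + dj] - z[i, j]) ** 2
                assert out.values[i, j] == pytest.approx(np.sqrt(sq))

    def test_shift_invariance_and_scaling(self, rng):
        z = rng.uniform(100, 200, (5, 5))
        t0 = land.compute_tri(grid(z)).values
        np.testing.assert_allclose(land.compute_tri(grid(z + 57.0)).values, t0, atol=1e-9)
        np.testing.assert_allclose(land.compute_tri(grid(-2.0 * z)).values, 2.0 * t0,
                                   rtol=1e-12)


class TestBilinear:
    def test_constant_preserved(self):
        g = grid(np.full((6, 6), 4.2), cell=250.0)
        out = land.resample_bilinear(g, target_cell=500.0)
        np.testing.assert_allclose(out.values, 4.2)
        assert out.cell == 500.0

    def test_midpoint_of_four_cells(self):
        g = grid(np.array([[0.0, 0.0], [1.0, 1.0]]), cell=100.0)
        # midpoint of the 4 cell centres
        val = g.value_at(np.array([100.0]), np.array([100.0]), method="bilinear")
        assert val[0] == pytest.approx(0.5)

    def test_random_points_match_four_neighbor_oracle(self, rng):
        vals = rng.uniform(0, 10, (8, 9))
        g = grid(vals, cell=100.0)
        xs = rng.uniform(50.0, 9 * 100 - 50.0, 10)
        ys = rng.uniform(50.0, 8 * 100 - 50.0, 10)
        got = g.value_at(xs, ys, method="bilinear")
        for k in range(10):
            fc = xs[k] / 100.0 - 0.5
            fr = (8 * 100 - ys[k]) / 100.0 - 0.5
            c0, r0 = int(np.floor(fc)), int(np.floor(fr))
            tc, tr = fc - c0, fr - r0
            expected = ((1 - tr) * (1 - tc) * vals[r0, c0]
                        + (1 - tr) * tc * vals[r0, c0 + 1]
                        + tr * (1 - tc) * vals[r0 + 1, c0]
                        + tr * tc * vals[r0 + 1, c0 + 1])
            assert got[k] == pytest.approx(expected)

    def test_nodata_weights_renormalised(self):
        vals = np.array([[1.0, np.nan], [1.0, 1.0]])
        g = grid(vals, cell=100.0)
        val = g.value_at(np.array([100.0]), np.array([100.0]), method="bilinear")
        assert val[0] == pytest.approx(1.0)


class TestExtraction:
    def make_stack(self, rng, shape=(10, 10)):
        elev = grid(rng.uniform(200, 400, shape))
        andvi = series(["2019-01-01"], [rng.uniform(-0.1, 0.1, shape)])
        dndvi = series(["2019-01-01"], [rng.uniform(-0.1, 0.1, shape)])
        temp = series(["2019-01-01"], [rng.uniform(20, 40, shape)])
        return land.LandscapeStack(andvi=andvi, dndvi=dndvi, elevation=elev,
                                   tri=land.compute_tri(elev), temperature=temp)

    def strata_at(self, points, t="2019-02-01"):
        rows = []
        for sid, (x, y) in enumerate(points):
            for case in (1, 0):
                rows.append({"stratum_id": sid, "case": case, "animal_id": "a",
                             "t_start": pd.Timestamp(t), "t_end": pd.Timestamp(t),
                             "x2": x, "y2": y})
        return pd.DataFrame(rows)

    def test_cell_center_identity(self, rng):
        stack = self.make_stack(rng)
        xs, ys = stack.elevation.cell_centers()
        out = land.extract_covariates(self.strata_at([(xs[3], ys[2])]), stack)
        assert out["elevation"].iloc[0] == stack.elevation.values[2, 3]
        assert out["aNDVI"].iloc[0] == stack.andvi.grids[0].values[2, 3]

    def test_off_map_point_drops_whole_stratum(self, rng):
        stack = self.make_stack(rng)
        xs, ys = stack.elevation.cell_centers()
        out = land.extract_covariates(
            self.strata_at([(xs[1], ys[1]), (-1e6, -1e6)]), stack)
        assert set(out["stratum_id"]) == {0}
        assert len(out) == 2  # the surviving stratum keeps both rows

    def test_random_points_match_pointwise_oracle(self, rng):
        stack = self.make_stack(rng)
        pts = [(rng.uniform(0, 5000), rng.uniform(0, 5000)) for _ in range(20)]
        out = land.extract_covariates(self.strata_at(pts), stack)
        for _, row in out.iterrows():
            r, c = stack.elevation.index_of(row["x2"], row["y2"])
            assert row["elevation"] == stack.elevation.values[r, c]
            assert row["TRI"] == stack.tri.values[r, c]
            assert row["temperature"] == stack.temperature.grids[0].values[r, c]

    def test_timestamp_before_coverage_raises(self, rng):
        stack = self.make_stack(rng)
        with pytest.raises(land.CoverageError):
            land.extract_covariates(self.strata_at([(100, 100)], t="2018-12-01"), stack)


def test_ascii_grid_roundtrip(tmp_path, rng):
    vals = rng.uniform(0, 1, (4, 5))
    vals[2, 3] = np.nan
    g = grid(vals, cell=250.0, x0=1000.0)
    path = tmp_path / "g.asc"
    land.write_ascii_grid(g, path)
    back = land.read_ascii_grid(path)
    assert back.cell == g.cell and back.x0 == g.x0 and back.y0 == g.y0
    np.testing.assert_allclose(back.values, g.values, rtol=1e-5, equal_nan=True)


def test_resample_then_extract_commutes_for_constant():
    g = grid(np.full((8, 8), 7.0), cell=250.0)
    coarse = land.resample_bilinear(g, target_cell=500.0)
    pts_x, pts_y = np.array([600.0]), np.array([700.0])
    assert coarse.value_at(pts_x, pts_y)[0] == g.value_at(pts_x, pts_y)[0] == 7.0
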