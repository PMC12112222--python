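import numpy as np
import pytest

from enmkit.change import (
    CentroidShift,
    ChangeStats,
    binarize,
    centroid,
    centroid_shift,
    change_map,
    change_stats,
    compass_sector,
)
from enmkit.grids import AlignmentError, GridHeader, Raster


def raster(vals, mask=None, cellsize=0.1, yll=0.0):
    vals = np.asarray(vals, dtype=float)
    h = GridHeader(ncols=vals.shape[1], nrows=vals.shape[0], xll=0.0, yll=yll,
                   cellsize=cellsize)
    return Raster(h, vals, mask)


class TestBinarize:
    def test_strictly_above_threshold_is_suitable(self):
        b = binarize(raster([[0.23, 0.22, 0.21]]), 0.22)
        np.testing.assert_array_equal(b.values, [[1, 0, 0]])

    def test_all_zero(self):
        b = binarize(raster(np.zeros((2, 2))), 0.22)
        assert not b.values.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(raster([[1.2]]), 0.22)


class TestChangeMap:
    def test_coding(self):
        cur = raster([[0.0, 0.0, 1.0, 1.0]])
        fut = raster([[0.0, 1.0, 1.0, 0.0]])
        cm = change_map(cur, fut)
        np.testing.assert_array_equal(cm.codes.values, [[0, -1, 1, 2]])

    def test_identical_maps_have_no_dynamics(self):
        rng = np.random.default_rng(0)
        cur = raster((rng.random((5, 5)) > 0.5).astype(float))
        cm = change_map(cur, cur)
        assert set(np.unique(cm.codes.values)) <= {0.0, 1.0}

    def test_complement_maps_only_expand_and_contract(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((5, 5)) > 0.5).astype(float)
        cm = change_map(raster(vals), raster(1.0 - vals))
        assert set(np.unique(cm.codes.values)) <= {-1.0, 2.0}

    def test_header_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            change_map(raster(np.zeros((2, 2))), raster(np.zeros((2, 2)), yll=1.0))


class TestChangeStats:
    def test_accounting_identity_exact(self):
        rng = np.random.default_rng(2)
        cur = raster((rng.random((20, 20)) > 0.4).astype(float), yll=20.0)
        fut = raster((rng.random((20, 20)) > 0.6).astype(float), yll=20.0)
        st = change_stats(change_map(cur, fut))
        assert st.area_future == pytest.approx(st.area_current + st.gain - st.loss, rel=1e-12)
        assert st.stable == pytest.approx(st.area_current - st.loss, rel=1e-12)

    def test_printed_period_row_arithmetic(self):
        # glacial-period style figures: current 212.00, future 197.86,
        # gain 3.64, loss 19.27 (1e4 km^2)
        st = ChangeStats.from_areas(212.00, gain=3.64, loss=19.27, area_future=197.86)
        assert st.range_change_pct == pytest.approx(-6.67, abs=0.005)
        assert st.pct_loss == pytest.approx(9.09, abs=0.005)
        assert st.pct_gain == pytest.approx(1.72, abs=0.005)

    def test_gain_equals_loss_is_no_net_change(self):
        st = ChangeStats.from_areas(100.0, gain=5.0, loss=5.0)
        assert st.range_change_pct == 0.0

    def test_zero_current_area_rejected(self):
        cur = raster(np.zeros((3, 3)))
        fut = raster(np.ones((3, 3)))
        with pytest.raises(ValueError):
            change_stats(change_map(cur, fut))

    def test_composition_occupancy_identity(self):
        # occupancy after A->B->C equals direct A->C occupancy
        rng = np.random.default_rng(3)
        maps = [raster((rng.random((8, 8)) > 0.5).astype(float)) for _ in range(3)]
        ab = change_map(maps[0], maps[1]).codes.values
        bc = change_map(maps[1], maps[2]).codes.values
        ac = change_map(maps[0], maps[2]).codes.values
        occupied_via_b = np.isin(bc, (-1, 1))
        occupied_direct = np.isin(ac, (-1, 1))
        np.testing.assert_array_equal(occupied_via_b, occupied_direct)


class TestCentroid:
    def test_single_cell(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 1.0
        r = raster(vals)
        lon, lat = centroid(r)
        elon, elat = r.header.rowcol_to_lonlat(np.array([1]), np.array([1]))
        assert (lon, lat) == pytest.approx((elon[0], elat[0]))

    def test_symmetry_about_meridian(self):
        vals = np.zeros((1, 21))
        vals[0, 0] = vals[0, 20] = 1.0
        h = GridHeader(ncols=21, nrows=1, xll=98.95, yll=20.0, cellsize=0.1)
        lon, _ = centroid(Raster(h, vals))
        assert lon == pytest.approx(100.0)

    def test_cos_weighting_pulls_equatorward(self):
        vals = np.ones((100, 1))
        h = GridHeader(ncols=1, nrows=100, xll=0.0, yll=0.0, cellsize=0.1)
        _, lat = centroid(Raster(h, vals))  # band from 0 to 10 degrees
        assert lat < 5.0

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(4)
        vals = (rng.random((15, 15)) > 0.5).astype(float)
        r = raster(vals, yll=30.0)
        lon, lat = centroid(r)
        s_lon = s_lat = s_w = 0.0
        from enmkit.grids import cell_area_km2

        for i in range(15):
            for j in range(15):
                if vals[i, j] == 1.0:
                    (lo,), (la,) = r.header.rowcol_to_lonlat(np.array([i]), np.array([j]))
                    w = cell_area_km2(la, r.header.cellsize)
                    s_lon += w * lo
                    s_lat += w * la
                    s_w += w
        assert lon == pytest.approx(s_lon / s_w, rel=1e-12)
        assert lat == pytest.approx(s_lat / s_w, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            centroid(raster(np.zeros((3, 3))))


class TestCentroidShift:
    def test_printed_speed_arithmetic(self):
        sh = CentroidShift((0, 0), (0, 1), 138.56, 0.0, "N", 20.0, 138.56 / 20.0)
        assert sh.speed_km_per_yr == pytest.approx(6.93, abs=0.005)

    def test_zero_shift(self):
        sh = centroid_shift((100.0, 25.0), (100.0, 25.0), 20.0)
        assert sh.distance_km == 0.0
        assert sh.speed_km_per_yr == 0.0

    def test_due_north_labelled_n(self):
        sh = centroid_shift((100.0, 25.0), (100.0, 26.0), 20.0)
        assert sh.bearing_deg == pytest.approx(0.0, abs=1e-9)
        assert sh.direction == "N"
        assert sh.speed_km_per_yr * sh.years == pytest.approx(sh.distance_km, abs=1e-9)

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            centroid_shift((0, 0), (1, 1), 0.0)

    @pytest.mark.parametrize(
        "bearing,label",
        [(0, "N"), (44, "NE"), (91, "E"), (135, "SE"), (180, "S"),
         (225, "SW"), (270, "W"), (315, "NW"), (350, "N")],
    )
    def test_compass_sectors(self, bearing, label):
        assert compass_sector(bearing) == label
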