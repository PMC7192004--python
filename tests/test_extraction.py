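"""Extraction core: spectral attribution, ground reference, classes, TIN."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from canopyflux.extraction import (
    ExtractionConfig, assign_ground_reference, attribute_point_spectra,
    classify_points, ndvi, run_extraction, summarize_cell, tin_metrics)
from canopyflux.io_formats import Band, PointCloud, RasterStack, make_grid


class TestNdvi:
    @pytest.mark.parametrize("n,r,expected", [
        (0.3, 0.3, 0.0),
        (0.5, 0.1, pytest.approx(0.6667, abs=1e-4)),
        (0.5, 0.05, pytest.approx((0.5 - 0.05) / 0.55)),
    ])
    def test_values(self, n, r, expected):
        assert ndvi(n, r) == expected

    def test_zero_denominator_is_missing(self):
        assert np.isnan(ndvi(0.0, 0.0))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            ndvi(-0.1, 0.2)


class TestAttribution:
    def _stack(self):
        # 6x6 NIR at 1 m; values encode (row, col)
        data = np.arange(36, dtype=float).reshape(6, 6)
        return RasterStack({"N": Band(data / 100.0, 0.0, 6.0, 1.0, 1.0)})

    def test_point_at_pixel_center(self):
        pc = PointCloud(np.array([[2.5, 3.5, 0.0]]))  # row 2, col 2
        out = attribute_point_spectra(pc, self._stack())
        assert out["N"][0] == pytest.approx(0.14)

    def test_tie_breaks_to_lower_row_col(self):
        # x=3.0 is equidistant between cols 2 and 3 -> col 2
        # y=3.0 is equidistant between rows 2 and 3 -> row 2
        pc = PointCloud(np.array([[3.0, 3.0, 0.0]]))
        out = attribute_point_spectra(pc, self._stack())
        assert out["N"][0] == pytest.approx(0.14)

    def test_coarse_thermal_shared_by_many_points(self, rng):
        # 0.6 m thermal pixel over 0.1 m point lattice: the 36 points
        # under one thermal pixel share its value
        tr = Band(np.array([[30.0, 40.0]]), 0.0, 0.6, 0.6, 0.6)
        xs = 0.05 + 0.1 * np.arange(6)
        gx, gy = np.meshgrid(xs, xs)
        pts = PointCloud(np.column_stack([gx.ravel(), gy.ravel() - 0.6 + 0.6,
                                          np.zeros(36)]))
        pts = PointCloud(np.column_stack([gx.ravel(),
                                          np.full(36, 0.3), np.zeros(36)]))
        out = attribute_point_spectra(pts, RasterStack({"Tr": tr}))
        assert (out["Tr"] == 30.0).all()

    def test_nodata_resolved_to_nearest_valid(self):
        data = np.full((3, 3), np.nan)
        data[2, 2] = 0.7
        stack = RasterStack({"N": Band(data, 0, 3, 1, 1)})
        pc = PointCloud(np.array([[0.5, 2.5, 0.0]]))  # lands on nodata
        out = attribute_point_spectra(pc, stack)
        assert out["N"][0] == pytest.approx(0.7)
        assert not out["no_pixel"][0]

    def test_all_nodata_flags_not_drops(self):
        stack = RasterStack({"N": Band(np.full((3, 3), np.nan), 0, 3, 1, 1)})
        pc = PointCloud(np.array([[1.5, 1.5, 0.0]]))
        out = attribute_point_spectra(pc, stack)
        assert len(out) == 1 and out["no_pixel"][0]
        assert np.isnan(out["N"][0])


class TestGroundReference:
    def test_mode1_rule(self):
        cell = pd.DataFrame({"x": [0, 0], "y": [0, 1],
                             "z": [10.0, 12.1], "NDVI": [0.2, 0.8]})
        out, flags = assign_ground_reference(cell, "I", ndvi_threshold=0.6)
        assert list(out["rel_height"]) == [0.0, pytest.approx(2.1)]
        assert flags == []

    def test_mode1_fallback_all_vegetation(self):
        cell = pd.DataFrame({"x": [0, 0], "y": [0, 1],
                             "z": [10.0, 12.1], "NDVI": [0.9, 0.8]})
        out, flags = assign_ground_reference(cell, "I")
        assert "no_ground_class" in flags
        assert out["rel_height"].max() == pytest.approx(2.1)

    def test_mode2_slope_aware_mode1_not(self):
        # 10 % slope; two canopy points both 2 m above local ground
        ground = np.array([[x, 0.0, 10 + 0.1 * x]
                           for x in np.linspace(0, 10, 201)])
        tree, gz = cKDTree(ground[:, :2]), ground[:, 2]
        cell = pd.DataFrame({"x": [1.0, 9.0], "y": [0.0, 0.0],
                             "z": [12.1, 12.9], "NDVI": [0.8, 0.8]})
        m2, _ = assign_ground_reference(cell, "II", tree, gz)
        assert m2["rel_height"].to_numpy() == pytest.approx([2.0, 2.0],
                                                            abs=0.01)
        soil = pd.DataFrame({"x": [0.0], "y": [0.0], "z": [10.0],
                             "NDVI": [0.1]})
        m1, _ = assign_ground_reference(pd.concat([cell, soil]), "I")
        rel = m1["rel_height"].to_numpy()[:2]
        assert abs(rel[0] - rel[1]) > 0.5  # slope leaks into mode I heights

    def test_negative_heights_floored_and_flagged(self):
        # LiDAR ground sits above a noisy photogrammetric soil point
        ground = np.array([[0.0, 0.0, 10.0], [0.0, 1.0, 10.0]])
        tree, gz = cKDTree(ground[:, :2]), ground[:, 2]
        cell = pd.DataFrame({"x": [0, 0], "y": [0, 1],
                             "z": [9.95, 10.2], "NDVI": [0.2, 0.2]})
        out, flags = assign_ground_reference(cell, "II", tree, gz)
        assert out["rel_height"].min() == 0.0
        assert "negative_rel_height" in flags

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_ground_reference(pd.DataFrame(columns=["x", "y", "z"]),
                                    "I")


class TestClassification:
    @pytest.mark.parametrize("ndvi_val,rel,expected", [
        (0.8, 0.49, "cover_crop"),   # just below the split
        (0.8, 0.50, "vine"),         # threshold inclusive on vine side
        (0.55, 5.0, "ground"),       # NDVI rules regardless of height
        (0.61, 2.0, "vine"),
    ])
    def test_boundaries(self, ndvi_val, rel, expected):
        cell = pd.DataFrame({"NDVI": [ndvi_val], "rel_height": [rel]})
        out = classify_points(cell, ExtractionConfig())
        assert out["class"][0] == expected


class TestTinMetrics:
    def test_flat_unit_square(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        m = tin_metrics(xy, np.full(4, 2.0))
        assert m.volume == pytest.approx(2.0, abs=1e-9)
        assert m.surface_area == pytest.approx(1.0, abs=1e-9)
        assert m.projected_area == pytest.approx(1.0, abs=1e-9)

    def test_tilted_plane(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        m = tin_metrics(xy, xy[:, 0].copy())
        assert m.volume == pytest.approx(0.5, abs=1e-9)
        assert m.surface_area == pytest.approx(np.sqrt(2), abs=1e-9)
        assert m.projected_area == pytest.approx(1.0, abs=1e-9)

    def test_two_points_degenerate(self):
        m = tin_metrics(np.array([[0, 0], [1, 1]], float), np.ones(2))
        assert (m.volume, m.surface_area, m.projected_area) == (0, 0, 0)
        assert "insufficient_points" in m.flags

    def test_collinear_degenerate(self):
        xy = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        m = tin_metrics(xy, np.ones(4))
        assert m.volume == 0.0
        assert "degenerate_geometry" in m.flags

    def test_duplicate_xy_keeps_highest(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [1, 1]], float)
        h = np.array([2.0, 2.0, 2.0, 0.5, 2.0])
        m = tin_metrics(xy, h)
        assert "duplicate_xy" in m.flags
        assert m.volume == pytest.approx(2.0, abs=1e-9)

    def test_max_edge_filter_removes_bridges(self):
        # two clusters 10 m apart; without the filter the hull bridges
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1],
                       [10, 0], [11, 0], [10, 1], [11, 1]], float)
        h = np.full(8, 2.0)
        assert tin_metrics(xy, h).projected_area > 10
        m = tin_metrics(xy, h, max_tin_edge=2.0)
        assert m.projected_area == pytest.approx(2.0, abs=1e-9)

    def test_volume_matches_monte_carlo(self, rng):
        # random surface: TIN volume vs MC integral of the interpolant
        xy = rng.uniform(0, 10, size=(300, 2))
        h = 1.0 + np.sin(xy[:, 0]) * np.cos(xy[:, 1] / 2) * 0.5
        m = tin_metrics(xy, h)
        interp = LinearNDInterpolator(xy, h)
        samples = rng.uniform(0, 10, size=(100_000, 2))
        vals = interp(samples)
        inside = np.isfinite(vals)
        mc = np.nanmean(vals) * m.projected_area / (inside.mean())
        mc = np.mean(vals[inside]) * m.projected_area
        assert m.volume == pytest.approx(mc, rel=0.01)

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(0, 5, size=(200, 2))
        h = rng.uniform(0, 2, 200)
        base = tin_metrics(xy, h)
        shifted = tin_metrics(xy + [123.4, -56.7], h)
        assert shifted.volume == pytest.approx(base.volume, rel=1e-9)
        assert shifted.surface_area == pytest.approx(base.surface_area,
                                                     rel=1e-9)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rotated = tin_metrics(xy @ rot.T, h)
        assert rotated.volume == pytest.approx(base.volume, rel=0.01)
        assert rotated.projected_area == pytest.approx(base.projected_area,
                                                       rel=0.01)

    def test_surface_area_at_least_projected(self, rng):
        for _ in range(20):
            xy = rng.uniform(0, 3, size=(30, 2))
            h = rng.uniform(0, 4, 30)
            m = tin_metrics(xy, h)
            assert m.surface_area >= m.projected_area - 1e-12


class TestSummaries:
    def _cell(self):
        rows = []
        for x in np.linspace(0.1, 3.5, 10):
            for y in np.linspace(0.1, 3.5, 10):
                rows.append({"x": x, "y": y, "z": 12.2, "N": 0.5, "R": 0.05,
                             "G": 0.1, "B": 0.1, "Tr": 30.0, "NDVI": 0.8,
                             "rel_height": 2.2, "class": "vine"})
        return pd.DataFrame(rows)

    def test_vine_only_cell_v_equals_vc(self):
        cell = self._cell()
        rec = summarize_cell(cell, ExtractionConfig(), 12.96)
        for metric in ("Volume", "SArea", "Area"):
            assert rec[f"{metric}_v"] == pytest.approx(rec[f"{metric}_vc"],
                                                       abs=1e-9)
        assert rec["h_v"] == rec["h_vc"] == pytest.approx(2.2)

    def test_fc_and_wc_from_projected_area(self):
        rec = summarize_cell(self._cell(), ExtractionConfig(), 12.96)
        assert rec["f_c"] == pytest.approx(rec["Area_vc"] / 12.96)
        assert rec["w_c"] == pytest.approx(3.35 * rec["f_c"])

    def test_adding_ground_points_leaves_vine_metrics(self, rng):
        cell = self._cell()
        rec1 = summarize_cell(cell, ExtractionConfig(), 12.96)
        soil = pd.DataFrame({
            "x": rng.uniform(0, 3.6, 50), "y": rng.uniform(0, 3.6, 50),
            "z": 10.0, "N": 0.25, "R": 0.2, "G": 0.2, "B": 0.2, "Tr": 45.0,
            "NDVI": 0.11, "rel_height": 0.0, "class": "ground"})
        rec2 = summarize_cell(pd.concat([cell, soil], ignore_index=True),
                              ExtractionConfig(), 12.96)
        for col in ("Volume_vc", "SArea_vc", "Area_vc", "h_vc"):
            assert rec2[col] == pytest.approx(rec1[col], abs=1e-12)


class TestRunExtraction:
    def test_grid_shape_preserved(self, flat_scene, flat_cells_mode2):
        cells = flat_cells_mode2
        assert len(cells) == flat_scene.grid.n_cells == 100
        assert list(cells["id"]) == list(range(100))

    def test_truth_recovery_mode2(self, flat_scene, flat_cells_mode2):
        j = flat_cells_mode2.merge(flat_scene.truth, on="id",
                                   suffixes=("", "_t"))
        occupied = j["Area_vc_t"] > 0.5
        for col in ("Volume_vc", "Area_vc"):
            rel = (j[col] - j[f"{col}_t"]) / j[f"{col}_t"]
            assert np.abs(rel[occupied]).max() < 0.05
        assert np.abs(j["h_vc"] - j["h_vc_t"])[occupied].max() < 0.05

    def test_empty_grid_cell_flagged_not_dropped(self):
        pc = PointCloud(np.array([[0.5, 0.5, 1.0]]))
        grid = make_grid((0, 0, 7.2, 3.6), 3.6)
        cells = run_extraction(pc, None, grid)
        assert len(cells) == 2
        assert "empty_cell" in cells.loc[1, "flags"]

    def test_mode2_requires_ground(self):
        pc = PointCloud(np.array([[0.5, 0.5, 1.0]]))
        grid = make_grid((0, 0, 3.6, 3.6), 3.6)
        with pytest.raises(ValueError, match="ground"):
            run_extraction(pc, None, grid, ExtractionConfig(mode="II"))

    def test_crs_mismatch_rejected(self, flat_scene):
        pc = PointCloud(flat_scene.cloud.xyz, crs="EPSG:32611")
        with pytest.raises(ValueError, match="CRS"):
            run_extraction(pc, flat_scene.rasters, flat_scene.grid)
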