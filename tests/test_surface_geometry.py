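"""Surface interpolation, point-to-sheet distance, depth and thickness."""

import numpy as np
import pandas as pd
import pytest

from fibdamage.io_formats import ParticleTable
from fibdamage.surface_geometry import (
    SurfaceSheet,
    interpolate_surface,
    local_thickness,
    particle_depth,
    particle_depths,
    point_triangle_distance,
    thickness_summary,
)


def brute_force_distance(sheet: SurfaceSheet, points: np.ndarray, samples: int = 1000):
    """Independent oracle: dense sampling of the sheet surface.

    Heights are evaluated with the sheet's own piecewise-linear
    interpolation on a dense lateral raster, then the nearest sampled
    surface point is found exhaustively.
    """
    us = np.linspace(sheet.u0, sheet.u_max, samples)
    vs = np.linspace(sheet.v0, sheet.v_max, samples)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    hh = sheet.height_at(uu.ravel(), vv.ravel())
    surf = np.column_stack([uu.ravel(), vv.ravel(), hh])
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = np.sqrt(((surf - p) ** 2).sum(axis=1).min())
    return out


class TestInterpolation:
    def test_single_slice_extrudes_constant(self):
        pts = np.array([[0.0, 100.0], [200.0, 100.0]])
        sheet = interpolate_surface([(0, pts)], grid_step=10.0)
        assert np.allclose(sheet.heights, 100.0)

    def test_linear_blend_between_slices(self):
        a = np.array([[0.0, 100.0], [200.0, 100.0]])
        b = np.array([[0.0, 200.0], [200.0, 200.0]])
        sheet = interpolate_surface([(0, a), (100, b)], grid_step=10.0)
        assert sheet.height_at(100.0, 50.0) == pytest.approx(150.0)

    def test_annotated_points_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        slices = []
        for s in (0, 100, 200):
            u = np.arange(0.0, 201.0, 10.0)
            slices.append((s, np.column_stack([u, rng.uniform(80, 120, len(u))])))
        sheet = interpolate_surface(slices, grid_step=10.0)
        for s, pts in slices:
            np.testing.assert_allclose(
                sheet.height_at(pts[:, 0], np.full(len(pts), float(s))), pts[:, 1], atol=1e-9
            )

    def test_empty_and_single_point_errors(self):
        with pytest.raises(ValueError):
            interpolate_surface([], grid_step=10.0)
        with pytest.raises(ValueError, match=">= 2"):
            interpolate_surface([(0, np.array([[1.0, 2.0]]))], grid_step=10.0)


class TestParticleDepth:
    def test_planar_slab_closed_form(self, planar_sheets):
        front, back = planar_sheets
        rec = particle_depth(np.array([150.0, 150.0, 150.0]), front, back, 10.0)
        assert rec.depth_nm == pytest.approx(50.0)
        assert rec.thickness_nm == pytest.approx(200.0)
        assert rec.inside

    def test_outside_slab_sign_convention(self, planar_sheets):
        front, back = planar_sheets
        rec = particle_depth(np.array([150.0, 150.0, 90.0]), front, back, 10.0)
        assert not rec.inside
        assert rec.depth_nm == pytest.approx(10.0)

    def test_depths_sum_to_thickness_for_planar_sheets(self, planar_sheets):
        front, back = planar_sheets
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.uniform(0, 290, 50), rng.uniform(0, 290, 50), rng.uniform(100, 300, 50)]
        )
        d_front = front.nearest_distance(pts)
        d_back = back.nearest_distance(pts)
        np.testing.assert_allclose(d_front + d_back, 200.0, atol=1e-9)

    def test_matches_brute_force_on_tilted_rough_sheet(self):
        rng = np.random.default_rng(5)
        u = np.arange(0.0, 300.0, 10.0)
        v = np.arange(0.0, 300.0, 10.0)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        heights = 150.0 + np.tan(np.deg2rad(10.0)) * uu + 2.0 * np.sin(uu / 25) * np.cos(vv / 30)
        sheet = SurfaceSheet(heights, 0.0, 0.0, 10.0)
        pts = np.column_stack(
            [rng.uniform(20, 270, 60), rng.uniform(20, 270, 60), rng.uniform(100, 300, 60)]
        )
        fast = sheet.nearest_distance(pts)
        brute = brute_force_distance(sheet, pts, samples=700)
        # dense sampling can only overestimate, by at most its raster pitch
        assert np.all(brute >= fast - 1e-9)
        np.testing.assert_allclose(fast, brute, atol=1.0)

    def test_lateral_outside_flagged(self, planar_sheets):
        front, back = planar_sheets
        rec = particle_depth(np.array([-50.0, 150.0, 150.0]), front, back, 10.0)
        assert not rec.in_bounds
        assert np.isnan(rec.depth_nm)

    def test_point_triangle_distance_regions(self):
        a, b, c = np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
        # face, vertex, edge cases
        assert point_triangle_distance(np.array([0.2, 0.2, 1.0]), a, b, c) == pytest.approx(1.0)
        assert point_triangle_distance(np.array([-1.0, -1.0, 0.0]), a, b, c) == pytest.approx(
            np.sqrt(2)
        )
        assert point_triangle_distance(np.array([0.5, -1.0, 0.0]), a, b, c) == pytest.approx(1.0)


class TestThickness:
    def test_planar_and_tilted_thickness(self, planar_sheets):
        front, back = planar_sheets
        assert local_thickness(front, back, (150.0, 150.0), 10.0) == pytest.approx(200.0)
        u = np.arange(0.0, 300.0, 10.0)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        tilted_back = SurfaceSheet(300.0 + 0.1 * uu, 0.0, 0.0, 10.0, role="back")
        got = local_thickness(front, tilted_back, (100.0, 50.0), 10.0)
        assert got == pytest.approx((300.0 + 10.0 - 100.0))

    def test_crossing_sheets_flagged(self, planar_sheets):
        front, back = planar_sheets
        assert np.isnan(local_thickness(back, front, (150.0, 150.0), 10.0))

    def test_summary_closed_form(self):
        df = pd.DataFrame(
            {
                "tomogram_id": ["a", "b", "c"],
                "thickness_nm": [100.0, 200.0, 300.0],
            }
        )
        s = thickness_summary(df)
        assert s["mean_nm"] == pytest.approx(200.0)
        assert s["median_nm"] == pytest.approx(200.0)
        assert s["sd_nm"] == pytest.approx(100.0)

    def test_single_tomogram_sd_zero_flagged(self):
        df = pd.DataFrame({"tomogram_id": ["a"], "thickness_nm": [150.0]})
        s = thickness_summary(df)
        assert s["sd_nm"] == 0.0
        assert not s["sd_defined"]

    def test_no_valid_records_raises(self):
        df = pd.DataFrame({"tomogram_id": ["a"], "thickness_nm": [np.nan]})
        with pytest.raises(ValueError):
            thickness_summary(df)


class TestParticleDepthsTable:
    def test_batch_matches_planar_truth(self, planar_sheets):
        front, back = planar_sheets
        rng = np.random.default_rng(1)
        n = 200
        z = rng.uniform(100, 300, n)
        df = pd.DataFrame(
            {
                "particle_id": [f"p{i}" for i in range(n)],
                "tomogram_id": "t0",
                "x": rng.uniform(0, 290, n),
                "y": rng.uniform(0, 290, n),
                "z": z,
            }
        )
        table = ParticleTable(df, 10.0)
        out = particle_depths(table, {"t0": (front, back)})
        expected = np.minimum(z - 100.0, 300.0 - z)
        np.testing.assert_allclose(out["depth_nm"], expected, atol=1e-9)
        assert out["inside"].all()
        np.testing.assert_allclose(out["thickness_nm"], 200.0)
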