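import math

import numpy as np
import pytest

from phenotraits.morphometry import (
    InstanceRecord,
    MORPH_TRAIT_NAMES,
    aggregate_morphology,
    convex_hull_area,
    instance_area,
    instance_perimeter,
    measure_instance,
    measure_instances,
    min_area_rect,
    orthogonal_bbox,
    roundness,
)


def square_map(n=10, pad=5):
    m = np.zeros((n + 2 * pad, n + 2 * pad), dtype=np.int32)
    m[pad : pad + n, pad : pad + n] = 1
    return m


def disk_map(r, pad=10):
    size = 2 * (r + pad) + 1
    yy, xx = np.mgrid[:size, :size] - (r + pad)
    return ((yy**2 + xx**2) <= r * r).astype(np.int32)


def brute_force_min_rect(points, step_deg=0.01):
    """Rotation-search oracle for the minimum-area enclosing rectangle.

    Global scan at ``step_deg``, then a local refinement pass around the
    best angle so the oracle's own grid error is negligible.
    """
    pts = np.asarray(points, dtype=float)

    def scan(angles):
        best = (np.inf, 0.0, 0.0, 0.0)
        for ang in angles:
            t = math.radians(ang)
            R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
            q = pts @ R.T
            ext = q.max(axis=0) - q.min(axis=0)
            area = ext[0] * ext[1]
            if area < best[0]:
                best = (area, max(ext), min(ext), ang)
        return best

    area, length, width, ang = scan(np.arange(0.0, 90.0, step_deg))
    area, length, width, _ = scan(
        np.arange(ang - step_deg, ang + step_deg, step_deg / 1000.0)
    )
    return area, length, width


class TestArea:
    def test_filled_square(self):
        assert instance_area(square_map(10), 1) == 100

    def test_single_pixel(self):
        m = np.zeros((5, 5), np.int32)
        m[2, 2] = 1
        assert instance_area(m, 1) == 1

    def test_digital_disk_equals_exhaustive_center_count(self):
        r = 20
        m = disk_map(r)
        expected = sum(
            1
            for y in range(m.shape[0])
            for x in range(m.shape[1])
            if (y - (r + 10)) ** 2 + (x - (r + 10)) ** 2 <= r * r
        )
        assert instance_area(m, 1) == expected

    def test_absent_label_raises(self):
        with pytest.raises(ValueError, match="label"):
            instance_area(square_map(), 7)


class TestPerimeter:
    @pytest.mark.parametrize("n", [3, 10, 25])
    def test_square_is_4_n_minus_1(self, n):
        assert instance_perimeter(square_map(n), 1) == pytest.approx(4 * (n - 1))

    def test_single_pixel_degenerate(self):
        m = np.zeros((3, 3), np.int32)
        m[1, 1] = 1
        assert instance_perimeter(m, 1) == 0.0

    def test_one_pixel_line_is_out_and_back(self):
        m = np.zeros((3, 8), np.int32)
        m[1, 1:7] = 1
        assert instance_perimeter(m, 1) == pytest.approx(2 * 5)

    def test_digital_disk_tracks_circumference(self):
        # an 8-chain through pixel centers overestimates a smooth contour by
        # ~5% at this radius; the band reflects the convention, not noise
        p = instance_perimeter(disk_map(50), 1)
        assert p == pytest.approx(2 * math.pi * 50, rel=0.06)
        assert p > 2 * math.pi * 50  # the chain never undershoots at this size

    def test_disconnected_instance_measures_largest_component(self):
        m = np.zeros((20, 20), np.int32)
        m[2:12, 2:12] = 1  # 10x10 block
        m[16, 16] = 1  # stray pixel, same label
        with pytest.warns(UserWarning, match="largest"):
            assert instance_perimeter(m, 1) == pytest.approx(36)


class TestRoundness:
    def test_ideal_circle_is_one(self):
        r = 7.3
        assert roundness(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)

    def test_ideal_square_is_pi_over_4(self):
        s = 11.0
        assert roundness(s * s, 4 * s) == pytest.approx(math.pi / 4)

    def test_digital_disk_within_digitization_band(self):
        rec = measure_instance(disk_map(50), 1)
        assert 0.9 <= rec.roundness <= 1.1

    def test_zero_perimeter_gives_nan(self):
        assert math.isnan(roundness(1.0, 0.0))


class TestBoundingGeometry:
    def test_axis_aligned_rectangle_extents(self):
        m = np.zeros((40, 40), np.int32)
        m[5:15, 5:25] = 1  # 10 rows x 20 cols
        assert orthogonal_bbox(m, 1) == (20, 10)

    def test_single_pixel_extents(self):
        m = np.zeros((5, 5), np.int32)
        m[3, 1] = 1
        assert orthogonal_bbox(m, 1) == (1, 1)

    def test_rotated_bar_has_nearly_equal_extents(self):
        # a 30x6 bar at 45 deg: both axis-aligned extents ~ (30+6)/sqrt(2) ~ 26
        t = math.radians(45)
        yy, xx = np.mgrid[:64, :64] - 32.0
        u = xx * math.cos(t) + yy * math.sin(t)
        v = -xx * math.sin(t) + yy * math.cos(t)
        m = ((np.abs(u) <= 15) & (np.abs(v) <= 3)).astype(np.int32)
        length, width = orthogonal_bbox(m, 1)
        rows, cols = np.nonzero(m)
        assert length == max(np.ptp(rows), np.ptp(cols)) + 1
        assert width == min(np.ptp(rows), np.ptp(cols)) + 1
        assert abs(length - width) <= 2 and 24 <= length <= 28


class TestMinAreaRect:
    def test_axis_aligned_square(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        length, width, area = min_area_rect(pts)
        assert (length, width, area) == (10, 10, 100)

    def test_rotated_rectangle_recovers_true_sides(self):
        t = math.radians(37)
        base = np.array([[0, 0], [30, 0], [30, 10], [0, 10]], float)
        R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        length, width, area = min_area_rect(base @ R.T)
        assert length == pytest.approx(30, abs=1e-6)
        assert width == pytest.approx(10, abs=1e-6)
        assert area == pytest.approx(300, abs=1e-6)

    def test_triangle_matches_brute_force(self):
        pts = np.array([[0, 0], [4, 0], [0, 3]], float)
        _, _, area = min_area_rect(pts)
        b_area, _, _ = brute_force_min_rect(pts)
        assert area == pytest.approx(b_area, rel=1e-4)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [3, 3]], float)
        length, width, area = min_area_rect(pts)
        assert length == pytest.approx(3 * math.sqrt(2))
        assert width == 0 and area == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_random_convex_polygons_match_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(rng.integers(4, 12), 2))
        _, _, area = min_area_rect(pts)
        b_area, _, _ = brute_force_min_rect(pts, step_deg=0.01)
        assert area <= b_area + 1e-9  # exact method can only beat the grid
        assert area == pytest.approx(b_area, rel=1e-4)


def gift_wrap_hull_area(points):
    """Gift-wrapping (Jarvis march) + shoelace oracle."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, float), axis=0)]
    if len(pts) < 3:
        return 0.0
    start = min(pts)
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = (cand[0] - cur[0]) * (p[1] - cur[1]) - (cand[1] - cur[1]) * (
                p[0] - cur[0]
            )
            d_c = (cand[0] - cur[0]) ** 2 + (cand[1] - cur[1]) ** 2
            d_p = (p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2
            if cross < 0 or (cross == 0 and d_p > d_c):
                cand = p
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestConvexHullArea:
    def test_square_shoelace(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert convex_hull_area(pts) == pytest.approx(100)

    def test_collinear_is_zero(self):
        assert convex_hull_area(np.array([[0, 0], [2, 2], [5, 5]], float)) == 0.0

    def test_random_cloud_matches_gift_wrapping(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, size=(50, 2))
        assert convex_hull_area(pts) == pytest.approx(gift_wrap_hull_area(pts))


class TestAggregate:
    def _two_leaf_records(self):
        m = np.zeros((60, 60), np.int32)
        m[5:15, 5:15] = 1  # area 100
        m[30:50, 30:40] = 2  # area 200
        return measure_instances(m)

    def test_two_leaves_closed_form(self):
        out = aggregate_morphology(self._two_leaf_records())
        assert out["Total Leaf Number"] == 2
        assert out["Total Leaf Area"] == 300
        assert out["Average Leaf Area"] == 150
        assert out["Maximum Leaf Area"] == 200
        assert out["STD_Area"] == pytest.approx(50)  # population SD
        assert out["CV_Area"] == pytest.approx(1 / 3)

    def test_single_leaf_degenerate_dispersion(self):
        m = square_map(10)
        out = aggregate_morphology(measure_instances(m))
        assert out["STD_Area"] == 0 and out["CV_Area"] == 0
        assert out["Average Leaf Area"] == out["Maximum Leaf Area"]

    def test_empty_scene(self):
        out = aggregate_morphology([])
        assert out["Total Leaf Number"] == 0
        assert out["Total Leaf Area"] == 0
        assert math.isnan(out["Average Perimeter"])
        assert len(out) == 35

    def test_full_trait_set_and_order(self):
        out = aggregate_morphology(self._two_leaf_records())
        assert tuple(out) == MORPH_TRAIT_NAMES

    def test_generated_rosette_matches_truth_exactly(self, rosette_scene):
        image, truth = rosette_scene
        out = aggregate_morphology(measure_instances(truth.label_map))
        assert out["Total Leaf Number"] == truth.count == 8
        assert out["Total Leaf Area"] == truth.visible_areas.sum()

    def test_ratio_trait_definitions(self):
        recs = self._two_leaf_records()
        out = aggregate_morphology(recs)
        areas = np.array([r.area for r in recs])
        mareas = np.array([r.mbb_area for r in recs])
        peris = np.array([r.perimeter for r in recs])
        assert out["Average Area/MBB_Area"] == pytest.approx(
            np.mean(areas / mareas)
        )
        assert out["Average Perimeter/Area"] == pytest.approx(
            peris.mean() / areas.mean()
        )
        assert out["STD_Perimeter/Area"] == pytest.approx(
            np.std(peris) / areas.mean()
        )
        assert out["STD_Area/MBB_Area"] == pytest.approx(
            np.std(areas) / mareas.mean()
        )


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_geometry_chain_on_random_shapes(self, seed):
        from conftest import random_instance_map

        rng = np.random.default_rng(seed)
        m = random_instance_map(rng, n_instances=3)
        for rec in measure_instances(m):
            assert rec.area <= rec.hull_area + 1e-9
            assert rec.hull_area <= rec.mbb_area + 1e-9
            assert rec.mbb_area <= rec.ortho_length * rec.ortho_width + 1e-9
            assert rec.mbb_length >= rec.mbb_width > 0
            assert rec.area >= 1

    def test_aggregates_permutation_invariant(self):
        m = np.zeros((60, 60), np.int32)
        m[5:15, 5:15] = 1
        m[30:50, 30:40] = 2
        m[20:26, 48:56] = 3
        recs = measure_instances(m)
        a = aggregate_morphology(recs)
        b = aggregate_morphology(recs[::-1])
        for k in a:
            assert a[k] == pytest.approx(b[k], nan_ok=True)

    def test_translation_leaves_traits_unchanged(self, rosette_scene):
        _, truth = rosette_scene
        m = truth.label_map
        shifted = np.roll(np.roll(m, 13, axis=0), -9, axis=1)
        # the rolled scene keeps all organs intact (border margin is ample)
        a = aggregate_morphology(measure_instances(m))
        b = aggregate_morphology(measure_instances(shifted))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9, nan_ok=True)

    def test_rot90_preserves_rigid_traits_exactly(self, rosette_scene):
        _, truth = rosette_scene
        m = truth.label_map
        a = aggregate_morphology(measure_instances(m))
        b = aggregate_morphology(measure_instances(np.rot90(m).copy()))
        for k in (
            "Total Leaf Area",
            "Average Perimeter",
            "Average Length",
            "Average Width",
            "Average MBB_Area",
            "Convex Hull Leaf Area",
        ):
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_cv_times_average_recovers_std(self):
        m = np.zeros((60, 60), np.int32)
        m[5:15, 5:15] = 1
        m[30:50, 30:40] = 2
        out = aggregate_morphology(measure_instances(m))
        for x in ("Perimeter", "Area", "Length", "Width"):
            avg = out[f"Average {x}" if x != "Area" else "Average Leaf Area"]
            std = out[f"STD_{x}"]
            cv = out[f"CV_{x}"]
            assert cv * avg == pytest.approx(std)
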