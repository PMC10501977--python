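"""Geometry: lines, signed distances, overlap ratio and flexion angle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneeqc.geometry import (
    CoincidentPointsError,
    DegenerateGeometryError,
    GeometryError,
    KeypointSet,
    Line2D,
    Point2D,
    View,
    compute_qc,
    fit_line,
    flexion_angle,
    overlap_ratio,
    signed_distance,
)


def transform_set(kps: KeypointSet, angle_deg: float, scale: float, tx: float, ty: float) -> KeypointSet:
    """Apply a similarity transform (rotation, uniform scale, translation)."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    pts = {}
    for lab, kp in kps.keypoints.items():
        x, y = kp.position.x, kp.position.y
        pts[lab] = (scale * (c * x - s * y) + tx, scale * (s * x + c * y) + ty)
    return KeypointSet.from_points(kps.view, pts)


class TestFitLine:
    def test_axis_aligned(self):
        line = fit_line(Point2D(0, 0), Point2D(0, 100))
        assert line.direction == (0.0, 1.0)
        assert line.anchor == Point2D(0, 0)

    def test_diagonal_direction_normalized(self):
        line = fit_line(Point2D(1, 1), Point2D(3, 3))
        assert line.direction == pytest.approx((math.sqrt(2) / 2, math.sqrt(2) / 2))

    def test_coincident_points_rejected(self):
        with pytest.raises(CoincidentPointsError):
            fit_line(Point2D(2, 5), Point2D(2, 5))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(GeometryError):
            Line2D(anchor=Point2D(0, 0), direction=(1.0, 1.0))


class TestSignedDistance:
    y_axis = Line2D(anchor=Point2D(0, 0), direction=(0.0, 1.0))

    def test_positive_on_reference_side(self):
        assert signed_distance(Point2D(10, 50), self.y_axis, Point2D(1, 0)) == pytest.approx(10.0)

    def test_negative_on_opposite_side(self):
        assert signed_distance(Point2D(-6, 50), self.y_axis, Point2D(1, 0)) == pytest.approx(-6.0)

    def test_reference_on_line_rejected(self):
        with pytest.raises(GeometryError):
            signed_distance(Point2D(1, 1), self.y_axis, Point2D(0, 7))

    def test_matches_bruteforce_nearest_point(self):
        """|signed distance| equals a dense nearest-point search on the line."""
        line = fit_line(Point2D(0, 0), Point2D(0.6, 0.8))
        p, ref = Point2D(4, 3), Point2D(4, 0)
        ts = np.linspace(-50, 50, 100_000)
        px = ts * line.direction[0]
        py = ts * line.direction[1]
        brute = np.min(np.hypot(px - p.x, py - p.y))
        s = signed_distance(p, line, ref)
        assert abs(abs(s) - brute) < 1e-3
        assert s == pytest.approx(1.4, abs=1e-12)  # |4*0.8 - 3*0.6|, ref side positive


class TestOverlapRatio:
    def test_hand_computed_example(self, ap_keypoints):
        assert overlap_ratio(ap_keypoints) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "e_xy,expected",
        [((10, 50), 0.0), ((-6, 50), 1.0)],
        ids=["E_at_C_no_overlap", "E_at_D_full_overlap"],
    )
    def test_boundaries(self, ap_keypoints, e_xy, expected):
        pts = {lab: (kp.position.x, kp.position.y) for lab, kp in ap_keypoints.keypoints.items()}
        pts["E"] = e_xy
        assert overlap_ratio(KeypointSet.from_points(View.AP, pts)) == pytest.approx(expected)

    def test_zero_width_head_rejected(self):
        kps = KeypointSet.from_points(
            View.AP, {"A": (0, 0), "B": (0, 100), "C": (5, 50), "D": (5, 60), "E": (5, 55)}
        )
        with pytest.raises(DegenerateGeometryError):
            overlap_ratio(kps)

    def test_monotone_in_e_position(self, ap_keypoints):
        """Ratio is nondecreasing as E sweeps from C toward D."""
        pts = {lab: (kp.position.x, kp.position.y) for lab, kp in ap_keypoints.keypoints.items()}
        values = []
        for ex in np.linspace(10, -6, 33):
            pts["E"] = (ex, 50.0)
            values.append(overlap_ratio(KeypointSet.from_points(View.AP, pts)))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(0.0) and values[-1] == pytest.approx(1.0)

    def test_similarity_invariance(self, ap_keypoints, rng):
        """Invariant under 100 random rotations + scalings + translations."""
        base = overlap_ratio(ap_keypoints)
        for _ in range(100):
            t = transform_set(
                ap_keypoints,
                angle_deg=rng.uniform(0, 360),
                scale=rng.uniform(0.1, 10),
                tx=rng.uniform(-500, 500),
                ty=rng.uniform(-500, 500),
            )
            assert abs(overlap_ratio(t) - base) < 1e-9

    @given(ratio=st.floats(0.0, 1.0), angle=st.floats(0, 360), scale=st.floats(0.2, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_constructed_ratio_recovered_under_transform(self, ratio, angle, scale):
        """A set built to have a given ratio keeps it under any similarity map."""
        e_x = 10 - 16 * ratio  # Sc=10, Sd=-6
        kps = KeypointSet.from_points(
            View.AP, {"A": (0, 0), "B": (0, 100), "C": (10, 50), "D": (-6, 50), "E": (e_x, 50)}
        )
        t = transform_set(kps, angle, scale, 40, -17)
        assert overlap_ratio(t) == pytest.approx(ratio, abs=1e-9)


class TestFlexionAngle:
    def test_collinear_extended_limb_is_180(self, lat_keypoints):
        assert flexion_angle(lat_keypoints) == pytest.approx(180.0)

    def test_perpendicular_shafts_are_90(self, lat_keypoints):
        pts = {lab: (kp.position.x, kp.position.y) for lab, kp in lat_keypoints.keypoints.items()}
        pts["I"] = (100, 120)
        assert flexion_angle(KeypointSet.from_points(View.LAT, pts)) == pytest.approx(90.0)

    def test_thirty_degree_bend(self, lat_keypoints):
        pts = {lab: (kp.position.x, kp.position.y) for lab, kp in lat_keypoints.keypoints.items()}
        pts["I"] = (50, 120 + 100 * math.cos(math.radians(30)))
        assert flexion_angle(KeypointSet.from_points(View.LAT, pts)) == pytest.approx(150.0, abs=0.01)

    def test_coincident_shaft_points_rejected(self, lat_keypoints):
        pts = {lab: (kp.position.x, kp.position.y) for lab, kp in lat_keypoints.keypoints.items()}
        pts["G"] = pts["F"]
        with pytest.raises(CoincidentPointsError):
            flexion_angle(KeypointSet.from_points(View.LAT, pts))

    def test_similarity_and_mirror_invariance(self, lat_keypoints, rng):
        base = flexion_angle(lat_keypoints)
        for _ in range(100):
            t = transform_set(
                lat_keypoints,
                angle_deg=rng.uniform(0, 360),
                scale=rng.uniform(0.1, 10),
                tx=rng.uniform(-500, 500),
                ty=rng.uniform(-500, 500),
            )
            assert abs(flexion_angle(t) - base) < 1e-9
        mirrored = KeypointSet.from_points(
            View.LAT,
            {lab: (-kp.position.x, kp.position.y) for lab, kp in lat_keypoints.keypoints.items()},
        )
        assert flexion_angle(mirrored) == pytest.approx(base)


class TestComputeQC:
    def test_ap_composition(self, ap_keypoints):
        res = compute_qc(ap_keypoints)
        assert res.view is View.AP
        assert res.overlap_ratio == pytest.approx(0.5)
        assert res.flexion_angle_deg is None and res.normalized_flexion is None

    def test_lat_composition(self, lat_keypoints):
        res = compute_qc(lat_keypoints)
        assert res.overlap_ratio == pytest.approx(0.5)
        assert res.flexion_angle_deg == pytest.approx(180.0)
        assert res.normalized_flexion == pytest.approx(1.0)

    def test_missing_required_keypoint_rejected(self, ap_keypoints):
        broken = KeypointSet(
            view=View.AP,
            keypoints={k: v for k, v in ap_keypoints.keypoints.items() if k != "C"},
        )
        with pytest.raises(GeometryError):
            compute_qc(broken)

    def test_out_of_range_ratio_clamped_and_flagged(self):
        # E beyond D: raw ratio > 1
        kps = KeypointSet.from_points(
            View.AP, {"A": (0, 0), "B": (0, 100), "C": (10, 50), "D": (-6, 50), "E": (-9, 50)}
        )
        res = compute_qc(kps)
        assert res.overlap_ratio == 1.0
        assert res.ratio_clamped
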