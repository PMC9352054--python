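import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cionaswim import features as ft
from cionaswim import synthetic_data as sd
from cionaswim.io_model import TrackRecording


def _rigid_transform(points, angle, shift):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return points @ R.T + shift


class TestDetectNeck:
    def test_sharp_drop_profile(self):
        w = np.empty(49)
        w[:12] = 10.0
        w[12:16] = np.linspace(10, 3, 4)
        w[16:] = 3.0
        # brute-force oracle: argmin of first differences of the 5-pt-smoothed profile
        smooth = np.convolve(w, np.ones(5) / 5, mode="same")
        oracle = 4 + int(np.argmin(np.diff(smooth)[4:23]))
        found = ft.detect_neck(w)
        assert found == oracle
        assert 12 <= found <= 13

    def test_monotone_increasing_widths_error(self):
        with pytest.raises(ft.NeckDetectionError):
            ft.detect_neck(np.linspace(1, 10, 49))

    def test_all_equal_widths_error(self):
        with pytest.raises(ft.NeckDetectionError):
            ft.detect_neck(np.full(49, 5.0))

    @pytest.mark.parametrize("planted", [6, 9, 12, 15, 18, 20])
    def test_simulator_constriction_recovered(self, planted):
        w = sd.width_template(planted)
        assert abs(ft.detect_neck(w) - planted) <= 1


class TestPartition:
    def test_neck_12_blocks(self):
        p = ft.partition_segments(12)
        assert p.ranges[0] == (0, 11)  # head points 0..10
        assert p.ranges[1] == (11, 14)  # neck 11..13
        sizes = [b - a for a, b in p.ranges[2:]]
        assert sizes == [7, 7, 7, 7, 7]

    def test_boundary_neck_4(self):
        p = ft.partition_segments(4)
        assert p.ranges[0] == (0, 3)  # 3 head points

    @given(st.integers(min_value=4, max_value=22))
    def test_cover_and_disjoint(self, neck):
        p = ft.partition_segments(neck)
        covered = []
        for a, b in p.ranges:
            covered.extend(range(a, b))
        assert covered == list(range(49))
        assert p.ranges[1] == (neck - 1, neck + 2)
        for (a, b), m in zip(p.ranges, p.midpoints):
            assert a <= m < b

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ft.partition_segments(3)


class TestCurvature:
    def test_straight_line_zero(self, straight_skeleton):
        assert np.max(np.abs(ft.curvature(straight_skeleton))) < 1e-10

    def test_circle_arc(self):
        # 49 points on a 100 px radius circle spanning 90 degrees
        theta = np.linspace(0, np.pi / 2, 49)
        pts = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        k = ft.curvature(pts)
        interior = np.abs(k[10:-10])
        np.testing.assert_allclose(interior, 0.01, rtol=0.05)

    def test_rigid_motion_invariance(self, rng):
        pts = sd.skeleton_from_curvature(rng.normal(scale=0.01, size=49), 0.3, np.zeros(2))
        k0 = ft.curvature(pts)
        k1 = ft.curvature(_rigid_transform(pts, 1.1, np.array([50.0, -20.0])))
        np.testing.assert_allclose(k0, k1, atol=1e-8)


class TestRelativeTangentAngles:
    def test_straight_all_zero(self, straight_skeleton):
        p = ft.partition_segments(12)
        np.testing.assert_allclose(ft.relative_tangent_angles(straight_skeleton, p), 0.0, atol=1e-12)

    def test_l_shape_tail_perpendicular(self):
        p = ft.partition_segments(12)
        pts = np.zeros((49, 2))
        pts[:25, 0] = np.arange(25)
        pts[25:, 0] = 24.0
        pts[25:, 1] = np.arange(1, 25)
        rta = ft.relative_tangent_angles(pts, p)
        assert abs(abs(rta[-1]) - np.pi / 2) < 1e-9

    def test_rotation_invariance(self, rng):
        pts = sd.skeleton_from_curvature(rng.normal(scale=0.01, size=49), 0.0, np.zeros(2))
        p = ft.partition_segments(12)
        r0 = ft.relative_tangent_angles(pts, p)
        r1 = ft.relative_tangent_angles(_rigid_transform(pts, 2.5, np.array([7.0, 7.0])), p)
        np.testing.assert_allclose(r0, r1, atol=1e-8)

    def test_coincident_endpoints_error(self):
        p = ft.partition_segments(12)
        pts = np.zeros((49, 2))
        with pytest.raises(ValueError):
            ft.relative_tangent_angles(pts, p)


class TestQuirkiness:
    def test_straight_is_one(self, straight_skeleton):
        assert ft.quirkiness(straight_skeleton) == pytest.approx(1.0)

    def test_square_extents_zero(self):
        # square lattice: equal extents along any principal-axis choice
        g = np.linspace(0, 1, 7)
        pts = np.array([(x, y) for x in g for y in g])
        assert ft.quirkiness(pts) == pytest.approx(0.0, abs=1e-6)

    def test_semicircle(self):
        theta = np.linspace(0, np.pi, 49)
        r = 10.0
        pts = r * np.column_stack([np.cos(theta), np.sin(theta)])
        assert ft.quirkiness(pts) == pytest.approx(np.sqrt(3) / 2, abs=1e-3)

    def test_rotation_invariance(self, rng):
        pts = sd.skeleton_from_curvature(rng.normal(scale=0.02, size=49), 0.0, np.zeros(2))
        q0 = ft.quirkiness(pts)
        q1 = ft.quirkiness(_rigid_transform(pts, 0.77, np.array([3.0, -9.0])))
        assert q0 == pytest.approx(q1, abs=1e-8)

    def test_coincident_points_error(self):
        with pytest.raises(ValueError):
            ft.quirkiness(np.zeros((49, 2)))


class TestSegmentSpeeds:
    def _static_recording(self, T=10):
        pts = np.tile(np.cumsum(np.ones((49, 2)), axis=0), (T, 1, 1))
        return TrackRecording(
            points=pts,
            widths=np.tile(sd.width_template(12), (T, 1)),
            valid=np.ones(T, bool),
            frame_index=np.arange(T),
        )

    def test_stationary_zero(self):
        rec = self._static_recording()
        s = ft.segment_speeds(rec, ft.partition_segments(12))
        np.testing.assert_allclose(s[1:], 0.0)
        assert np.isnan(s[0]).all()

    def test_rigid_translation_three_four_five(self):
        rec = self._static_recording()
        shift = np.arange(10)[:, None, None] * np.array([3.0, 4.0])
        rec.points = rec.points + shift
        s = ft.segment_speeds(rec, ft.partition_segments(12))
        np.testing.assert_allclose(s[1:], 5.0)

    def test_gap_masks_both_sides(self):
        rec = self._static_recording()
        rec.valid[4] = False
        s = ft.segment_speeds(rec, ft.partition_segments(12))
        assert np.isnan(s[4]).all() and np.isnan(s[5]).all()
        assert np.isfinite(s[3]).all() and np.isfinite(s[6]).all()

    def test_unit_conversion(self):
        # px/frame -> um/s is a pure scale: um_per_pixel * fps
        assert 5.0 * 11.5605 * 30 == pytest.approx(1734.075)


class TestHeadRigidity:
    def test_straight_skeleton_zero_deviation(self, straight_skeleton):
        rec = TrackRecording(
            points=straight_skeleton[None],
            widths=sd.width_template(12)[None],
            valid=np.array([True]),
            frame_index=np.array([0]),
        )
        prof = ft.head_rigidity_profile(rec, ft.partition_segments(12))
        np.testing.assert_allclose(prof["deviation"], 0.0, atol=1e-9)

    def test_simulator_head_stiffer_than_tail(self, sim_recording):
        rec, gt, cfg = sim_recording
        prof = ft.head_rigidity_profile(rec)
        med = prof.groupby("region")["deviation"].median()
        assert med["head"] < med["tail"]

    def test_rotation_invariance(self, sim_recording):
        rec, gt, cfg = sim_recording
        part = ft.partition_recording(rec)
        prof0 = ft.head_rigidity_profile(rec, part)
        rot = TrackRecording(
            points=np.stack([_rigid_transform(p, 0.9, np.array([10.0, 4.0])) for p in rec.points]),
            widths=rec.widths,
            valid=rec.valid,
            frame_index=rec.frame_index,
        )
        prof1 = ft.head_rigidity_profile(rot, part)
        np.testing.assert_allclose(prof0["deviation"], prof1["deviation"], atol=1e-8)


class TestFeaturePanel:
    def test_panel_has_25_named_columns_and_no_holes(self, sim_recording):
        rec, gt, cfg = sim_recording
        from cionaswim import eigenposture as ep

        kappa = ft.curvature(rec.points)
        basis = ep.fit_eigenbasis(kappa)
        ec = ep.project(kappa, basis)
        panel = ft.feature_panel(rec, ec)
        assert list(panel.columns[2:]) == ft.PANEL_COLUMNS
        assert len(ft.PANEL_COLUMNS) == 25
        body = panel[ft.PANEL_COLUMNS].to_numpy()[rec.valid]
        # speeds are undefined on the first frame only
        assert np.isfinite(body[1:]).all()
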