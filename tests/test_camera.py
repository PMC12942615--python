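"""Pinhole observation model: projection, calibration, interpolation."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitval import camera as cam
from gaitval import kinematics as kin


@pytest.fixture
def simple_camera():
    """Camera at origin looking down +x, f = 1000 px, c = (960, 540)."""
    R = np.array([[0.0, 0.0, -1.0], [0.0, -1.0, 0.0], [1.0, 0.0, 0.0]])
    return cam.CameraModel(position=(0, 0, 0), orientation=R, focal_px=1000.0)


class TestProjectPoint:
    def test_optical_axis_maps_to_principal_point(self, simple_camera):
        u, v = cam.project_point(simple_camera, (2.0, 0.0, 0.0))
        assert (u, v) == pytest.approx((960.0, 540.0))

    def test_lateral_offset_closed_form(self, simple_camera):
        # 0.5 m lateral offset at 2 m depth with f = 1000 -> 250 px
        u, v = cam.project_point(simple_camera, (2.0, 0.0, -0.5))
        assert abs(u - 960.0) == pytest.approx(250.0)

    def test_doubling_depth_halves_offset(self, simple_camera):
        u1, _ = cam.project_point(simple_camera, (2.0, 0.0, -0.5))
        u2, _ = cam.project_point(simple_camera, (4.0, 0.0, -0.5))
        assert abs(u2 - 960.0) == pytest.approx(abs(u1 - 960.0) / 2.0)

    def test_behind_camera_rejected(self, simple_camera):
        with pytest.raises(cam.BehindCameraError):
            cam.project_point(simple_camera, (-1.0, 0.0, 0.0))

    def test_invariant_to_joint_rigid_transform(self, simple_camera):
        """Moving camera and scene together leaves pixels unchanged."""
        rng = np.random.default_rng(0)
        pts = rng.normal([3.0, 0.0, 0.0], 0.4, size=(20, 3))
        base = cam.project_point(simple_camera, pts)
        for _ in range(10):
            Q = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3)
            moved = cam.CameraModel(
                position=tuple(Q @ np.asarray(simple_camera.position) + t),
                orientation=simple_camera.orientation @ Q.T,
                focal_px=simple_camera.focal_px)
            assert np.abs(cam.project_point(moved, pts @ Q.T + t) - base).max() < 1e-6


class TestProjectRecording:
    def test_static_pose_constant_pixels(self, anthro):
        from gaitval import synthetic as sg
        pat = sg.GaitPattern(gait_speed=1.0, step_length=0.6,
                             joint_profiles={}, pelvis_vertical_amplitude=0.0,
                             pelvis_lateral_amplitude=0.0, pelvis_obliquity_deg=0.0)
        rec = sg.build_recording(pat, anthro, duration=4.0)
        rec = dataclasses.replace(rec, keypoints3d=np.repeat(
            rec.keypoints3d[:1], rec.n_frames, axis=0))
        stream = cam.project_recording(cam.lateral_camera(), rec)
        assert np.abs(np.diff(stream.data[..., :2], axis=0)).max() < 1e-12

    def test_frontal_depth_decreases_and_hips_magnify(self, recording):
        camera = cam.frontal_camera()
        stream = cam.project_recording(camera, recording, view="frontal")
        depth = camera.to_camera(recording.keypoint("mid_hip"))[:, 2]
        assert np.all(np.diff(depth) < 0)
        gap = np.abs(stream.positions("hip_L")[:, 0] - stream.positions("hip_R")[:, 0])
        # smooth the oscillatory sway component before the monotone check
        trend = np.convolve(gap, np.ones(120) / 120, mode="valid")
        assert trend[-1] > trend[0]
        assert np.all(np.diff(trend) > -0.05)

    def test_out_of_frame_flagged_not_clipped(self, recording):
        stream = cam.project_recording(cam.lateral_camera(), recording)
        assert stream.frame_valid.any() and not stream.frame_valid.all()
        # flagged frames keep their (out-of-range) projected coordinates
        bad = ~stream.frame_valid
        uv = stream.data[bad][..., :2]
        w, h = cam.DEFAULT_RESOLUTION
        assert ((uv[..., 0] < 0) | (uv[..., 0] > w)
                | (uv[..., 1] < 0) | (uv[..., 1] > h)).any()

    def test_lateral_heel_tracks_3d_projection(self, recording, ortho_lateral):
        stream = cam.project_recording(ortho_lateral, recording)
        per_point = cam.project_point(ortho_lateral, recording.keypoint("heel_R"))
        assert np.abs(stream.positions("heel_R") - per_point).max() < 1e-9


class TestCalibration:
    def test_force_plate_constants(self):
        scale = cam.calibrate_scale(460.0)
        assert scale.meters_per_pixel == pytest.approx(0.001)
        assert cam.calibrate_scale(920.0).meters_per_pixel == pytest.approx(0.0005)

    def test_invalid_pixel_length(self):
        with pytest.raises(ValueError):
            cam.calibrate_scale(0.0)

    def test_depth_mismatch_error_follows_similar_triangles(self):
        """A reference at depth d and a target at depth d + delta give a
        relative length error of exactly delta / (d + delta)."""
        camera = cam.lateral_camera(distance=3.0, along_x=0.0)
        ref = np.array([[-0.23, 0.0, 0.0], [0.23, 0.0, 0.0]])
        uv = cam.project_point(camera, ref)
        scale = cam.calibrate_scale(float(np.hypot(*(uv[1] - uv[0]))))
        errors = []
        for delta in (0.15, 0.3, 0.6):
            tgt = ref - [0.0, 0.0, delta]
            uv2 = cam.project_point(camera, tgt)
            meas = np.hypot(*(uv2[1] - uv2[0])) * scale.meters_per_pixel
            rel = abs(meas - 0.46) / 0.46
            assert rel == pytest.approx(delta / (3.0 + delta), rel=1e-9)
            errors.append(rel)
        assert errors == sorted(errors)

    def test_orthographic_limit_of_perspective(self, sagittal_recording):
        """Planar sagittal angles from a 50 m perspective camera agree
        with the true angles to < 0.1 deg."""
        far = cam.lateral_camera(distance=50.0, focal_px=1500.0 * 50.0 / 3.0)
        fro = cam.frontal_camera(distance_beyond=50.0,
                                 focal_px=1500.0 * 55.0 / 7.0)
        planar = kin.sml_joint_angles(
            cam.project_recording(far, sagittal_recording),
            cam.project_recording(fro, sagittal_recording))
        for joint in ("hip", "knee", "ankle"):
            truth = sagittal_recording.true_angles[(joint, "sagittal", "R")].values
            est = planar[(joint, "sagittal", "R")].values
            assert np.abs(est - truth).max() < 0.1, joint


class TestPixelNoise:
    def test_zero_sigma_identity(self, recording, ortho_lateral):
        stream = cam.project_recording(ortho_lateral, recording)
        assert np.array_equal(cam.add_pixel_noise(stream, 0.0, seed=1).data,
                              stream.data)

    def test_seeded_reproducibility(self, recording, ortho_lateral):
        stream = cam.project_recording(ortho_lateral, recording)
        a = cam.add_pixel_noise(stream, 2.0, seed=9)
        b = cam.add_pixel_noise(stream, 2.0, seed=9)
        assert np.array_equal(a.data, b.data)


class TestInterpolateLowConfidence:
    def _stream(self, data):
        return cam.KeypointStream(view="lateral", sample_rate=60.0,
                                  keypoint_names=("p",), data=data)

    def test_all_confident_is_noop(self):
        data = np.random.default_rng(0).normal(size=(10, 1, 3))
        data[..., 2] = 1.0
        out = cam.interpolate_low_confidence(self._stream(data), 0.5, 3)
        assert np.array_equal(out.data, data)

    def test_single_dropout_becomes_neighbor_midpoint(self):
        data = np.zeros((3, 1, 3))
        data[0, 0] = [0.0, 0.0, 0.8]
        data[1, 0] = [99.0, 99.0, 0.1]
        data[2, 0] = [2.0, 4.0, 0.8]
        out = cam.interpolate_low_confidence(self._stream(data), 0.5, 2)
        assert out.data[1, 0, :2] == pytest.approx([1.0, 2.0])
        assert out.data[0, 0, :2] == pytest.approx([0.0, 0.0])

    def test_matches_bruteforce_weighted_mean(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(40, 2, 3))
        data[..., 2] = rng.uniform(0, 1, size=(40, 2))
        thr, win = 0.4, 4
        out = cam.interpolate_low_confidence(self._stream(data), thr, win)
        for j in range(2):
            for i in range(40):
                conf = data[:, j, 2]
                if conf[i] >= thr:
                    assert np.array_equal(out.data[i, j], data[i, j])
                    continue
                nb = [k for k in range(max(0, i - win), min(40, i + win + 1))
                      if conf[k] >= thr]
                if not nb:
                    continue
                w = conf[nb]
                expect = (w[:, None] * data[nb, j, :2]).sum(0) / w.sum()
                assert out.data[i, j, :2] == pytest.approx(expect)

    def test_window_without_confident_frames_holds_nearest(self):
        data = np.zeros((7, 1, 3))
        data[:, 0, 0] = np.arange(7)
        data[:, 0, 2] = [0.9, 0.0, 0.0, 0.0, 0.0, 0.0, 0.9]
        out = cam.interpolate_low_confidence(self._stream(data), 0.5, 1)
        # middle frame has no confident neighbor in its window: value is
        # held from the nearest confident frame and flagged with conf 0
        assert out.data[3, 0, 0] in (0.0, 6.0)
        assert out.data[3, 0, 2] == 0.0

    def test_invalid_arguments(self):
        data = np.zeros((3, 1, 3))
        with pytest.raises(ValueError):
            cam.interpolate_low_confidence(self._stream(data), 1.5, 3)
        with pytest.raises(ValueError):
            cam.interpolate_low_confidence(self._stream(data), 0.5, 0)
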