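"""Event detection, cycle segmentation, spatiotemporal parameters."""

import numpy as np
import pytest

from gaitval import camera as cam
from gaitval import events as ev
from gaitval import synthetic as sg
from conftest import match_events


def _detect3d(recording, side):
    return ev.detect_events_3d(recording.keypoint(f"heel_{side}"),
                               recording.keypoint(f"big_toe_{side}"),
                               recording.keypoint("mid_hip"),
                               recording.sample_rate, side=side)


class TestDetect3D:
    def test_noise_free_recovery_within_one_frame(self, recording):
        for side in ("L", "R"):
            errors = match_events(_detect3d(recording, side),
                                  [e for e in recording.true_events
                                   if e.side == side])
            assert errors and max(errors) < 1.0

    def test_stationary_subject_yields_no_events(self):
        still = np.tile([1.0, 0.1, 0.0], (300, 1))
        out = ev.detect_events_3d(still, still, still + [0, 0.8, 0], 60.0)
        assert out == []

    def test_time_reversal_swaps_roles(self, recording):
        """Reversing time turns anterior extrema into posterior ones:
        detected heel strikes of the reversed walk match reversed toe-off
        roles (the reversed heel-anterior peaks sit where posterior peaks
        were)."""
        heel = recording.keypoint("heel_R")[::-1]
        toe = recording.keypoint("big_toe_R")[::-1]
        pelvis = recording.keypoint("mid_hip")[::-1]
        fwd = _detect3d(recording, "R")
        rev = ev.detect_events_3d(heel, toe, pelvis, 60.0, side="R")
        n = recording.n_frames - 1
        fwd_hs = sorted(n / 60.0 - e.time for e in fwd if e.type == ev.HEEL_STRIKE)
        # reversed-time heel signal = -(forward heel anterior signal):
        # its maxima are the forward signal's minima; but reversing x
        # direction too makes HS peaks of the reversed walk line up with
        # forward HS peaks mirrored in time
        rev_hs = sorted(e.time for e in rev if e.type == ev.HEEL_STRIKE)
        for t in rev_hs:
            assert min(abs(t - u) for u in fwd_hs) < 0.5

    def test_single_cycle_insufficient(self, pattern, anthro):
        rec = sg.build_recording(pattern, anthro, duration=3.5)
        short = {k: v[:80] for k, v in (("heel", rec.keypoint("heel_R")),
                                        ("toe", rec.keypoint("big_toe_R")),
                                        ("mid", rec.keypoint("mid_hip")))}
        with pytest.raises(ValueError):
            ev.detect_events_3d(short["heel"], short["toe"], short["mid"], 60.0)


class TestDetect2D:
    def test_orthographic_recovery_within_one_frame(self, recording,
                                                    ortho_lateral, ortho_scale):
        stream = cam.project_recording(ortho_lateral, recording)
        for side in ("L", "R"):
            det = ev.detect_events_2d(stream, ortho_scale, side=side)
            errors = match_events(det, [e for e in recording.true_events
                                        if e.side == side])
            assert errors and max(errors) < 1.0

    def test_constant_keypoints_no_events(self, ortho_scale):
        names = tuple(sg.KEYPOINT_NAMES)
        data = np.ones((200, len(names), 3))
        stream = cam.KeypointStream("lateral", 60.0, names, data)
        assert ev.detect_events_2d(stream, ortho_scale, side="R") == []

    def test_missing_scale_rejected(self, recording, ortho_lateral):
        stream = cam.project_recording(ortho_lateral, recording)
        with pytest.raises(ValueError):
            ev.detect_events_2d(stream, None)

    def test_noise_degrades_timing_monotonically(self, recording,
                                                 ortho_lateral, ortho_scale):
        stream = cam.project_recording(ortho_lateral, recording)
        medians = []
        for sigma in (0.0, 3.0, 8.0):
            errs = []
            for rep in range(10):
                noisy = cam.add_pixel_noise(stream, sigma, seed=100 + rep)
                det = ev.detect_events_2d(noisy, ortho_scale, side="R",
                                          expected_stride_s=recording.pattern.stride_time)
                errs += match_events(det, [e for e in recording.true_events
                                           if e.side == "R"])
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]


class TestCyclesAndParams:
    def test_segment_cycles_pairs(self):
        evs = [ev.GaitEvent("R", ev.HEEL_STRIKE, t, int(t * 60), "truth")
               for t in (1.0, 2.1, 3.2)]
        assert ev.segment_cycles(evs, "R") == [(1.0, 2.1), (2.1, 3.2)]

    def test_segment_cycles_requires_two_strikes(self):
        evs = [ev.GaitEvent("R", ev.HEEL_STRIKE, 1.0, 60, "truth")]
        with pytest.raises(ValueError):
            ev.segment_cycles(evs, "R")

    def test_representative_cycle_crosses_walkway_center(self):
        t = np.linspace(0, 9, 540)
        x = t * 1.1  # crosses x = 5 m at t ~ 4.55
        cycles = [(0.5, 1.6), (4.0, 5.1), (7.5, 8.6)]
        assert ev.representative_cycle(cycles, x, t, center_x=5.0) == (4.0, 5.1)

    def test_true_events_reproduce_true_params(self, recording):
        heel_x = {}
        for side in ("L", "R"):
            hs = recording.events_of(side, ev.HEEL_STRIKE)
            heel_x[side] = ev.positions_at_events(
                recording.true_events, recording.keypoint(f"heel_{side}")[:, 0],
                recording.time, side)
        p = ev.spatiotemporal_params(recording.true_events, heel_x,
                                     side="R", cycle_index=1)
        t = recording.true_params
        assert p.stance_time == pytest.approx(t.stance_time, abs=1e-9)
        assert p.swing_time == pytest.approx(t.swing_time, abs=1e-9)
        assert p.stride_length == pytest.approx(t.stride_length, rel=1e-3)
        assert p.step_length == pytest.approx(t.step_length, rel=2e-3)

    def test_symmetric_step_is_half_stride(self, recording):
        heel_x = {}
        for side in ("L", "R"):
            heel_x[side] = ev.positions_at_events(
                recording.true_events, recording.keypoint(f"heel_{side}")[:, 0],
                recording.time, side)
        p = ev.spatiotemporal_params(recording.true_events, heel_x,
                                     side="R", cycle_index=1)
        assert p.step_length == pytest.approx(p.stride_length / 2.0, rel=2e-3)

    def test_stance_plus_swing_equals_stride(self, recording):
        events, heel_x = [], {}
        for side in ("L", "R"):
            det = _detect3d(recording, side)
            events += det
            heel_x[side] = ev.positions_at_events(
                det, recording.keypoint(f"heel_{side}")[:, 0],
                recording.time, side)
        hs = sorted(e.time for e in events
                    if e.side == "R" and e.type == ev.HEEL_STRIKE)
        p = ev.spatiotemporal_params(events, heel_x, side="R", cycle_index=0)
        assert p.stance_time + p.swing_time == pytest.approx(hs[1] - hs[0])

    def test_detected_params_recover_reference_pace(self, recording):
        events, heel_x = [], {}
        for side in ("L", "R"):
            det = _detect3d(recording, side)
            events += det
            heel_x[side] = ev.positions_at_events(
                det, recording.keypoint(f"heel_{side}")[:, 0],
                recording.time, side)
        p = ev.spatiotemporal_params(events, heel_x, side="R", cycle_index=1)
        assert p.gait_speed == pytest.approx(1.091, rel=0.02)

    def test_negative_phase_rejected(self):
        with pytest.raises(ValueError):
            ev.SpatiotemporalParams(1.0, 0.6, 1.2, -0.1, 0.4)

    def test_swing_more_sensitive_than_stance_to_jitter(self, recording):
        """Fixed event-time jitter inflates the relative error of the
        shorter phase (swing) more than that of stance."""
        rng = np.random.default_rng(11)
        t = recording.true_params
        hs, to = 0.0, t.stance_time
        next_hs = t.stride_time
        stance_rel, swing_rel = [], []
        for _ in range(100):
            j = rng.normal(0.0, 1.0 / 60.0, size=3)
            stance = (to + j[1]) - (hs + j[0])
            swing = (next_hs + j[2]) - (to + j[1])
            stance_rel.append(abs(stance - t.stance_time) / t.stance_time)
            swing_rel.append(abs(swing - t.swing_time) / t.swing_time)
        assert np.mean(swing_rel) >= np.mean(stance_rel)


class TestAlignment:
    def _hs(self, times, side="R"):
        return [ev.GaitEvent(side, ev.HEEL_STRIKE, t, int(round(t * 60)), "x")
                for t in times]

    def test_identical_lists_align_at_zero(self):
        evs = self._hs([1.0, 2.0])
        assert ev.align_streams(evs, evs) == 0.0

    def test_constant_shift_recovered(self):
        ref = self._hs([1.0, 2.0])
        other = self._hs([1.25, 2.25])
        assert ev.align_streams(ref, other) == pytest.approx(-0.25)

    def test_requires_right_heel_strike(self):
        with pytest.raises(ValueError):
            ev.align_streams(self._hs([1.0], side="L"), self._hs([2.0]))

    def test_injected_audio_offset_recovered(self, recording, ortho_lateral,
                                             ortho_scale):
        """A known device-clock offset, injected on the monocular stream,
        is recovered by right-heel-strike alignment to within a frame."""
        offset = 0.12
        stream = cam.project_recording(ortho_lateral, recording)
        det = ev.detect_events_2d(stream, ortho_scale, side="R")
        shifted = [e.shifted(-offset, 60.0) for e in det]
        ref = [e for e in recording.true_events if e.side == "R"]
        recovered = ev.align_streams(ref, shifted)
        assert abs(recovered - offset) < 1.0 / 60.0
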