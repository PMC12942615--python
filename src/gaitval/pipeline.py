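"""End-to-end emulated study: simulate, capture, measure, compare.

For each synthetic subject and trial, one ground-truth walk is measured
by three arms that mirror the study design:

* **MB** (marker-based reference): segment transforms plus a small
  configurable perturbation — the gold standard is modeled as a system
  with known sub-degree error, not as perfect truth;
* **M-ML** (multi-camera markerless): the same transform route with its
  own, larger noise level;
* **S-ML** (single-camera markerless): two monocular pinhole views
  (lateral and frontal), pixel jitter with confidence scores,
  confidence-based interpolation, force-plate pixel calibration, planar
  angles and image-plane event detection, plus an emulated audio-clock
  offset removed by right-heel-strike alignment.

Each arm contributes one representative gait cycle per trial (the cycle
nearest the walkway center, standing in for the force-plate crossing);
pooled cycles feed ICC(2,1) and RMSE agreement statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import camera as cam
from . import events as ev
from . import kinematics as kin
from .agreement import AgreementReport, build_report
from .synthetic import (AnthropometricProfile, GroundTruthRecording,
                        build_recording, default_pattern)

__all__ = ["StudyConfig", "NoiseLevels", "NOISE_PRESETS", "GaitCycleResult",
           "run_study", "measure_recording", "perturb_transforms"]

SYSTEMS = ("S-ML", "M-ML", "MB")


@dataclass(frozen=True)
class NoiseLevels:
    """Per-system measurement noise magnitudes."""

    mb_rot_sigma_deg: float = 0.5     # MB segment-pose angular jitter
    mb_pos_sigma_m: float = 0.002     # MB marker position jitter
    mml_rot_sigma_deg: float = 2.0    # M-ML pose jitter (markerless 3D)
    mml_pos_sigma_m: float = 0.005
    sml_pixel_sigma: float = 3.0      # S-ML pose-estimation jitter (px)


NOISE_PRESETS = {
    "ideal": NoiseLevels(0.0, 0.0, 0.0, 0.0, 0.0),
    "bench": NoiseLevels(0.1, 0.0005, 0.5, 0.002, 1.0),
    "realistic": NoiseLevels(),
}


@dataclass(frozen=True)
class StudyConfig:
    """Study-level configuration; defaults emulate the reference design
    (16 subjects, 2 trials each, 60 Hz, ~10 m walkway)."""

    n_subjects: int = 16
    trials_per_subject: int = 2
    duration_s: float = 7.0
    sample_rate: float = 60.0
    height_mean_m: float = 1.6925
    height_sd_m: float = 0.0919
    speed_mean_mps: float = 1.091
    speed_sd_mps: float = 0.093
    step_mean_m: float = 0.609
    step_sd_m: float = 0.048
    noise: NoiseLevels | str = "realistic"
    lateral_distance_m: float = 3.0
    frontal_beyond_m: float = 2.0
    # wide-angle smartphone intrinsics: keeps even tall subjects fully
    # in the lateral frame across several strides at 3 m
    focal_px: float = 1200.0
    orthographic: bool = False
    audio_offset_s: float = 0.12
    confidence_threshold: float = 0.3
    interp_window: int = 5
    seed: int = 0
    reference: str = "MB"
    self_comparison: bool = False
    rmse_aggregation: str = "per_cycle"

    def noise_levels(self) -> NoiseLevels:
        if isinstance(self.noise, str):
            return NOISE_PRESETS[self.noise]
        return self.noise

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        if isinstance(self.noise, str) and self.noise not in NOISE_PRESETS:
            raise ValueError(f"unknown noise preset {self.noise!r}")

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        noise = raw.get("noise", "realistic")
        if isinstance(noise, dict):
            raw["noise"] = NoiseLevels(**noise)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        raw = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GaitCycleResult:
    """One representative gait cycle as measured by one system."""

    subject: int
    trial: int
    system: str
    cycle: tuple[float, float]            # [t_HS, t_nextHS] on the common clock
    curves: dict                          # (joint, plane) -> 101-point array
    params: ev.SpatiotemporalParams
    events: list[ev.GaitEvent] = field(default_factory=list)
    clock_offset: float = 0.0             # applied right-HS alignment shift


def perturb_transforms(stream: kin.SegmentTransformStream, rot_sigma_deg: float,
                       pos_sigma_m: float, rng: np.random.Generator
                       ) -> kin.SegmentTransformStream:
    """Multiplicative small-rotation and additive translation jitter."""
    out = {}
    for name, T in stream.transforms.items():
        T = T.copy()
        n = T.shape[0]
        if rot_sigma_deg > 0:
            rotvec = rng.normal(0.0, np.deg2rad(rot_sigma_deg), size=(n, 3))
            T[:, :3, :3] = T[:, :3, :3] @ _rotvec_to_matrix(rotvec)
        if pos_sigma_m > 0:
            T[:, :3, 3] += rng.normal(0.0, pos_sigma_m, size=(n, 3))
        out[name] = T
    return kin.SegmentTransformStream(out, stream.sample_rate)


def _rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues formula, vectorized over leading axes."""
    theta = np.linalg.norm(rotvec, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(theta > 1e-12, rotvec / theta, 0.0)
    t = theta[..., 0]
    K = np.zeros(rotvec.shape[:-1] + (3, 3))
    K[..., 0, 1], K[..., 0, 2] = -axis[..., 2], axis[..., 1]
    K[..., 1, 0], K[..., 1, 2] = axis[..., 2], -axis[..., 0]
    K[..., 2, 0], K[..., 2, 1] = -axis[..., 1], axis[..., 0]
    st = np.sin(t)[..., None, None]
    ct = (1 - np.cos(t))[..., None, None]
    return np.eye(3) + st * K + ct * (K @ K)


# ---------------------------------------------------------------------------
# measurement arms

def _pick_cycle(events, heel_x, cycles, rep_index):
    """Spatiotemporal parameters for the representative cycle, falling
    back to the nearest complete cycle when events are missing in it
    (possible under heavy keypoint noise)."""
    order = sorted(range(len(cycles)), key=lambda i: abs(i - rep_index))
    last_err = None
    for i in order:
        try:
            return ev.spatiotemporal_params(events, heel_x, side="R",
                                            cycle_index=i), i
        except ValueError as exc:
            last_err = exc
    raise ValueError(f"no complete gait cycle in recording: {last_err}")


def _detect_3d(keypoints3d_of, sample_rate, expected_stride):
    events, heel_x = [], {}
    for side in ("L", "R"):
        det = ev.detect_events_3d(keypoints3d_of(f"heel_{side}"),
                                  keypoints3d_of(f"big_toe_{side}"),
                                  keypoints3d_of("mid_hip"),
                                  sample_rate, side=side,
                                  expected_stride_s=expected_stride)
        events += det
        n = keypoints3d_of(f"heel_{side}").shape[0]
        t = np.arange(n) / sample_rate
        heel_x[side] = ev.positions_at_events(
            det, keypoints3d_of(f"heel_{side}")[:, 0], t, side)
    return events, heel_x


def _transform_arm(recording: GroundTruthRecording, system: str,
                   rot_sigma: float, pos_sigma: float,
                   rng: np.random.Generator, subject: int, trial: int
                   ) -> GaitCycleResult:
    """MB / M-ML: Cardan angles from (perturbed) transforms, 3D events."""
    from .synthetic import add_keypoint_noise

    stream = perturb_transforms(recording.segment_transforms,
                                rot_sigma, pos_sigma, rng)
    noisy = add_keypoint_noise(recording, pos_sigma,
                               seed=int(rng.integers(2 ** 31)))
    angles = kin.transform_joint_angles(stream)
    expected = recording.pattern.stride_time
    events, heel_x = _detect_3d(noisy.keypoint, recording.sample_rate, expected)

    cycles = ev.segment_cycles(events, "R")
    t = recording.time
    rep = ev.representative_cycle(cycles, noisy.keypoint("mid_hip")[:, 0], t,
                                  center_x=recording.walkway_length / 2)
    params, idx = _pick_cycle(events, heel_x, cycles, cycles.index(rep))
    rep = cycles[idx]
    curves = {(j, p): kin.time_normalize(angles[(j, p, "R")], rep)
              for j, p in kin.OUTCOME_PLANES}
    return GaitCycleResult(subject, trial, system, rep, curves, params, events)


def _sml_arm(recording: GroundTruthRecording, config: StudyConfig,
             rng: np.random.Generator, subject: int, trial: int
             ) -> GaitCycleResult:
    """S-ML: two monocular views, pixel pipeline, 2D events, alignment later."""
    noise = config.noise_levels()
    mode = "orthographic" if config.orthographic else "perspective"
    lateral_cam = cam.lateral_camera(distance=config.lateral_distance_m,
                                     along_x=recording.walkway_length / 2,
                                     focal_px=config.focal_px, mode=mode)
    frontal_cam = cam.frontal_camera(distance_beyond=config.frontal_beyond_m,
                                     walkway_length=recording.walkway_length,
                                     focal_px=config.focal_px, mode=mode)
    lateral = cam.project_recording(lateral_cam, recording, view="lateral")
    frontal = cam.project_recording(frontal_cam, recording, view="frontal")

    if noise.sml_pixel_sigma > 0:
        lateral = cam.add_pixel_noise(lateral, noise.sml_pixel_sigma,
                                      seed=int(rng.integers(2 ** 31)))
        frontal = cam.add_pixel_noise(frontal, noise.sml_pixel_sigma,
                                      seed=int(rng.integers(2 ** 31)))
        lateral = cam.interpolate_low_confidence(
            lateral, config.confidence_threshold, config.interp_window)
        frontal = cam.interpolate_low_confidence(
            frontal, config.confidence_threshold, config.interp_window)

    # crop the lateral stream to the span where the subject is in frame
    a, b = _largest_valid_run(lateral.frame_valid)
    lateral = lateral.cropped(a, b)
    frontal_c = frontal.cropped(a, b)

    # force-plate calibration: the reference length lies flat at the
    # walkway center, at the walkway midline's depth
    plate_mid = np.array([[recording.walkway_length / 2 - 0.23, 0.0, 0.0],
                          [recording.walkway_length / 2 + 0.23, 0.0, 0.0]])
    uv = cam.project_point(lateral_cam, plate_mid)
    scale = cam.calibrate_scale(float(np.hypot(*(uv[1] - uv[0]))))

    angles = kin.sml_joint_angles(lateral, frontal_c)
    expected = recording.pattern.stride_time
    events = []
    heel_x = {}
    for side in ("L", "R"):
        det = ev.detect_events_2d(lateral, scale, side=side,
                                  expected_stride_s=expected)
        events += det
        n = lateral.n_frames
        t = np.arange(n) / lateral.sample_rate
        u = lateral.positions(f"heel_{side}")[:, 0]
        x_m = (u - lateral_cam.principal_point[0]) * scale.meters_per_pixel \
            + lateral_cam.position[0]
        heel_x[side] = ev.positions_at_events(det, x_m, t, side)

    # device clock: the smartphone pair lags the lab clock by the audio
    # offset; detection happens in device time, alignment removes it
    events = [e.shifted(-config.audio_offset_s, lateral.sample_rate)
              for e in events]

    cycles = ev.segment_cycles(events, "R")
    u_mid = lateral.positions("mid_hip")[:, 0]
    x_mid = (u_mid - lateral_cam.principal_point[0]) * scale.meters_per_pixel \
        + lateral_cam.position[0]
    t_dev = np.arange(lateral.n_frames) / lateral.sample_rate - config.audio_offset_s
    rep = ev.representative_cycle(cycles, x_mid, t_dev,
                                  center_x=recording.walkway_length / 2)
    params, idx = _pick_cycle(events, heel_x, cycles, cycles.index(rep))
    rep = cycles[idx]

    # angle series run on the cropped lateral clock (device time)
    curves = {}
    for j, p in kin.OUTCOME_PLANES:
        series = angles[(j, p, "R")]
        series = kin.JointAngleSeries(j, p, "R", series.values,
                                      series.sample_rate)
        cyc_local = (rep[0] + config.audio_offset_s,
                     rep[1] + config.audio_offset_s)
        curves[(j, p)] = kin.time_normalize(series, cyc_local)
    return GaitCycleResult(subject, trial, "S-ML", rep, curves, params, events)


def _largest_valid_run(valid: np.ndarray) -> tuple[int, int]:
    best, cur, start, best_start = 0, 0, 0, 0
    for i, v in enumerate(valid):
        if v:
            if cur == 0:
                start = i
            cur += 1
            if cur > best:
                best, best_start = cur, start
        else:
            cur = 0
    if best == 0:
        raise ValueError("subject never fully inside the camera frame")
    return best_start, best_start + best


def measure_recording(recording: GroundTruthRecording, config: StudyConfig,
                      rng: np.random.Generator, subject: int, trial: int
                      ) -> dict[str, GaitCycleResult]:
    """All measurement arms for one trial, aligned at the right heel strike."""
    noise = config.noise_levels()
    arms: dict[str, GaitCycleResult] = {}
    arms["MB"] = _transform_arm(recording, "MB", noise.mb_rot_sigma_deg,
                                noise.mb_pos_sigma_m, rng, subject, trial)
    if config.self_comparison:
        arms["MB2"] = dataclasses.replace(arms["MB"], system="MB2")
    else:
        arms["M-ML"] = _transform_arm(recording, "M-ML", noise.mml_rot_sigma_deg,
                                      noise.mml_pos_sigma_m, rng, subject, trial)
        arms["S-ML"] = _sml_arm(recording, config, rng, subject, trial)
        # temporal alignment at the right heel strike nearest the S-ML
        # representative cycle (the monocular views cover a shorter span)
        offset = _align_sml(arms["MB"], arms["S-ML"])
        sml = arms["S-ML"]
        arms["S-ML"] = dataclasses.replace(
            sml, clock_offset=offset,
            cycle=(sml.cycle[0] + offset, sml.cycle[1] + offset),
            events=[e.shifted(offset, config.sample_rate) for e in sml.events])
    return arms


def _align_sml(mb: GaitCycleResult, sml: GaitCycleResult) -> float:
    """Right-HS alignment robust to the shorter monocular coverage.

    A plain first-to-first rule assumes both systems saw the same first
    cycle; the lateral camera's field of view starts later, so the
    S-ML anchor is its first right heel strike and the MB anchor is the
    MB right heel strike closest to it once the audio-scale offset is
    taken out modulo one stride.
    """
    sml_hs = [e.time for e in sml.events
              if e.side == "R" and e.type == ev.HEEL_STRIKE]
    mb_hs = [e.time for e in mb.events
             if e.side == "R" and e.type == ev.HEEL_STRIKE]
    if not sml_hs or not mb_hs:
        raise ValueError("both systems need a right heel strike to align")
    anchor = sml_hs[0]
    nearest = min(mb_hs, key=lambda t: abs(t - anchor))
    return nearest - anchor


def run_study(config: StudyConfig) -> tuple[AgreementReport, list[GaitCycleResult]]:
    """Simulate and measure the whole cohort; return report and pooled cycles.

    Deterministic under a fixed ``config.seed``: every random draw comes
    from a seed sequence spawned per subject and trial.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    pooled: dict[str, list[GaitCycleResult]] = {}
    all_results: list[GaitCycleResult] = []
    for s in range(config.n_subjects):
        subj_rng = np.random.default_rng(subject_seeds[s])
        height = subj_rng.normal(config.height_mean_m, config.height_sd_m)
        speed = subj_rng.normal(config.speed_mean_mps, config.speed_sd_mps)
        step = subj_rng.normal(config.step_mean_m, config.step_sd_m)
        anthro = AnthropometricProfile.from_height(height)
        pattern = default_pattern(anthro, gait_speed=speed, step_length=step)
        trial_seeds = subject_seeds[s].spawn(config.trials_per_subject)
        for trial in range(config.trials_per_subject):
            trial_rng = np.random.default_rng(trial_seeds[trial])
            phase = 0.2 + 0.25 * trial_rng.random()
            rec = build_recording(pattern, anthro, duration=config.duration_s,
                                  sample_rate=config.sample_rate,
                                  initial_phase=phase)
            try:
                arms = measure_recording(rec, config, trial_rng, s, trial)
            except Exception as exc:
                raise RuntimeError(
                    f"measurement failed for subject {s}, trial {trial}: {exc}"
                ) from exc
            for name, result in arms.items():
                pooled.setdefault(name, []).append(result)
                all_results.append(result)
    report = build_report(pooled, reference=config.reference,
                          rmse_aggregation=config.rmse_aggregation)
    return report, all_results
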