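"""Monocular observation model: pinhole projection and pixel calibration.

The single-camera markerless route observes the walk through two fixed
smartphone-like cameras (1920x1080, 60 Hz): a *lateral* camera on the
subject's right with its optical axis perpendicular to the line of
progression, and a *frontal* camera at the end of the walkway looking
back along it.  Projection is an ideal pinhole (no lens distortion —
the dominant monocular error mechanisms are perspective and depth
scaling, not distortion).  Image convention: origin top-left, u right,
v down.

Metric scale is recovered the way a video-only system does it: from a
reference object of known physical length visible in the image (a force
plate, 0.46 m), giving a single meters-per-pixel factor valid at the
reference depth only — the depth-dependent scale error that follows is
one of the mechanisms this package exists to expose.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "CalibrationScale",
    "KeypointStream",
    "lateral_camera",
    "frontal_camera",
    "project_point",
    "project_recording",
    "calibrate_scale",
    "interpolate_low_confidence",
    "add_pixel_noise",
]

DEFAULT_RESOLUTION = (1920, 1080)
FORCE_PLATE_LENGTH_M = 0.46


class BehindCameraError(ValueError):
    """A point at non-positive depth cannot be projected."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: pose in the walkway frame plus intrinsics.

    ``orientation`` rotates walkway coordinates into the camera frame
    (rows are the camera's x/y/z axes in walkway coordinates; camera z
    is the optical axis, camera y points down in the image).
    ``mode="orthographic"`` replaces the perspective division by a fixed
    scale of ``focal_px / nominal_depth`` pixels per meter — the limit a
    perspective camera approaches as it is moved away with the focal
    length scaled up proportionally.
    """

    position: tuple[float, float, float]
    orientation: np.ndarray
    focal_px: float = 1500.0
    principal_point: tuple[float, float] = (960.0, 540.0)
    resolution: tuple[int, int] = DEFAULT_RESOLUTION
    mode: str = "perspective"
    nominal_depth: float | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "orientation", R)
        if self.focal_px <= 0:
            raise ValueError("focal_px must be positive")
        if self.mode not in ("perspective", "orthographic"):
            raise ValueError("mode must be 'perspective' or 'orthographic'")
        if self.mode == "orthographic" and not self.nominal_depth:
            raise ValueError("orthographic mode requires nominal_depth")

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float) - np.asarray(self.position)
        return p @ self.orientation.T


def lateral_camera(distance: float = 3.0, height: float = 0.9,
                   along_x: float = 5.0, focal_px: float = 1500.0,
                   mode: str = "perspective") -> CameraModel:
    """Camera on the subject's right (+z), optical axis along -z.

    Image u grows with walkway x (the walking direction), v points down.
    """
    R = np.array([[1.0, 0.0, 0.0],
                  [0.0, -1.0, 0.0],
                  [0.0, 0.0, -1.0]])
    return CameraModel(position=(along_x, height, distance), orientation=R,
                       focal_px=focal_px, mode=mode,
                       nominal_depth=distance if mode == "orthographic" else None)


def frontal_camera(distance_beyond: float = 2.0, height: float = 1.0,
                   walkway_length: float = 10.0, focal_px: float = 1500.0,
                   mode: str = "perspective") -> CameraModel:
    """Camera past the end of the walkway looking back along -x.

    The subject walks toward the camera, so depth decreases over the
    trial.  Image u grows toward the subject's left (-z), v points down.
    """
    R = np.array([[0.0, 0.0, -1.0],
                  [0.0, -1.0, 0.0],
                  [-1.0, 0.0, 0.0]])
    x = walkway_length + distance_beyond
    return CameraModel(position=(x, height, 0.0), orientation=R,
                       focal_px=focal_px, mode=mode,
                       nominal_depth=x - walkway_length / 2.0
                       if mode == "orthographic" else None)


@dataclass
class KeypointStream:
    """Per-camera 2D keypoint time series in pixels with confidence.

    ``data`` has shape (n_frames, n_keypoints, 3): u, v, confidence.
    ``frame_valid`` flags frames where the whole body is inside the
    image; frames outside the frustum are flagged, never clipped.
    ``time_offset`` is the stream's clock offset (s): sample *i* was
    taken at ``i / sample_rate + time_offset`` on the common study clock
    (emulates imperfect audio synchronization between devices).
    """

    view: str
    sample_rate: float
    keypoint_names: tuple[str, ...]
    data: np.ndarray
    frame_valid: np.ndarray | None = None
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("data must be (n_frames, n_keypoints, 3)")
        if not np.all(np.isfinite(self.data[..., :2])):
            raise ValueError("pixel coordinates must be finite")
        conf = self.data[..., 2]
        if conf.min() < -1e-9 or conf.max() > 1 + 1e-9:
            raise ValueError("confidence must lie in [0, 1]")
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate + self.time_offset

    def positions(self, name: str) -> np.ndarray:
        return self.data[:, self.keypoint_names.index(name), :2]

    def confidences(self, name: str) -> np.ndarray:
        return self.data[:, self.keypoint_names.index(name), 2]

    def cropped(self, start: int, stop: int) -> "KeypointStream":
        return dataclasses.replace(
            self, data=self.data[start:stop],
            frame_valid=self.frame_valid[start:stop],
            time_offset=self.time_offset + start / self.sample_rate)

    def with_offset(self, offset_s: float) -> "KeypointStream":
        return dataclasses.replace(self, time_offset=self.time_offset + offset_s)


@dataclass(frozen=True)
class CalibrationScale:
    """Metric scale from a reference object of known length in the image."""

    meters_per_pixel: float
    reference_length_m: float = FORCE_PLATE_LENGTH_M
    reference_length_px: float | None = None

    def __post_init__(self) -> None:
        if self.meters_per_pixel <= 0:
            raise ValueError("meters_per_pixel must be positive")


def calibrate_scale(reference_length_px: float,
                    reference_length_m: float = FORCE_PLATE_LENGTH_M
                    ) -> CalibrationScale:
    """Pixel calibration against the in-scene reference object."""
    if reference_length_px <= 0:
        raise ValueError("reference length in pixels must be positive")
    return CalibrationScale(
        meters_per_pixel=reference_length_m / reference_length_px,
        reference_length_m=reference_length_m,
        reference_length_px=reference_length_px)


def project_point(camera: CameraModel, point3d) -> tuple | np.ndarray:
    """Pinhole projection of walkway-frame point(s) to pixels.

    ``u = f * Xc / Zc + cu``, ``v = f * Yc / Zc + cv`` in camera
    coordinates; raises :class:`BehindCameraError` for non-positive
    depth (perspective mode).  Accepts a single point or ``(..., 3)``
    arrays.
    """
    p = camera.to_camera(point3d)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    cu, cv = camera.principal_point
    if camera.mode == "orthographic":
        s = camera.focal_px / camera.nominal_depth
        uv = np.stack([s * p[..., 0] + cu, s * p[..., 1] + cv], axis=-1)
    else:
        z = p[..., 2]
        if np.any(z <= 0):
            raise BehindCameraError("point at non-positive depth")
        uv = np.stack([camera.focal_px * p[..., 0] / z + cu,
                       camera.focal_px * p[..., 1] / z + cv], axis=-1)
    if single:
        u, v = uv[0]
        return float(u), float(v)
    return uv


def project_recording(camera: CameraModel, recording,
                      view: str | None = None) -> KeypointStream:
    """Project a ground-truth recording into one monocular pixel stream.

    Noise-free projection carries confidence 1.0 (or the recording's own
    confidence channel when present).  Frames where any keypoint falls
    outside the image are flagged in ``frame_valid`` rather than
    clipped; a frame behind the camera raises.
    """
    uv = project_point(camera, recording.keypoints3d)
    w, hgt = camera.resolution
    inside = ((uv[..., 0] >= 0) & (uv[..., 0] <= w)
              & (uv[..., 1] >= 0) & (uv[..., 1] <= hgt))
    conf = recording.confidence if recording.confidence is not None \
        else np.ones(uv.shape[:2])
    data = np.concatenate([uv, conf[..., None]], axis=-1)
    if view is None:
        axis = camera.orientation[2]
        view = "lateral" if abs(axis[2]) > abs(axis[0]) else "frontal"
    return KeypointStream(view=view, sample_rate=recording.sample_rate,
                          keypoint_names=tuple(recording.keypoint_names),
                          data=data, frame_valid=inside.all(axis=1))


def add_pixel_noise(stream: KeypointStream, sigma_px: float, seed: int,
                    assign_confidence: bool = True) -> KeypointStream:
    """Seed-reproducible i.i.d. Gaussian jitter on pixel keypoints.

    Models pose-estimation jitter; confidence is re-assigned to decrease
    with the injected perturbation magnitude when requested.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    rng = np.random.default_rng(seed)
    data = stream.data.copy()
    if sigma_px > 0:
        noise = rng.normal(0.0, sigma_px, size=data[..., :2].shape)
        data[..., :2] += noise
        if assign_confidence:
            r = np.linalg.norm(noise, axis=-1)
            data[..., 2] = np.exp(-0.5 * (r / (2.0 * sigma_px)) ** 2)
    return dataclasses.replace(stream, data=data)


def interpolate_low_confidence(stream: KeypointStream, threshold: float,
                               window: int) -> KeypointStream:
    """Replace low-certainty keypoints by confidence-weighted neighbors.

    For every (frame, keypoint) with confidence below ``threshold``, the
    position becomes the confidence-weighted mean of that keypoint's
    positions in the confident frames within ``window`` frames on either
    side; its output confidence is the weight mass used (mean confidence
    of the contributing frames).  Confident samples pass through
    untouched.  If a window holds no confident frame the value is held
    from the nearest confident frame and its confidence set to 0.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    data = stream.data.copy()
    n, m, _ = data.shape
    for j in range(m):
        conf = stream.data[:, j, 2]
        ok = conf >= threshold
        low = np.nonzero(~ok)[0]
        if low.size == 0:
            continue
        ok_idx = np.nonzero(ok)[0]
        for i in low:
            lo, hi = max(0, i - window), min(n, i + window + 1)
            nb = ok_idx[(ok_idx >= lo) & (ok_idx < hi)]
            if nb.size == 0:
                if ok_idx.size == 0:
                    continue  # nothing confident at all: leave as-is
                nearest = ok_idx[np.argmin(np.abs(ok_idx - i))]
                data[i, j, :2] = stream.data[nearest, j, :2]
                data[i, j, 2] = 0.0
                continue
            w = conf[nb]
            data[i, j, :2] = (w[:, None] * stream.data[nb, j, :2]).sum(0) / w.sum()
            data[i, j, 2] = float(w.mean())
    return dataclasses.replace(stream, data=data)
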