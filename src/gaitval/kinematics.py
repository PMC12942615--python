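"""Joint-angle computation by the two measurement routes.

Two independent routes produce lower-limb joint angles:

* the *planar* route works on single-view 2D keypoints (image pixels,
  v axis pointing down) and computes signed angles between keypoint
  vectors — this is what a monocular markerless system can do;
* the *transform* route works on per-segment 4x4 homogeneous poses and
  extracts clinical Cardan angles from relative segment rotations —
  this is what a 3D (multi-camera markerless or marker-based) system does.

Walkway frame convention used throughout the package: x = line of
progression, y = vertical (up), z = mediolateral (to the subject's right
when walking in +x).  Cardan sequence: mediolateral (flexion/extension),
then anteroposterior (ab/adduction), then longitudinal (axial rotation),
i.e. intrinsic z-x-y in the walkway axes.

Sign convention for reported angles: flexion, dorsiflexion and abduction
positive; extension, plantarflexion and adduction negative, on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentTransformStream",
    "JointAngleSeries",
    "planar_angle",
    "relative_rotation",
    "cardan_angles",
    "compose_cardan",
    "transform_joint_angles",
    "sml_joint_angles",
    "time_normalize",
]

#: segments expected by the transform route
SEGMENTS = ("pelvis", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")

#: the outcome set: (joint, plane) pairs reported by the study design
OUTCOME_PLANES = (
    ("hip", "sagittal"),
    ("hip", "frontal"),
    ("knee", "sagittal"),
    ("knee", "frontal"),
    ("ankle", "sagittal"),
)

_ORTHONORMAL_TOL = 1e-8
_GIMBAL_TOL = 1e-6  # rad away from |beta| = pi/2


class GimbalLockError(ValueError):
    """Second Cardan angle too close to +-90 deg for a stable decomposition."""


@dataclass
class SegmentTransformStream:
    """Time series of rigid poses (walkway frame -> segment frame).

    ``transforms`` maps segment name to an (n_frames, 4, 4) array.  The
    rotation blocks must be proper rotations; this is validated on
    construction to the tolerance a motion-capture export should meet.
    """

    transforms: dict[str, np.ndarray]
    sample_rate: float

    def __post_init__(self) -> None:
        for name, T in self.transforms.items():
            T = np.asarray(T, dtype=float)
            if T.ndim != 3 or T.shape[1:] != (4, 4):
                raise ValueError(f"segment {name!r}: expected (n, 4, 4) array")
            self.transforms[name] = T
            _check_rigid(T, name)

    @property
    def n_frames(self) -> int:
        return next(iter(self.transforms.values())).shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def __getitem__(self, segment: str) -> np.ndarray:
        return self.transforms[segment]


@dataclass
class JointAngleSeries:
    """One joint/plane/side angle trace in degrees, at the stream's rate."""

    joint: str
    plane: str
    side: str
    values: np.ndarray
    sample_rate: float
    convention: str = "flexion/dorsiflexion/abduction positive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("joint angle series contains non-finite values")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


def _check_rigid(T: np.ndarray, name: str = "transform") -> None:
    R = T[..., :3, :3]
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"{name}: rotation block not orthonormal (err={err:.2e})")
    if np.any(np.linalg.det(R) < 0):
        raise ValueError(f"{name}: rotation block has negative determinant")
    if np.abs(T[..., 3, :] - np.array([0.0, 0.0, 0.0, 1.0])).max() > 1e-9:
        raise ValueError(f"{name}: last row is not (0, 0, 0, 1)")


# ---------------------------------------------------------------------------
# elemental rotations (shared with the synthetic generator)

def rot_x(deg):
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 0, 0] = 1.0
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    return R


def rot_y(deg):
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 1, 1] = 1.0
    R[..., 0, 0] = c
    R[..., 0, 2] = s
    R[..., 2, 0] = -s
    R[..., 2, 2] = c
    return R


def rot_z(deg):
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 2, 2] = 1.0
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    return R


# ---------------------------------------------------------------------------
# planar (single-view) route

def planar_angle(p_proximal, p_center, p_distal) -> np.ndarray | float:
    """Signed deflection angle (deg) at ``p_center`` between two segments.

    Measured from the continuation of the proximal segment
    (proximal->center) to the distal segment (center->distal), so three
    collinear points give 0 and a right-angle bend gives +-90.  The sign
    is the atan2(cross, dot) sign in image coordinates (u right, v
    down).  Inputs may be single points ``(u, v)`` or arrays of shape
    ``(..., 2)``; broadcasting applies frame-wise.

    Raises ``ValueError`` when either segment degenerates to zero length
    (coincident points), where the angle is undefined.
    """
    a = np.asarray(p_center, dtype=float) - np.asarray(p_proximal, dtype=float)
    b = np.asarray(p_distal, dtype=float) - np.asarray(p_center, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise ValueError("planar_angle undefined: coincident keypoints")
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang) if ang.ndim == 0 else ang


def _segment_tilt(p_top, p_bottom) -> np.ndarray:
    """Signed tilt (deg) of the segment top->bottom from image vertical.

    Zero when the segment hangs straight down (+v); positive when the
    bottom end is displaced toward +u.
    """
    d = np.asarray(p_bottom, dtype=float) - np.asarray(p_top, dtype=float)
    return np.degrees(np.arctan2(d[..., 0], d[..., 1]))


# ---------------------------------------------------------------------------
# transform (3D) route

def relative_rotation(parent_T: np.ndarray, child_T: np.ndarray) -> np.ndarray:
    """Rotation of the child segment expressed in the parent frame.

    Accepts single 4x4 transforms or stacks ``(n, 4, 4)``; returns the
    matching ``(..., 3, 3)`` rotation ``R_parent^T @ R_child``.
    """
    parent_T = np.asarray(parent_T, dtype=float)
    child_T = np.asarray(child_T, dtype=float)
    for T in (parent_T, child_T):
        _check_rigid(T if T.ndim == 3 else T[None])
    Rp = parent_T[..., :3, :3]
    Rc = child_T[..., :3, :3]
    return np.swapaxes(Rp, -1, -2) @ Rc


def cardan_angles(R: np.ndarray, sequence: str = "zxy"):
    """Cardan decomposition of ``R`` into three elemental rotations (deg).

    With the default clinical sequence ``"zxy"`` (intrinsic), ``R`` is
    factored as ``Rz(a) @ Rx(b) @ Ry(c)``: *a* about the mediolateral
    axis (flexion/extension), *b* about the anteroposterior axis
    (ab/adduction), *c* about the longitudinal axis (axial rotation).

    Raises :class:`GimbalLockError` when the middle angle is within
    ~1e-6 rad of +-90 deg, where *a* and *c* are not separable.
    """
    if sequence != "zxy":
        raise NotImplementedError("only the clinical z-x-y sequence is provided")
    R = np.asarray(R, dtype=float)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"rotation not orthonormal (err={err:.2e})")
    s_b = np.clip(R[..., 2, 1], -1.0, 1.0)
    if np.any(np.abs(np.abs(np.arcsin(s_b)) - np.pi / 2) < _GIMBAL_TOL):
        raise GimbalLockError("second Cardan angle at +-90 deg: sequence singular")
    b = np.degrees(np.arcsin(s_b))
    a = np.degrees(np.arctan2(-R[..., 0, 1], R[..., 1, 1]))
    c = np.degrees(np.arctan2(-R[..., 2, 0], R[..., 2, 2]))
    return a, b, c


def compose_cardan(a, b, c, sequence: str = "zxy") -> np.ndarray:
    """Inverse of :func:`cardan_angles`: build ``R`` from the angle triple."""
    if sequence != "zxy":
        raise NotImplementedError("only the clinical z-x-y sequence is provided")
    return rot_z(a) @ rot_x(b) @ rot_y(c)


# per-joint mapping between matrix Cardan angles and clinical signs.
# (matrix angle) * sign = clinical value; frontal-plane sign flips with
# side because abduction is "away from the midline".
_FLEX_SIGN = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}
_SIDE_SIGN = {"R": 1.0, "L": -1.0}

_JOINT_PARENT_CHILD = {
    "hip": ("pelvis", "thigh"),
    "knee": ("thigh", "shank"),
    "ankle": ("shank", "foot"),
}


def joint_rotation(joint: str, side: str, flexion, frontal, axial) -> np.ndarray:
    """Clinical angles -> relative rotation matrix (parent -> child).

    The exact inverse of the extraction in :func:`transform_joint_angles`;
    the synthetic generator uses it to pose segments, which makes the
    angle round trip exact by construction.
    """
    s = _SIDE_SIGN[side]
    return compose_cardan(
        np.asarray(flexion, dtype=float) * _FLEX_SIGN[joint],
        np.asarray(frontal, dtype=float) * (-s),
        np.asarray(axial, dtype=float) * (-s),
    )


def transform_joint_angles(transforms: SegmentTransformStream) -> dict:
    """Clinical joint angles from per-segment pose streams.

    hip = pelvis->thigh, knee = thigh->shank, ankle = shank->foot.  The
    foot segment frame is defined to coincide with the shank frame in the
    neutral (anatomical) pose, so neutral dorsiflexion decomposes to zero
    without an explicit offset.  Returns a dict keyed ``(joint, plane,
    side)`` with planes sagittal, frontal and transverse (the transverse
    series is retained internally but is not part of the reported
    outcome set).
    """
    out: dict[tuple[str, str, str], JointAngleSeries] = {}
    for side in ("L", "R"):
        s = _SIDE_SIGN[side]
        for joint, (parent, child) in _JOINT_PARENT_CHILD.items():
            pname = parent if parent == "pelvis" else f"{parent}_{side}"
            cname = f"{child}_{side}"
            for name in (pname, cname):
                if name not in transforms.transforms:
                    raise KeyError(f"missing segment {name!r}")
            R = relative_rotation(transforms[pname], transforms[cname])
            a, b, c = cardan_angles(R)
            values = {
                "sagittal": a * _FLEX_SIGN[joint],
                "frontal": b * (-s),
                "transverse": c * (-s),
            }
            for plane, v in values.items():
                out[(joint, plane, side)] = JointAngleSeries(
                    joint, plane, side, v, transforms.sample_rate
                )
    return out


# ---------------------------------------------------------------------------
# single-camera (planar) joint angle sets

_SAGITTAL_TRIADS = {
    # joint -> keypoint roles used in the lateral view
    "hip": ("mid_hip", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "big_toe"),
}


def _kp(stream, name: str) -> np.ndarray:
    """(n, 2) pixel positions of a named keypoint."""
    return stream.positions(name)


def sml_joint_angles(lateral, frontal) -> dict:
    """Single-camera joint angles from the two monocular views.

    Sagittal-plane hip/knee/ankle angles come from the lateral view,
    frontal-plane hip/knee angles from the frontal view — each view is
    used only for the plane it observes best.  Keypoint triads:

    * hip (sagittal): thigh tilt (hip->knee) from image vertical,
      flexion positive toward the walking direction;
    * knee (sagittal): signed angle hip–knee–ankle, 0 when collinear,
      flexion positive;
    * ankle (sagittal): signed angle between the shank line (knee->
      ankle) and the sole line (heel->big_toe) minus the 90 deg neutral
      shank–sole angle, dorsiflexion positive;
    * hip/knee (frontal): the same constructions on the frontal view's
      u axis, abduction positive.

    Both streams must already be expressed on a common clock (see
    ``events.align_streams``).
    """
    out: dict[tuple[str, str, str], JointAngleSeries] = {}
    walk_sign = _walking_direction_sign(lateral)
    for side in ("L", "R"):
        hip = _kp(lateral, f"hip_{side}")
        knee = _kp(lateral, f"knee_{side}")
        ankle = _kp(lateral, f"ankle_{side}")
        heel = _kp(lateral, f"heel_{side}")
        toe = _kp(lateral, f"big_toe_{side}")

        hip_sag = walk_sign * _segment_tilt(hip, knee)
        knee_sag = walk_sign * planar_angle(hip, knee, ankle)
        # sole line through heel->toe: the 2D stand-in for the foot axis
        shank = ankle - knee
        sole = toe - heel
        cross = shank[..., 0] * sole[..., 1] - shank[..., 1] * sole[..., 0]
        dot = (shank * sole).sum(axis=-1)
        ankle_sag = -walk_sign * np.degrees(np.arctan2(cross, dot)) - 90.0

        # frontal view: u axis runs toward the subject's left (camera
        # faces the walker), so +u displacement of the knee relative to
        # the hip is adduction for the right leg, abduction for the left.
        hip_f = _kp(frontal, f"hip_{side}")
        knee_f = _kp(frontal, f"knee_{side}")
        ankle_f = _kp(frontal, f"ankle_{side}")
        s = _SIDE_SIGN[side]
        hip_front = -s * _segment_tilt(hip_f, knee_f)
        knee_front = s * planar_angle(hip_f, knee_f, ankle_f)

        rate = lateral.sample_rate
        out[("hip", "sagittal", side)] = JointAngleSeries("hip", "sagittal", side, hip_sag, rate)
        out[("knee", "sagittal", side)] = JointAngleSeries("knee", "sagittal", side, knee_sag, rate)
        out[("ankle", "sagittal", side)] = JointAngleSeries("ankle", "sagittal", side, ankle_sag, rate)
        out[("hip", "frontal", side)] = JointAngleSeries(
            "hip", "frontal", side, hip_front, frontal.sample_rate
        )
        out[("knee", "frontal", side)] = JointAngleSeries(
            "knee", "frontal", side, knee_front, frontal.sample_rate
        )
    return out


def _walking_direction_sign(lateral) -> float:
    """+1 when the subject moves toward +u in the lateral view, else -1."""
    u = _kp(lateral, "mid_hip")[:, 0]
    return 1.0 if u[-1] >= u[0] else -1.0


# ---------------------------------------------------------------------------

def time_normalize(series, cycle, n_points: int = 101) -> np.ndarray:
    """Resample one gait cycle onto ``n_points`` evenly spaced phase points.

    ``series`` is a :class:`JointAngleSeries` (or any object with
    ``values``/``time`` arrays); ``cycle`` is the ``(t_heel_strike,
    t_next_heel_strike)`` pair in seconds.  Linear interpolation; the
    endpoints are the interpolated values at the heel-strike instants.
    """
    t0, t1 = float(cycle[0]), float(cycle[1])
    values = np.asarray(series.values, dtype=float)
    time = np.asarray(series.time, dtype=float)
    if not (t1 > t0):
        raise ValueError("cycle end must follow cycle start")
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise ValueError("cycle boundaries outside the recorded data")
    if np.count_nonzero((time >= t0) & (time <= t1)) < 2:
        raise ValueError("cycle spans fewer than 2 samples")
    phase_t = np.linspace(t0, t1, n_points)
    return np.interp(phase_t, time, values)
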