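"""Synthetic ground-truth walking recordings.

The generator stands in for the capture front ends of a three-system
gait study: it produces a subject walking a straight ~10 m path at a
comfortable pace, sampled at 60 Hz, with exactly known joint-angle
profiles, gait events and spatiotemporal parameters.  Everything
downstream (camera projection, angle extraction, event detection,
agreement statistics) can then be validated against construction truth.

Model
-----
The pelvis translates along the progression axis at constant speed with
sinusoidal vertical/lateral oscillations and a pelvic obliquity roll;
each leg is a pelvis->thigh->shank->foot rigid chain posed by periodic
joint-angle profiles (truncated Fourier series of the gait-cycle phase).
Events are defined analytically from phase — heel strike at phase 0,
toe off at phase = stance fraction, left leg half a cycle out of phase —
so ground truth is exact rather than detected.

The default profiles are *event-locked*: they are cosine series (zero
derivative at heel strike) and two free harmonics are solved, once, so
the pelvis-relative toe extremum and the toe-height minimum fall exactly
on the analytic toe-off phase.  This makes coordinate-based event
detection on noise-free data recover the constructed events to the
frame, which is what the generator's validation role requires.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, linalg, optimize

from .events import GaitEvent, SpatiotemporalParams, HEEL_STRIKE, TOE_OFF
from .kinematics import (
    SegmentTransformStream,
    JointAngleSeries,
    OUTCOME_PLANES,
    joint_rotation,
    rot_x,
)

__all__ = [
    "AnthropometricProfile",
    "FourierProfile",
    "GaitPattern",
    "GroundTruthRecording",
    "default_pattern",
    "build_recording",
    "add_keypoint_noise",
    "KEYPOINT_NAMES",
]

#: the 24-point keypoint schema (a declared convention covering head,
#: trunk, upper and lower limbs; the pose-estimation schema it emulates
#: is not standardized across vendors)
KEYPOINT_NAMES = (
    "head_top", "nose", "neck", "sternum", "mid_spine", "mid_hip",
    "shoulder_L", "shoulder_R", "elbow_L", "elbow_R", "wrist_L", "wrist_R",
    "hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R",
    "heel_L", "heel_R", "big_toe_L", "big_toe_R", "small_toe_L", "small_toe_R",
)

#: Table-style reference values (marker-based column) used as generator
#: defaults: gait speed (m/s), step length (m), stance and swing times (s)
DEFAULT_GAIT_SPEED = 1.091
DEFAULT_STEP_LENGTH = 0.609
DEFAULT_STANCE_FRACTION = 0.725 / (0.725 + 0.361)

# default sagittal/frontal peak targets (deg) for the shipped profiles
_PEAKS = {
    ("hip", "sagittal"): (-12.57, 26.44),
    ("knee", "sagittal"): (1.75, 61.53),
    ("hip", "frontal"): (-3.57, 7.99),
    ("knee", "frontal"): (-2.0, 9.78),
}

_SIDES = ("L", "R")
_REF_HEIGHT = 1.6925  # m; cohort mean height the default offsets are scaled to


@dataclass(frozen=True)
class AnthropometricProfile:
    """Body segment dimensions (m) of one synthetic subject.

    Defaults follow standard anthropometric proportions of stature for a
    1.69 m adult; ``ankle_height`` is the height of the ankle joint
    center above the sole.
    """

    height: float = _REF_HEIGHT
    pelvis_width: float = 0.17
    thigh_length: float = 0.41
    shank_length: float = 0.42
    foot_length: float = 0.255
    heel_to_ankle: float = 0.07
    ankle_height: float = 0.085

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.thigh_length + self.shank_length >= self.height:
            raise ValueError("leg length must be shorter than stature")
        if self.heel_to_ankle >= self.foot_length:
            raise ValueError("heel_to_ankle must be within the foot")

    @classmethod
    def from_height(cls, height: float) -> "AnthropometricProfile":
        """Scale all default segment lengths proportionally to stature."""
        k = height / _REF_HEIGHT
        return cls(height=height, pelvis_width=0.17 * k, thigh_length=0.41 * k,
                   shank_length=0.42 * k, foot_length=0.255 * k,
                   heel_to_ankle=0.07 * k, ankle_height=0.085 * k)

    @property
    def pelvis_height(self) -> float:
        """Hip-center height in neutral standing (sole on the floor)."""
        return self.thigh_length + self.shank_length + self.ankle_height


@dataclass(frozen=True)
class FourierProfile:
    """Truncated Fourier series of normalized gait phase, in degrees.

    value(phase) = a0 + sum_k cos_k * cos(2 pi k phase)
                      + sum_k sin_k * sin(2 pi k phase)
    """

    a0: float = 0.0
    cos: tuple[float, ...] = ()
    sin: tuple[float, ...] = ()

    def __call__(self, phase) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full(phase.shape, self.a0)
        for k, a in enumerate(self.cos, start=1):
            out += a * np.cos(2 * np.pi * k * phase)
        for k, b in enumerate(self.sin, start=1):
            out += b * np.sin(2 * np.pi * k * phase)
        return out

    def rescaled(self, lo: float, hi: float, n_grid: int = 4096) -> "FourierProfile":
        """Affinely remap the profile so its range over a cycle is [lo, hi]."""
        phase = np.linspace(0.0, 1.0, n_grid, endpoint=False)
        v = self(phase)
        vmin, vmax = float(v.min()), float(v.max())
        if vmax - vmin < 1e-12:
            raise ValueError("cannot rescale a constant profile")
        g = (hi - lo) / (vmax - vmin)
        off = lo - g * vmin
        return FourierProfile(
            a0=self.a0 * g + off,
            cos=tuple(a * g for a in self.cos),
            sin=tuple(b * g for b in self.sin),
        )


ZERO_PROFILE = FourierProfile()


def _resolve_speed_step_cadence(speed, step, cadence):
    given = sum(v is not None for v in (speed, step, cadence))
    if given < 2:
        raise ValueError("give at least two of gait_speed, step_length, cadence")
    if speed is None:
        speed = step * cadence / 60.0
    elif step is None:
        step = 60.0 * speed / cadence
    elif cadence is None:
        cadence = 60.0 * speed / step
    if abs(speed - step * cadence / 60.0) > 1e-6 * max(speed, 1.0):
        raise ValueError("inconsistent gait_speed / step_length / cadence triple")
    return float(speed), float(step), float(cadence)


@dataclass(frozen=True)
class GaitPattern:
    """A periodic walking pattern: pace, phase structure, joint profiles.

    Any two of ``gait_speed`` (m/s), ``step_length`` (m) and ``cadence``
    (steps/min) determine the third through speed = step * cadence / 60.
    ``joint_profiles`` maps ``(joint, plane)`` to the right-leg profile;
    the left leg runs the same profile ``left_right_phase_offset`` of a
    cycle later.  Pelvis oscillation amplitudes are in meters: the
    vertical motion carries two and four oscillations per stride (both
    side-symmetric), the lateral sway one; the obliquity (roll about the
    progression axis, degrees) lowers each hip toward its own stance
    side and is what makes each heel lowest at its own heel strike.
    """

    gait_speed: float | None = DEFAULT_GAIT_SPEED
    step_length: float | None = DEFAULT_STEP_LENGTH
    cadence: float | None = None
    stance_fraction: float = DEFAULT_STANCE_FRACTION
    joint_profiles: dict = field(default_factory=dict)
    left_right_phase_offset: float = 0.5
    pelvis_vertical_amplitude: float = 0.032
    pelvis_vertical_amplitude2: float = 0.0
    pelvis_lateral_amplitude: float = 0.03
    pelvis_obliquity_deg: float = 6.0

    def __post_init__(self) -> None:
        speed, step, cadence = _resolve_speed_step_cadence(
            self.gait_speed, self.step_length, self.cadence)
        object.__setattr__(self, "gait_speed", speed)
        object.__setattr__(self, "step_length", step)
        object.__setattr__(self, "cadence", cadence)
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")

    @property
    def stride_time(self) -> float:
        return 120.0 / self.cadence

    @property
    def stride_length(self) -> float:
        return self.gait_speed * self.stride_time

    def profile(self, joint: str, plane: str) -> FourierProfile:
        return self.joint_profiles.get((joint, plane), ZERO_PROFILE)

    def true_params(self) -> SpatiotemporalParams:
        return SpatiotemporalParams(
            gait_speed=self.gait_speed,
            step_length=self.step_length,
            stride_length=self.stride_length,
            stance_time=self.stance_fraction * self.stride_time,
            swing_time=(1.0 - self.stance_fraction) * self.stride_time,
        )

    def replace(self, **kw) -> "GaitPattern":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruthRecording:
    """Simulator output: exact trajectories, poses, angles and events."""

    sample_rate: float
    keypoints3d: np.ndarray                 # (n_frames, 24, 3) m, walkway frame
    keypoint_names: tuple[str, ...]
    segment_transforms: SegmentTransformStream
    true_angles: dict                       # (joint, plane, side) -> JointAngleSeries
    true_events: list[GaitEvent]
    true_params: SpatiotemporalParams
    pattern: GaitPattern
    anthro: AnthropometricProfile
    start_x: float = 0.3
    walkway_length: float = 10.0
    confidence: np.ndarray | None = None    # (n_frames, 24) in [0, 1]

    @property
    def n_frames(self) -> int:
        return self.keypoints3d.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def keypoint(self, name: str) -> np.ndarray:
        return self.keypoints3d[:, self.keypoint_names.index(name), :]

    def events_of(self, side: str, etype: str) -> list[GaitEvent]:
        return sorted((e for e in self.true_events
                       if e.side == side and e.type == etype),
                      key=lambda e: e.time)


# ---------------------------------------------------------------------------
# default pattern design

def _fourier_basis_row(p: float, K: int, derivative: bool) -> list[float]:
    if derivative:
        row = [0.0]
        row += [-k * np.sin(2 * np.pi * k * p) for k in range(1, K + 1)]
        row += [k * np.cos(2 * np.pi * k * p) for k in range(1, K + 1)]
    else:
        row = [1.0]
        row += [np.cos(2 * np.pi * k * p) for k in range(1, K + 1)]
        row += [np.sin(2 * np.pi * k * p) for k in range(1, K + 1)]
    return row


def _fit_fourier(phase: np.ndarray, values: np.ndarray, n_harmonics: int,
                 zero_deriv_at: tuple = (0.0,),
                 pin_values: tuple = ()) -> FourierProfile:
    """Least-squares Fourier fit with exact slope and value constraints.

    ``zero_deriv_at`` phases get an exactly zero derivative and
    ``pin_values`` pairs ``(phase, value)`` are interpolated exactly;
    both are enforced through a particular-solution + null-space
    parameterization.  The event-locked default pattern relies on exact
    stationarity at the heel-strike and toe-off phases.
    """
    K = n_harmonics
    cols = [np.ones_like(phase)]
    cols += [np.cos(2 * np.pi * k * phase) for k in range(1, K + 1)]
    cols += [np.sin(2 * np.pi * k * phase) for k in range(1, K + 1)]
    A = np.stack(cols, axis=1)
    C = [_fourier_basis_row(p, K, derivative=True) for p in zero_deriv_at]
    d = [0.0] * len(C)
    for p, v in pin_values:
        C.append(_fourier_basis_row(p, K, derivative=False))
        d.append(float(v))
    C = np.asarray(C)
    d = np.asarray(d)
    x_p = C.T @ np.linalg.solve(C @ C.T, d)
    N = linalg.null_space(C)
    coef, *_ = np.linalg.lstsq(A @ N, values - A @ x_p, rcond=None)
    full = x_p + N @ coef
    return FourierProfile(a0=full[0], cos=tuple(full[1:1 + K]),
                          sin=tuple(full[1 + K:]))


def _knot_profile(knot_phase: np.ndarray, knot_value: np.ndarray,
                  stance_fraction: float, n_harmonics: int = 8,
                  pin_values: tuple = ()) -> FourierProfile:
    """Smooth periodic profile through knots, as a truncated Fourier series.

    A periodic cubic spline through the knots is sampled densely and
    projected onto the constrained Fourier basis (zero slope at the
    heel-strike and toe-off phases, optional exact value pins).  Fitting
    the dense spline rather than the knots avoids interpolation ringing.
    """
    p = np.r_[knot_phase, knot_phase[0] + 1.0]
    v = np.r_[knot_value, knot_value[0]]
    spline = interpolate.CubicSpline(p, v, bc_type="periodic")
    grid = np.linspace(0.0, 1.0, 2048, endpoint=False)
    return _fit_fourier(grid, spline(grid), n_harmonics,
                        zero_deriv_at=(0.0, stance_fraction),
                        pin_values=pin_values)


# Default profile knots (phase, value in degrees), drawn at the default
# stance fraction and rescaled to the reference peak targets.  The hip
# holds flexion through loading response and rises quickly in swing; the
# knee shows a loading-response bump, near-extension in terminal stance
# and its flexion peak in mid-swing; the foot-pitch (gamma) knots encode
# heel-down contact at heel strike, foot-flat stance and push-off, from
# which the ankle profile is derived.
_SF0 = DEFAULT_STANCE_FRACTION
_HIP_KNOTS = (
    np.array([0.0, 0.08, 0.18, 0.30, 0.42, 0.55, 0.62, _SF0, 0.72, 0.78, 0.85, 0.90, 0.95]),
    np.array([26.4, 23.5, 15.0, 1.0, -9.0, -12.5, -13.0, -12.3, -3.0, 9.0, 18.0, 23.5, 25.9]),
)
_KNEE_KNOTS = (
    np.array([0.0, 0.05, 0.12, 0.22, 0.32, 0.42, 0.52, 0.60, 0.64, _SF0, 0.71, 0.755, 0.80, 0.86, 0.92, 0.97]),
    np.array([6.0, 13.0, 24.0, 12.0, 4.0, 3.0, 7.0, 11.0, 15.0, 20.0, 42.0, 61.0, 57.0, 35.0, 13.0, 6.5]),
)
_GAMMA_KNOTS = (
    np.array([0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.49,
              0.52, 0.55, 0.58, 0.61, 0.63, 0.65, _SF0, 0.72, 0.78, 0.85, 0.92, 0.96]),
    np.array([38.0, 14.0, 3.0, 2.0, 1.0, 0.0, 0.0, 0.0, 1.0, 2.0, -3.0,
              -5.0, -11.0, -18.0, -30.0, -42.0, -52.0, -64.0, -45.0, -20.0, -2.0, 14.0, 26.0]),
)


def _warp_phase(phase: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Map default-stance-fraction knot phases onto another stance fraction."""
    p = np.asarray(phase, dtype=float)
    stance = p * (stance_fraction / _SF0)
    swing = stance_fraction + (p - _SF0) * (1 - stance_fraction) / (1 - _SF0)
    return np.where(p <= _SF0, stance, swing)


def default_pattern(anthro: AnthropometricProfile | None = None,
                    gait_speed: float = DEFAULT_GAIT_SPEED,
                    step_length: float = DEFAULT_STEP_LENGTH,
                    stance_fraction: float = DEFAULT_STANCE_FRACTION,
                    sagittal_only: bool = False,
                    **pattern_kw) -> GaitPattern:
    """The shipped walking pattern, event-locked for the given body.

    Sagittal peaks match the marker-based reference means (peak hip
    flexion 26.44 deg, extension -12.57 deg, peak knee flexion
    61.53 deg, minimum 1.75 deg); frontal profiles are small, matching
    reported hip/knee ab/adduction peaks.  All profiles are exactly
    stationary at the heel-strike and toe-off phases, the late-stance
    foot pitch is solved so the toe rides a ground target into a strict
    height minimum at toe off, and :func:`_lock_toe_off` zeroes the
    pelvis-relative toe velocity at the toe-off phase — together these
    make coordinate-based event detection exact on noise-free data.

    ``sagittal_only`` zeroes the frontal profiles and all out-of-plane
    pelvis motion (the geometry under which a lateral planar view is
    exact).
    """
    anthro = anthro or AnthropometricProfile()
    sf = stance_fraction
    hip = _knot_profile(_warp_phase(_HIP_KNOTS[0], sf), _HIP_KNOTS[1], sf)
    hip = hip.rescaled(*_PEAKS[("hip", "sagittal")])
    knee = _knot_profile(_warp_phase(_KNEE_KNOTS[0], sf), _KNEE_KNOTS[1], sf)
    knee = knee.rescaled(*_PEAKS[("knee", "sagittal")])

    profiles = {("hip", "sagittal"): hip, ("knee", "sagittal"): knee}
    if not sagittal_only:
        neg = FourierProfile(cos=(-1.0,))
        profiles[("hip", "frontal")] = neg.rescaled(*_PEAKS[("hip", "frontal")])
        profiles[("knee", "frontal")] = neg.rescaled(*_PEAKS[("knee", "frontal")])
    else:
        pattern_kw.setdefault("pelvis_lateral_amplitude", 0.0)
        pattern_kw.setdefault("pelvis_obliquity_deg", 0.0)

    pattern = GaitPattern(gait_speed=gait_speed, step_length=step_length,
                          cadence=None, stance_fraction=sf,
                          joint_profiles=profiles, **pattern_kw)

    # ankle profile from world foot-pitch targets (gamma = shank tilt +
    # ankle angle; the shank tilt is hip - knee in closed form), with the
    # toe riding a gently descending ground target from foot-flat to a
    # strict height minimum at toe off (2 mm inside the foot's reach at
    # the toe-off posture, so the target stays attainable).  The ride and
    # the toe-off lock are iterated so the lock's pelvis correction is
    # reflected in the ride's ankle-height profile.
    gphi = _warp_phase(_GAMMA_KNOTS[0], sf)
    fwd = anthro.foot_length - anthro.heel_to_ankle
    reach = np.hypot(fwd, anthro.ankle_height)
    pitch0 = np.degrees(np.arctan2(anthro.ankle_height, fwd))
    late = (gphi >= 0.13 * sf / _SF0) & (gphi <= sf + 1e-9)
    lo = gphi[late][0]
    delta = hip(gphi) - knee(gphi)
    for _ in range(2):
        gval = _GAMMA_KNOTS[1].copy()
        ay = _chain_points(pattern, anthro, gphi[late], "R")["ankle"][:, 1]
        target_hi = 0.016
        target_sf = ay[-1] - reach + 0.002
        toe_target = target_hi + (target_sf - target_hi) * (gphi[late] - lo) / (sf - lo)
        gval[late] = np.degrees(
            np.arcsin(np.clip((toe_target - ay) / reach, -1.0, 1.0))) + pitch0
        theta = gval - delta
        pins = ((0.0, theta[0]), (sf, theta[late][-1]))
        ankle = _knot_profile(gphi, theta, sf, n_harmonics=12, pin_values=pins)
        profiles = dict(pattern.joint_profiles)
        profiles[("ankle", "sagittal")] = ankle
        pattern = _lock_toe_off(pattern.replace(joint_profiles=profiles), anthro)
    return pattern


def _lock_toe_off(pattern: GaitPattern, anthro: AnthropometricProfile) -> GaitPattern:
    """Zero the toe velocity at the toe-off phase, exactly.

    The knot-fitted profiles are already stationary at the event phases,
    so the pelvis-relative toe velocity at toe off is a small residual
    driven by frontal-plane couplings and the pelvis oscillation.  Two
    small corrections absorb it: a first-harmonic ankle term (vanishing,
    with zero slope, at heel strike) for the progression component, and
    the pelvis second vertical harmonic for the height component.
    """
    sf = pattern.stance_fraction
    ankle = pattern.profile("ankle", "sagittal")

    def make(x):
        u1, a4 = x
        cos = list(ankle.cos) if ankle.cos else [0.0]
        cos[0] += u1
        corrected = FourierProfile(a0=ankle.a0 - u1, cos=tuple(cos),
                                   sin=ankle.sin)
        profs = dict(pattern.joint_profiles)
        profs[("ankle", "sagittal")] = corrected
        return pattern.replace(joint_profiles=profs,
                               pelvis_vertical_amplitude2=a4)

    h = 1e-5

    def residual(x):
        cand = make(x)
        lo = _chain_points(cand, anthro, np.array([sf - h]), "R")
        hi = _chain_points(cand, anthro, np.array([sf + h]), "R")
        dx = (hi["big_toe"][0, 0] - lo["big_toe"][0, 0]) / (2 * h)
        dy = (hi["big_toe"][0, 1] - lo["big_toe"][0, 1]) / (2 * h)
        return [dx, dy]

    sol = optimize.root(residual, x0=[0.0, 0.0], tol=1e-13)
    if max(abs(np.asarray(residual(sol.x)))) > 1e-9:
        raise RuntimeError(f"toe-off lock failed to converge: {sol.message}")
    return make(sol.x)


# ---------------------------------------------------------------------------
# forward kinematics

def _pelvis_state(pattern: GaitPattern, anthro: AnthropometricProfile,
                  phase: np.ndarray):
    """Pelvis-frame rotation and pelvis-relative vertical/lateral offsets."""
    obliquity = pattern.pelvis_obliquity_deg * np.cos(2 * np.pi * phase)
    R = rot_x(obliquity)
    dy = (-pattern.pelvis_vertical_amplitude * np.cos(4 * np.pi * phase)
          - pattern.pelvis_vertical_amplitude2 * np.cos(8 * np.pi * phase))
    dz = pattern.pelvis_lateral_amplitude * np.sin(2 * np.pi * phase)
    return R, dy, dz


def _chain_points(pattern: GaitPattern, anthro: AnthropometricProfile,
                  phase: np.ndarray, side: str,
                  with_rotations: bool = False):
    """Leg-chain joint/keypoint positions relative to the pelvis path point.

    ``phase`` is the *right-leg* gait phase; the left leg lags by the
    pattern's phase offset.  Positions are expressed in the walkway
    frame with the pelvis progression point at the origin (the constant
    forward translation is added by :func:`build_recording`).
    """
    phase = np.asarray(phase, dtype=float)
    leg_phase = phase if side == "R" else phase - pattern.left_right_phase_offset
    sz = 1.0 if side == "R" else -1.0

    R_pelvis, dy, dz = _pelvis_state(pattern, anthro, phase)
    origin = np.stack([np.zeros_like(phase), anthro.pelvis_height + dy, dz], axis=-1)

    hip_flex = pattern.profile("hip", "sagittal")(leg_phase)
    hip_front = pattern.profile("hip", "frontal")(leg_phase)
    hip_ax = pattern.profile("hip", "transverse")(leg_phase)
    knee_flex = pattern.profile("knee", "sagittal")(leg_phase)
    knee_front = pattern.profile("knee", "frontal")(leg_phase)
    ankle_flex = pattern.profile("ankle", "sagittal")(leg_phase)

    R_thigh = R_pelvis @ joint_rotation("hip", side, hip_flex, hip_front, hip_ax)
    R_shank = R_thigh @ joint_rotation("knee", side, knee_flex, knee_front, 0.0)
    R_foot = R_shank @ joint_rotation("ankle", side, ankle_flex, 0.0, 0.0)

    def off(R, v):
        return (R @ np.asarray(v, dtype=float)[:, None])[..., 0]

    hip = origin + off(R_pelvis, [0.0, 0.0, sz * anthro.pelvis_width / 2.0])
    knee = hip + off(R_thigh, [0.0, -anthro.thigh_length, 0.0])
    ankle = knee + off(R_shank, [0.0, -anthro.shank_length, 0.0])
    fwd = anthro.foot_length - anthro.heel_to_ankle
    heel = ankle + off(R_foot, [-anthro.heel_to_ankle, -anthro.ankle_height, 0.0])
    big_toe = ankle + off(R_foot, [fwd, -anthro.ankle_height, 0.0])
    small_toe = ankle + off(R_foot, [fwd - 0.03, -anthro.ankle_height, sz * 0.05])

    pts = {"hip": hip, "knee": knee, "ankle": ankle, "heel": heel,
           "big_toe": big_toe, "small_toe": small_toe, "pelvis_origin": origin}
    if with_rotations:
        rots = {"pelvis": (R_pelvis, origin), "thigh": (R_thigh, hip),
                "shank": (R_shank, knee), "foot": (R_foot, ankle)}
        return pts, rots
    return pts


def _trunk_points(anthro: AnthropometricProfile, R_pelvis: np.ndarray,
                  origin: np.ndarray) -> dict:
    """Head/trunk/arm keypoints rigidly attached to the pelvis frame."""
    k = anthro.height / _REF_HEIGHT
    offsets = {
        "head_top": (0.0, 0.78, 0.0), "nose": (0.05, 0.64, 0.0),
        "neck": (0.0, 0.47, 0.0), "sternum": (0.0, 0.35, 0.0),
        "mid_spine": (0.0, 0.20, 0.0), "mid_hip": (0.0, 0.0, 0.0),
        "shoulder_L": (0.0, 0.44, -0.185), "shoulder_R": (0.0, 0.44, 0.185),
        "elbow_L": (0.0, 0.14, -0.21), "elbow_R": (0.0, 0.14, 0.21),
        "wrist_L": (0.0, -0.11, -0.22), "wrist_R": (0.0, -0.11, 0.22),
    }
    out = {}
    for name, v in offsets.items():
        vec = np.asarray(v, dtype=float) * k
        out[name] = origin + (R_pelvis @ vec[:, None])[..., 0]
    return out


def build_recording(pattern: GaitPattern,
                    anthro: AnthropometricProfile | None = None,
                    duration: float = 7.0,
                    sample_rate: float = 60.0,
                    start_x: float = 0.3,
                    initial_phase: float = 0.3,
                    walkway_length: float = 10.0) -> GroundTruthRecording:
    """Forward-simulate one walk and return exact ground truth.

    The recording must cover at least 3 full gait cycles.  Events are
    placed analytically: right heel strikes wherever the right-leg phase
    crosses an integer, toe offs at phase = stance fraction, the left
    leg half a cycle later.  ``initial_phase`` sets the phase at the
    first frame (default mid single-support, so no event coincides with
    the recording boundary).
    """
    anthro = anthro or AnthropometricProfile()
    stride_time = pattern.stride_time
    if duration < 3.0 * stride_time:
        raise ValueError(
            f"duration {duration:.2f}s covers fewer than 3 gait cycles "
            f"(stride time {stride_time:.2f}s)")

    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    phase = initial_phase + t / stride_time
    pelvis_x = start_x + pattern.gait_speed * t

    names = list(KEYPOINT_NAMES)
    kp = np.zeros((n, len(names), 3))
    transforms: dict[str, np.ndarray] = {}

    R_pelvis, dy, dz = _pelvis_state(pattern, anthro, phase)
    origin = np.stack([pelvis_x, anthro.pelvis_height + dy, dz], axis=-1)
    transforms["pelvis"] = _to_homogeneous(R_pelvis, origin)

    for name, p in _trunk_points(anthro, R_pelvis, origin).items():
        kp[:, names.index(name), :] = p

    for side in _SIDES:
        pts, rots = _chain_points(pattern, anthro, phase, side, with_rotations=True)
        shift = np.stack([pelvis_x, np.zeros(n), np.zeros(n)], axis=-1)
        for key, pos in pts.items():
            if key == "pelvis_origin":
                continue
            kp[:, names.index(f"{key}_{side}"), :] = pos + shift
        for seg in ("thigh", "shank", "foot"):
            R, p = rots[seg]
            transforms[f"{seg}_{side}"] = _to_homogeneous(R, p + shift)

    stream = SegmentTransformStream(transforms, sample_rate)

    true_angles = {}
    for joint, plane in OUTCOME_PLANES:
        prof = pattern.profile(joint, plane)
        for side in _SIDES:
            leg_phase = phase if side == "R" else phase - pattern.left_right_phase_offset
            true_angles[(joint, plane, side)] = JointAngleSeries(
                joint, plane, side, prof(leg_phase), sample_rate)

    events = _analytic_events(pattern, initial_phase, duration, sample_rate)

    return GroundTruthRecording(
        sample_rate=sample_rate, keypoints3d=kp, keypoint_names=tuple(names),
        segment_transforms=stream, true_angles=true_angles,
        true_events=events, true_params=pattern.true_params(),
        pattern=pattern, anthro=anthro, start_x=start_x,
        walkway_length=walkway_length)


def _to_homogeneous(R: np.ndarray, p: np.ndarray) -> np.ndarray:
    n = p.shape[0]
    T = np.zeros((n, 4, 4))
    T[:, :3, :3] = R
    T[:, :3, 3] = p
    T[:, 3, 3] = 1.0
    return T


def _analytic_events(pattern: GaitPattern, initial_phase: float,
                     duration: float, sample_rate: float) -> list[GaitEvent]:
    stride = pattern.stride_time
    sf = pattern.stance_fraction
    offs = {"R": 0.0, "L": pattern.left_right_phase_offset}
    events = []
    for side, lag in offs.items():
        for etype, ph in ((HEEL_STRIKE, 0.0), (TOE_OFF, sf)):
            k0 = int(np.floor(initial_phase - lag - ph)) - 1
            k = k0
            while True:
                k += 1
                t = (k + lag + ph - initial_phase) * stride
                if t < -1e-9:
                    continue
                if t > duration + 1e-9:
                    break
                events.append(GaitEvent(side, etype, t,
                                        int(round(t * sample_rate)), "truth"))
    events.sort(key=lambda e: e.time)
    return events


# ---------------------------------------------------------------------------

def add_keypoint_noise(recording: GroundTruthRecording, sigma: float,
                       seed: int, assign_confidence: bool = False
                       ) -> GroundTruthRecording:
    """Seed-reproducible i.i.d. Gaussian jitter on the 3D keypoints (m).

    ``sigma = 0`` returns a copy with bit-identical trajectories.  With
    ``assign_confidence`` a per-frame-per-keypoint confidence in [0, 1]
    is attached, decreasing with the injected perturbation magnitude
    (emulating a pose estimator's self-reported certainty).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=recording.keypoints3d.shape) if sigma > 0 \
        else np.zeros_like(recording.keypoints3d)
    conf = None
    if assign_confidence:
        r = np.linalg.norm(noise, axis=-1)
        scale = max(sigma, 1e-12)
        conf = np.exp(-0.5 * (r / (2.0 * scale)) ** 2)
    return dataclasses.replace(
        recording,
        keypoints3d=recording.keypoints3d + noise,
        confidence=conf,
    )
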