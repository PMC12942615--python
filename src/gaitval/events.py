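"""Gait event detection, cycle segmentation and spatiotemporal parameters.

Two event detectors mirror how the three measurement systems work:

* :func:`detect_events_3d` — coordinate-based (Zeni-style) extremum
  detection on pelvis-relative heel/toe displacement along the line of
  progression, as 3D systems (multi-camera markerless, marker-based) do;
* :func:`detect_events_2d` — image-plane rules on a single lateral
  view: heel strike from the pelvis-relative heel extremum in pixels,
  toe off from the toe keypoint leaving its stance-height baseline by a
  metric threshold (converted through the pixel calibration).

Spatiotemporal parameters follow the standard definitions: stride length
is the same-side heel-to-heel distance along the progression axis over
one cycle, step length the contralateral distance at successive
contacts, stance/swing the HS->TO and TO->next-HS durations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "GaitEvent",
    "SpatiotemporalParams",
    "detect_events_3d",
    "detect_events_2d",
    "segment_cycles",
    "representative_cycle",
    "spatiotemporal_params",
    "align_streams",
]

HEEL_STRIKE = "heel_strike"
TOE_OFF = "toe_off"


@dataclass(frozen=True)
class GaitEvent:
    side: str            # "L" | "R"
    type: str            # heel_strike | toe_off
    time: float          # s
    frame: int           # round(time * sample_rate)
    source_method: str   # threeD | twoD | truth

    def shifted(self, offset_s: float, sample_rate: float) -> "GaitEvent":
        t = self.time + offset_s
        return replace(self, time=t, frame=int(round(t * sample_rate)))


@dataclass
class SpatiotemporalParams:
    """The five study outcomes; stance + swing = stride time by definition."""

    gait_speed: float    # m/s
    step_length: float   # m
    stride_length: float  # m
    stance_time: float   # s
    swing_time: float    # s

    def __post_init__(self) -> None:
        for name in ("gait_speed", "step_length", "stride_length",
                     "stance_time", "swing_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def stride_time(self) -> float:
        return self.stance_time + self.swing_time

    def as_dict(self) -> dict[str, float]:
        return {
            "gait_speed": self.gait_speed,
            "step_length": self.step_length,
            "stride_length": self.stride_length,
            "stance_time": self.stance_time,
            "swing_time": self.swing_time,
        }


PARAM_NAMES = ("gait_speed", "step_length", "stride_length", "stance_time", "swing_time")


# ---------------------------------------------------------------------------
# 3D (coordinate-based) detection

def _relative_extrema(signal: np.ndarray, min_distance: int) -> np.ndarray:
    """Peak indices of ``signal`` with a minimum spacing; empty if flat."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 3 or np.ptp(signal) < 1e-9:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(signal, distance=max(1, min_distance),
                          prominence=0.1 * np.ptp(signal))
    return peaks


def _subframe(signal: np.ndarray, i: int) -> float:
    """Sub-frame extremum location by parabolic interpolation around i."""
    if i <= 0 or i >= signal.size - 1:
        return float(i)
    y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-15:
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def estimate_stride_frames(signal: np.ndarray, sample_rate: float) -> float:
    """Dominant-period estimate (frames) of a pelvis-relative limb signal.

    Uses the strongest non-zero Fourier component; robust enough to seed
    the minimum inter-peak distance of the extremum detectors.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    if np.ptp(x) < 1e-9:
        raise ValueError("flat signal: no periodicity to estimate")
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    k = int(np.argmax(spec))
    if freqs[k] <= 0:
        raise ValueError("could not estimate stride period")
    return sample_rate / freqs[k]


def detect_events_3d(heel: np.ndarray, toe: np.ndarray, pelvis: np.ndarray,
                     sample_rate: float, side: str = "R",
                     expected_stride_s: float | None = None) -> list[GaitEvent]:
    """Coordinate-based events for one limb from 3D trajectories.

    Heel strikes are local maxima of the anterior pelvis-relative heel
    displacement ``heel_x - pelvis_x``; toe offs are local maxima of the
    posterior toe displacement ``pelvis_x - toe_x``.  Minimum inter-peak
    distance is half the expected stride time (estimated from the
    signal's dominant period when not given).  A stationary subject
    yields an empty list.
    """
    heel = np.atleast_2d(np.asarray(heel, dtype=float))
    toe = np.atleast_2d(np.asarray(toe, dtype=float))
    pelvis = np.atleast_2d(np.asarray(pelvis, dtype=float))
    if not (heel.shape[0] == toe.shape[0] == pelvis.shape[0]):
        raise ValueError("trajectories must share a common clock and length")
    hs_sig = heel[:, 0] - pelvis[:, 0]
    to_sig = pelvis[:, 0] - toe[:, 0]
    if np.ptp(hs_sig) < 1e-9 and np.ptp(to_sig) < 1e-9:
        return []
    if expected_stride_s is None:
        stride_frames = estimate_stride_frames(hs_sig, sample_rate)
    else:
        stride_frames = expected_stride_s * sample_rate
    dist = int(round(0.5 * stride_frames))
    events = [
        GaitEvent(side, HEEL_STRIKE, _subframe(hs_sig, i) / sample_rate,
                  int(i), "threeD")
        for i in _relative_extrema(hs_sig, dist)
    ]
    events += [
        GaitEvent(side, TOE_OFF, _subframe(to_sig, i) / sample_rate,
                  int(i), "threeD")
        for i in _relative_extrema(to_sig, dist)
    ]
    events.sort(key=lambda e: e.time)
    if sum(e.type == HEEL_STRIKE for e in events) < 2:
        raise ValueError("fewer than one complete gait cycle detected")
    return events


# ---------------------------------------------------------------------------
# 2D (single lateral view) detection

def detect_events_2d(lateral, scale, side: str = "R",
                     toe_off_threshold_m: float = 0.02,
                     hysteresis_frames: int = 2,
                     expected_stride_s: float | None = None) -> list[GaitEvent]:
    """Image-plane events for one limb from the lateral keypoint stream.

    Heel strikes: local maxima of the heel's mid-hip-relative horizontal
    displacement (sign resolved from the walking direction).  Toe offs:
    within each same-side cycle, the first sustained rise of the toe
    keypoint above its stance-phase height baseline by
    ``toe_off_threshold_m`` (converted to pixels through ``scale``)
    marks lift-off; the event time is the toe-height minimum immediately
    preceding that crossing, which is the last frame of ground contact.
    A 2-frame hysteresis suppresses single-frame jitter.
    """
    if scale is None:
        raise ValueError("pixel calibration (CalibrationScale) is required")
    fs = lateral.sample_rate
    heel = lateral.positions(f"heel_{side}")
    toe = lateral.positions(f"big_toe_{side}")
    midhip = lateral.positions("mid_hip")

    direction = 1.0 if midhip[-1, 0] >= midhip[0, 0] else -1.0
    hs_sig = direction * (heel[:, 0] - midhip[:, 0])
    if np.ptp(hs_sig) < 1e-9:
        return []
    if expected_stride_s is None:
        stride_frames = estimate_stride_frames(hs_sig, fs)
    else:
        stride_frames = expected_stride_s * fs
    hs_idx = _relative_extrema(hs_sig, int(round(0.5 * stride_frames)))
    events = [GaitEvent(side, HEEL_STRIKE, _subframe(hs_sig, i) / fs, int(i), "twoD")
              for i in hs_idx]

    # toe height in meters above the (arbitrary) image baseline; v points
    # down.  All toe-off decisions run on a quadratic Savitzky-Golay
    # smoothed copy; the raw-minus-smoothed residual provides the noise
    # scale for the localization band.
    toe_h = -toe[:, 1] * scale.meters_per_pixel
    toe_s = savgol_filter(toe_h, 9, 2) if toe_h.size >= 9 else toe_h
    noise_sigma = 1.4826 * float(np.median(np.abs(toe_h - toe_s)))
    thr = toe_off_threshold_m
    for a, b in zip(hs_idx[:-1], hs_idx[1:]):
        seg_s = toe_s[a:b]
        baseline = np.median(np.sort(seg_s)[: max(3, seg_s.size // 4)])
        above = seg_s > baseline + thr
        # skip the initial descent: at heel strike the toe is still high,
        # so the lift-off search starts only once the foot is down
        contact = np.nonzero(seg_s < baseline + 0.5 * thr)[0]
        if contact.size == 0:
            continue
        crossing = None
        for i in range(int(contact[0]), seg_s.size - hysteresis_frames):
            if above[i: i + hysteresis_frames + 1].all():
                crossing = i
                break
        if crossing is None:
            continue
        # toe off = the last ground-contact instant before the sustained
        # crossing: the last sample still within a noise band of the
        # pre-crossing height minimum, with sub-frame refinement
        c0 = int(contact[0])
        window = seg_s[c0: crossing + 1]
        band = max(0.002, 2.0 * noise_sigma)
        under = np.nonzero(window <= window.min() + band)[0]
        j = c0 + int(under[-1])
        idx = a + j
        events.append(GaitEvent(side, TOE_OFF, (a + _subframe(-seg_s, j)) / fs,
                                int(idx), "twoD"))
    events.sort(key=lambda e: e.time)
    return events


# ---------------------------------------------------------------------------
# cycles and parameters

def segment_cycles(events: list[GaitEvent], side: str) -> list[tuple[float, float]]:
    """Consecutive same-side heel-strike pairs ``[t_HS, t_nextHS]``."""
    hs = sorted(e.time for e in events if e.side == side and e.type == HEEL_STRIKE)
    if len(hs) < 2:
        raise ValueError("need at least 2 same-side heel strikes")
    return list(zip(hs[:-1], hs[1:]))


def representative_cycle(cycles: list[tuple[float, float]],
                         position_x: np.ndarray, time: np.ndarray,
                         center_x: float = 5.0) -> tuple[float, float]:
    """The cycle whose midpoint position is nearest the walkway center.

    Synthetic stand-in for "the cycle crossing the force plate":
    ``position_x`` is the subject's progression coordinate (m) sampled
    at ``time``; the instrumented plate sits at ``center_x``.
    """
    if not cycles:
        raise ValueError("no cycles to select from")
    mids = [0.5 * (a + b) for a, b in cycles]
    pos = np.interp(mids, time, np.asarray(position_x, dtype=float))
    return cycles[int(np.argmin(np.abs(pos - center_x)))]


def _events_of(events, side, etype):
    return sorted((e for e in events if e.side == side and e.type == etype),
                  key=lambda e: e.time)


def spatiotemporal_params(events: list[GaitEvent], heel_x: dict,
                          side: str = "R",
                          cycle_index: int = 0) -> SpatiotemporalParams:
    """Spatiotemporal parameters for one same-side gait cycle.

    ``heel_x`` maps side -> array of heel progression positions (m) at
    that side's successive heel strikes, ordered in time (for the
    single-camera route these are pixel coordinates already scaled to
    meters).  ``cycle_index`` selects which same-side cycle to measure.
    """
    other = "L" if side == "R" else "R"
    hs = _events_of(events, side, HEEL_STRIKE)
    to = _events_of(events, side, TOE_OFF)
    if len(hs) < cycle_index + 2:
        raise ValueError("events do not span the requested cycle")
    t0, t1 = hs[cycle_index].time, hs[cycle_index + 1].time
    stride_time = t1 - t0
    tos_in = [e for e in to if t0 < e.time < t1]
    if not tos_in:
        raise ValueError("no toe-off inside the cycle")
    t_to = tos_in[0].time
    stance = t_to - t0
    swing = t1 - t_to
    if stance <= 0 or swing <= 0:
        raise ValueError("event ordering error: non-positive phase duration")

    x_side = np.asarray(heel_x[side], dtype=float)
    stride_length = abs(x_side[cycle_index + 1] - x_side[cycle_index])

    hs_other = _events_of(events, other, HEEL_STRIKE)
    contra = [(i, e) for i, e in enumerate(hs_other) if t0 < e.time < t1]
    if not contra:
        raise ValueError("no contralateral heel strike inside the cycle")
    i_c, _ = contra[0]
    x_other = np.asarray(heel_x[other], dtype=float)
    step_length = abs(x_other[i_c] - x_side[cycle_index])

    return SpatiotemporalParams(
        gait_speed=stride_length / stride_time,
        step_length=step_length,
        stride_length=stride_length,
        stance_time=stance,
        swing_time=swing,
    )


def positions_at_events(events: list[GaitEvent], position: np.ndarray,
                        time: np.ndarray, side: str,
                        etype: str = HEEL_STRIKE) -> np.ndarray:
    """Trajectory positions linearly interpolated at the event times.

    Events carry sub-frame times, so reading the trajectory at the
    nearest frame would add up to half a frame of travel; interpolation
    removes that bias.
    """
    ts = [e.time for e in _events_of(events, side, etype)]
    return np.interp(ts, np.asarray(time, dtype=float),
                     np.asarray(position, dtype=float))


def align_streams(reference_events: list[GaitEvent],
                  other_events: list[GaitEvent]) -> float:
    """Temporal offset aligning two systems at the first right heel strike.

    Returns ``offset = t_ref(first right HS) - t_other(first right HS)``;
    *adding* the offset to the other system's clock makes the two first
    right heel strikes coincide exactly.
    """
    ref = _events_of(reference_events, "R", HEEL_STRIKE)
    oth = _events_of(other_events, "R", HEEL_STRIKE)
    if not ref or not oth:
        raise ValueError("both event lists need at least one right heel strike")
    return ref[0].time - oth[0].time
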