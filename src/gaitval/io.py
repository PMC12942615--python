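"""Plain-text readers and writers for the package's file interfaces.

All formats are UTF-8 text with ``.`` decimal separators: CSV for
trajectories, keypoints, angles and spatiotemporal tables; JSON for
segment transforms (row-major 16-number 4x4 matrices per segment per
frame), events and agreement reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import KeypointStream
from .events import GaitEvent
from .kinematics import SegmentTransformStream

__all__ = [
    "write_ground_truth_csv", "read_ground_truth_csv",
    "write_keypoints_csv", "read_keypoints_csv",
    "write_transforms_json", "read_transforms_json",
    "write_events_json", "read_events_json",
    "write_angles_csv", "write_spatiotemporal_csv",
]


def write_ground_truth_csv(recording, path) -> None:
    """Long-format 3D keypoints: frame, time_s, keypoint, x_m, y_m, z_m."""
    n, m, _ = recording.keypoints3d.shape
    frames = np.repeat(np.arange(n), m)
    df = pd.DataFrame({
        "frame": frames,
        "time_s": frames / recording.sample_rate,
        "keypoint": list(recording.keypoint_names) * n,
        "x_m": recording.keypoints3d[:, :, 0].ravel(),
        "y_m": recording.keypoints3d[:, :, 1].ravel(),
        "z_m": recording.keypoints3d[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False)


def read_ground_truth_csv(path) -> tuple[np.ndarray, tuple, float]:
    """Returns (keypoints3d, keypoint_names, sample_rate)."""
    df = pd.read_csv(path)
    names = tuple(dict.fromkeys(df["keypoint"]))
    n = df["frame"].nunique()
    kp = df[["x_m", "y_m", "z_m"]].to_numpy().reshape(n, len(names), 3)
    times = df.drop_duplicates("frame")["time_s"].to_numpy()
    rate = 1.0 / np.diff(times).mean() if n > 1 else 60.0
    return kp, names, float(round(rate, 6))


def write_keypoints_csv(stream: KeypointStream, path) -> None:
    """Per-view 2D keypoints: frame, time_s, keypoint, u_px, v_px, confidence."""
    n, m, _ = stream.data.shape
    frames = np.repeat(np.arange(n), m)
    df = pd.DataFrame({
        "frame": frames,
        "time_s": frames / stream.sample_rate + stream.time_offset,
        "keypoint": list(stream.keypoint_names) * n,
        "u_px": stream.data[:, :, 0].ravel(),
        "v_px": stream.data[:, :, 1].ravel(),
        "confidence": stream.data[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False)


def read_keypoints_csv(path, view: str, sample_rate: float = 60.0) -> KeypointStream:
    df = pd.read_csv(path)
    names = tuple(dict.fromkeys(df["keypoint"]))
    n = df["frame"].nunique()
    data = df[["u_px", "v_px", "confidence"]].to_numpy().reshape(n, len(names), 3)
    t0 = float(df["time_s"].iloc[0])
    return KeypointStream(view=view, sample_rate=sample_rate,
                          keypoint_names=names, data=data, time_offset=t0)


def write_transforms_json(stream: SegmentTransformStream, path) -> None:
    payload = {
        "sample_rate": stream.sample_rate,
        "segments": {name: [list(map(float, T.ravel()))
                            for T in stream.transforms[name]]
                     for name in stream.transforms},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_transforms_json(path) -> SegmentTransformStream:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    transforms = {name: np.asarray(mats, dtype=float).reshape(-1, 4, 4)
                  for name, mats in payload["segments"].items()}
    return SegmentTransformStream(transforms, payload["sample_rate"])


def write_events_json(events: list[GaitEvent], path) -> None:
    payload = [{"side": e.side, "type": "HS" if e.type == "heel_strike" else "TO",
                "time_s": e.time} for e in sorted(events, key=lambda e: e.time)]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_events_json(path, sample_rate: float = 60.0) -> list[GaitEvent]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for rec in payload:
        etype = "heel_strike" if rec["type"] == "HS" else "toe_off"
        t = float(rec["time_s"])
        out.append(GaitEvent(rec["side"], etype, t,
                             int(round(t * sample_rate)), "file"))
    return out


def write_angles_csv(rows: list[dict], path) -> None:
    """Angle table: cycle_id, phase_pct, joint, plane, side, angle_deg, system."""
    pd.DataFrame(rows, columns=["cycle_id", "phase_pct", "joint", "plane",
                                "side", "angle_deg", "system"]).to_csv(path, index=False)


def write_spatiotemporal_csv(rows: list[dict], path) -> None:
    cols = ["subject", "trial", "system", "gait_speed_mps", "step_length_m",
            "stride_length_m", "stance_time_s", "swing_time_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
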