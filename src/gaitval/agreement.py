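"""Agreement statistics: ICC(2,1), curve and peak RMSE, reliability bands.

Reliability of spatiotemporal parameters across measurement systems is
quantified with the intraclass correlation coefficient ICC(2,1) —
two-way random effects, absolute agreement, single measurement (the
Shrout–Fleiss convention) — computed here directly from the two-way
ANOVA mean squares.  Kinematic agreement uses RMSE over time-normalized
gait-cycle curves and over per-cycle extrema.  ICC interpretation
follows the conventional bands: < 0.5 poor, 0.5–0.75 moderate,
0.75–0.9 good, >= 0.9 excellent (left-closed at each boundary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import OUTCOME_PLANES
from .events import PARAM_NAMES

__all__ = [
    "icc_2_1",
    "interpret_icc",
    "rmse_curves",
    "extract_peaks",
    "rmse_peaks",
    "AgreementReport",
    "build_report",
]


class DegenerateInputError(ValueError):
    """The ratings matrix carries no variance: ICC is undefined."""


def icc_2_1(matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is an (n_targets, k_raters) complete two-way layout —
    here rows are pooled gait cycles and columns measurement systems.
    From the two-way ANOVA mean squares (rows MSR, columns MSC,
    residual MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    Raises :class:`DegenerateInputError` when the matrix has no variance
    at all (never silently returns NaN) and ``ValueError`` on
    incomplete or undersized input.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings matrix must be 2-D (targets x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete (no missing cells)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300 or ss_total < 1e-300:
        raise DegenerateInputError("ratings matrix has no variance")
    return float((msr - mse) / denom)


def interpret_icc(icc: float) -> str:
    """Reliability band label for an ICC value (total on (-inf, 1])."""
    if icc > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def rmse_curves(a, b) -> float:
    """RMSE (deg) between two time-normalized gait-cycle curves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("curves must be finite")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def extract_peaks(curve) -> tuple[float, float]:
    """Global (max, min) of a normalized cycle curve.

    The phase of each extremum (percent of the gait cycle) is available
    through :func:`peak_phases` when needed as metadata.
    """
    c = np.asarray(curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty curve")
    return float(c.max()), float(c.min())


def peak_phases(curve) -> tuple[float, float]:
    """Phases (% cycle) at which the max and min of the curve occur."""
    c = np.asarray(curve, dtype=float)
    scale = 100.0 / (c.size - 1)
    return float(np.argmax(c) * scale), float(np.argmin(c) * scale)


def rmse_peaks(peaks_test, peaks_ref) -> float:
    """RMSE (deg) between paired per-cycle extremum values."""
    a = np.asarray(peaks_test, dtype=float)
    b = np.asarray(peaks_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("peak lists must be paired (equal length)")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# study-level report

@dataclass
class AgreementReport:
    """Per-parameter ICC + band and per-joint/plane RMSE summaries.

    ``parameters``: name -> {system: {"mean":, "sd":}} plus
    ``icc``: name -> {system: {"value":, "band":}} for each test system
    against the reference.  ``kinematics``: "joint_plane" -> {system:
    {"cycle_rmse":, "peak_max_rmse":, "peak_min_rmse":}}.
    """

    reference: str
    systems: tuple[str, ...]
    parameters: dict
    icc: dict
    kinematics: dict

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "reference": self.reference,
            "systems": list(self.systems),
            "parameters": self.parameters,
            "icc": self.icc,
            "kinematics": self.kinematics,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    def parameter_table(self) -> pd.DataFrame:
        """Table-1-style summary: mean +- SD per system and ICC columns."""
        rows = []
        for name in self.parameters:
            row = {"parameter": name}
            for sys_name, stats in self.parameters[name].items():
                row[sys_name] = f"{stats['mean']:.3f} ± {stats['sd']:.3f}"
            for sys_name, entry in self.icc.get(name, {}).items():
                row[f"ICC ({sys_name})"] = round(entry["value"], 3)
            rows.append(row)
        return pd.DataFrame(rows)

    def kinematics_table(self) -> pd.DataFrame:
        rows = []
        for jp, per_sys in self.kinematics.items():
            for sys_name, stats in per_sys.items():
                rows.append({"joint_plane": jp, "system": sys_name, **stats})
        return pd.DataFrame(rows)


def build_report(results: dict, reference: str,
                 rmse_aggregation: str = "per_cycle") -> AgreementReport:
    """Agreement report across measurement systems.

    ``results`` maps system label -> list of per-cycle results (objects
    with ``params`` — a SpatiotemporalParams — and ``curves`` — a dict
    ``(joint, plane)`` -> 101-point array); the lists must be pooled in
    the same order for every system.  ICC(2,1) is computed per parameter
    for each test system against the reference as a two-column matrix of
    pooled cycles.  Curve RMSE is computed per cycle then averaged
    (``rmse_aggregation="per_cycle"``) or on the pooled concatenated
    points (``"pooled"``).
    """
    if reference not in results:
        raise ValueError(f"reference system {reference!r} missing from results")
    if len(results) < 2:
        raise ValueError("need at least 2 systems to compare")
    if rmse_aggregation not in ("per_cycle", "pooled"):
        raise ValueError("rmse_aggregation must be 'per_cycle' or 'pooled'")
    n_cycles = {s: len(r) for s, r in results.items()}
    if len(set(n_cycles.values())) != 1:
        raise ValueError(f"mismatched pooled cycle counts across systems: {n_cycles}")

    systems = tuple(results)
    tests = [s for s in systems if s != reference]

    parameters: dict = {}
    icc: dict = {}
    for name in PARAM_NAMES:
        values = {s: np.array([getattr(r.params, name) for r in results[s]])
                  for s in systems}
        parameters[name] = {
            s: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for s, v in values.items()
        }
        icc[name] = {}
        for s in tests:
            mat = np.column_stack([values[s], values[reference]])
            try:
                val = icc_2_1(mat)
            except DegenerateInputError:
                val = 1.0 if np.allclose(mat[:, 0], mat[:, 1]) else float("nan")
            icc[name][s] = {"value": val, "band": interpret_icc(val)}

    kinematics: dict = {}
    for joint, plane in OUTCOME_PLANES:
        key = f"{joint}_{plane}"
        kinematics[key] = {}
        ref_curves = [r.curves[(joint, plane)] for r in results[reference]]
        for s in tests:
            test_curves = [r.curves[(joint, plane)] for r in results[s]]
            if rmse_aggregation == "per_cycle":
                cycle_rmse = float(np.mean([
                    rmse_curves(a, b) for a, b in zip(test_curves, ref_curves)]))
            else:
                cycle_rmse = rmse_curves(np.concatenate(test_curves),
                                         np.concatenate(ref_curves))
            maxes_t, mins_t = zip(*(extract_peaks(c) for c in test_curves))
            maxes_r, mins_r = zip(*(extract_peaks(c) for c in ref_curves))
            kinematics[key][s] = {
                "cycle_rmse": cycle_rmse,
                "peak_max_rmse": rmse_peaks(maxes_t, maxes_r),
                "peak_min_rmse": rmse_peaks(mins_t, mins_r),
            }

    return AgreementReport(reference=reference, systems=systems,
                           parameters=parameters, icc=icc,
                           kinematics=kinematics)
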