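import numpy as np
import pytest

from gaitval import camera as cam
from gaitval import synthetic as sg


@pytest.fixture(scope="session")
def anthro():
    return sg.AnthropometricProfile()


@pytest.fixture(scope="session")
def pattern(anthro):
    return sg.default_pattern(anthro)


@pytest.fixture(scope="session")
def recording(pattern, anthro):
    return sg.build_recording(pattern, anthro, duration=7.0)


@pytest.fixture(scope="session")
def sagittal_recording(anthro):
    pat = sg.default_pattern(anthro, sagittal_only=True)
    return sg.build_recording(pat, anthro, duration=7.0)


@pytest.fixture(scope="session")
def ortho_lateral():
    """Far-field (orthographic) lateral camera, feet-to-head in frame."""
    return cam.lateral_camera(distance=50.0, focal_px=1500.0 * 50.0 / 3.0,
                              mode="orthographic")


@pytest.fixture(scope="session")
def ortho_frontal():
    return cam.frontal_camera(focal_px=1500.0 * 6.0, mode="orthographic")


@pytest.fixture(scope="session")
def ortho_scale(ortho_lateral):
    return cam.CalibrationScale(
        meters_per_pixel=ortho_lateral.nominal_depth / ortho_lateral.focal_px)


def match_events(detected, truth_events, sample_rate=60.0):
    """Frame errors of true events inside the detected coverage span."""
    errors = []
    for etype in ("heel_strike", "toe_off"):
        dts = [e for e in detected if e.type == etype]
        if not dts:
            continue
        lo = min(e.time for e in dts) - 1.0 / sample_rate
        hi = max(e.time for e in dts) + 1.0 / sample_rate
        trues = [e for e in truth_events if e.type == etype and lo <= e.time <= hi]
        for t in trues:
            nearest = min(dts, key=lambda d: abs(d.time - t.time))
            errors.append(abs(nearest.time - t.time) * sample_rate)
    return errors
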