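import numpy as np
import pytest

from mpiflow.curves import (
    IntensityCurve,
    estimate_baseline,
    interpolate,
    subtract_baseline,
)
from mpiflow.geometry import TubeGeometry
from mpiflow.simulate import BolusSimConfig


def make_curve(times, intensities, factor=10, baseline_window=None):
    """Interpolated, baseline-subtracted curve from raw samples."""
    curve = interpolate(IntensityCurve(np.asarray(times), np.asarray(intensities)), factor)
    estimate_baseline(curve, baseline_window)
    return subtract_baseline(curve)


@pytest.fixture
def tube_4mm():
    return TubeGeometry(inner_diameter_mm=4.0)


@pytest.fixture
def tube_6mm():
    return TubeGeometry(inner_diameter_mm=6.0)


@pytest.fixture
def noiseless_config(tube_4mm):
    """A clean transit at a resting coronary velocity."""
    return BolusSimConfig(
        velocity_cm_s=20.6,
        geometry=tube_4mm,
        noise_sd=0.0,
        baseline_level=0.0,
        seed=0,
    )
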