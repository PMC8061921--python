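"""The two bolus surveying techniques: FDHM and adapted tracer dilution.

FDHM (full duration at half maximum) measures how long at least half of
the peak signal intensity is present while the bolus crosses the field of
view; with the longitudinal FOV size ``s`` and a per-tube correction
factor ``c`` the mean velocity is ``v = c * s / FDHM``.

The tracer-dilution (TD) technique adapts the Stewart-Hamilton indicator
dilution principle from temperature to image intensity: the flow is
``Q = epsilon / AUC``, where AUC is the area under the baseline-subtracted
time-intensity curve between the onset crossing and the 33%-of-peak
decline point, and ``epsilon`` is a calibration factor absorbing injected
amount, initial intensity and the dilution constant.  Dividing by the
lumen cross-section ``A`` gives ``v = epsilon / (A * AUC)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import IntensityCurve
from .errors import (
    BaselineStateError,
    DomainError,
    OnsetDetectionError,
    TruncatedBolusError,
)
from .geometry import TubeGeometry

__all__ = [
    "VelocityEstimate",
    "compute_fdhm",
    "velocity_from_fdhm",
    "compute_auc",
    "velocity_from_auc",
    "flow_from_auc",
    "pressure_gradient",
]

_MM_PER_CM = 10.0


@dataclass
class VelocityEstimate:
    """One bolus's raw statistic, calibration factor and resulting velocity.

    ``method`` is ``"fdhm"`` or ``"td"``; ``raw_statistic`` is the FDHM
    duration (s) or the AUC (a.u.*s); ``correction_factor`` is ``c``
    (dimensionless) or ``epsilon`` (composite calibration units).
    """

    method: str
    raw_statistic: float
    correction_factor: float
    velocity_cm_s: float
    velocity_error_cm_s: float = 0.0
    auc_bounds: tuple[float, float] | None = None


def _cross_time(t0: float, x0: float, t1: float, x1: float, level: float) -> float:
    """Linear-interpolation crossing time of `level` between two samples."""
    if x1 == x0:
        return t0
    return t0 + (level - x0) * (t1 - t0) / (x1 - x0)


def compute_fdhm(curve: IntensityCurve) -> float:
    """Duration for which the signal stays at or above half its maximum.

    Uses the contiguous half-maximum interval around the global peak; the
    crossing on each side is refined linearly between the two bracketing
    samples.  Requires the curve to dip below half maximum on both sides
    of the peak (otherwise the transit is truncated).
    """
    x = curve.intensities
    t = curve.times
    if len(x) < 3:
        raise TruncatedBolusError("curve too short for FDHM")
    i_peak = int(np.argmax(x))
    half = 0.5 * float(x[i_peak])
    if half <= 0:
        raise DomainError("non-positive peak intensity; was the baseline subtracted?")

    below_left = np.nonzero(x[:i_peak] < half)[0]
    if len(below_left) == 0:
        raise TruncatedBolusError("signal never below half maximum before the peak")
    j = int(below_left[-1])
    t_left = _cross_time(t[j], x[j], t[j + 1], x[j + 1], half)

    below_right = np.nonzero(x[i_peak:] < half)[0]
    if len(below_right) == 0:
        raise TruncatedBolusError("signal never below half maximum after the peak")
    k = i_peak + int(below_right[0])
    t_right = _cross_time(t[k - 1], x[k - 1], t[k], x[k], half)

    return float(t_right - t_left)


def velocity_from_fdhm(fdhm_s: float, fov_length_mm: float, c: float) -> float:
    """Mean velocity ``v = c * s / FDHM`` in cm/s (``s`` given in mm)."""
    if fdhm_s <= 0:
        raise DomainError(f"fdhm must be > 0, got {fdhm_s}")
    if fov_length_mm <= 0 or c <= 0:
        raise DomainError("fov length and correction factor must be > 0")
    return c * (fov_length_mm / _MM_PER_CM) / fdhm_s


def compute_auc(
    curve: IntensityCurve,
    onset_multiple: float = 1.0,
    decline_fraction: float = 0.33,
) -> tuple[float, float, float]:
    """Area under the baseline-subtracted curve between onset and decline.

    The integration starts where the subtracted curve first rises to the
    baseline mean level (``onset_multiple`` times it, i.e. where the raw
    signal reaches twice the baseline for the default multiple) and ends
    where the signal first falls to ``decline_fraction`` of the maximum
    after the peak — the tail is cut there because its end is hidden in
    background noise.  Integration is trapezoidal with the exact crossing
    times inserted as boundary points.

    Returns ``(auc, t_start, t_end)``.
    """
    if curve.baseline_value is None:
        raise BaselineStateError("compute_auc requires a recorded baseline")
    if not curve.is_baseline_subtracted:
        raise BaselineStateError("compute_auc requires a baseline-subtracted curve")
    if not 0 < decline_fraction < 1:
        raise DomainError("decline_fraction must be in (0, 1)")
    x = curve.intensities
    t = curve.times
    i_peak = int(np.argmax(x))
    i_max = float(x[i_peak])
    if i_max <= 0:
        raise DomainError("non-positive peak intensity")

    onset_level = onset_multiple * curve.baseline_value
    if onset_level > 0:
        at_or_above = np.nonzero(x >= onset_level)[0]
    else:
        at_or_above = np.nonzero(x > 0)[0]
        onset_level = 0.0
    if len(at_or_above) == 0 or at_or_above[0] > i_peak:
        raise OnsetDetectionError("no onset crossing found before the peak")
    i_on = int(at_or_above[0])
    if i_on == 0:
        t_start = float(t[0])
    else:
        t_start = _cross_time(t[i_on - 1], x[i_on - 1], t[i_on], x[i_on], onset_level)

    decline_level = decline_fraction * i_max
    below = np.nonzero(x[i_peak:] <= decline_level)[0]
    if len(below) == 0:
        raise TruncatedBolusError(
            "signal never declines to the AUC end level; transit truncated"
        )
    i_end = i_peak + int(below[0])
    t_end = _cross_time(t[i_end - 1], x[i_end - 1], t[i_end], x[i_end], decline_level)

    # assemble integration grid with exact boundary values
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    xx = np.concatenate(
        ([np.interp(t_start, t, x)], x[inside], [np.interp(t_end, t, x)])
    )
    auc = float(np.trapezoid(xx, tt))
    return auc, float(t_start), float(t_end)


def velocity_from_auc(auc: float, epsilon: float, geometry: TubeGeometry) -> float:
    """Mean velocity ``v = epsilon / (A * AUC)`` in cm/s."""
    if auc <= 0:
        raise DomainError(f"auc must be > 0, got {auc}")
    if epsilon <= 0:
        raise DomainError(f"epsilon must be > 0, got {epsilon}")
    return epsilon / (geometry.area_cm2 * auc)


def flow_from_auc(auc: float, epsilon: float) -> float:
    """Volumetric flow ``Q = epsilon / AUC`` (units set by epsilon's)."""
    if auc <= 0:
        raise DomainError(f"auc must be > 0, got {auc}")
    return epsilon / auc


def pressure_gradient(velocity_m_s: float) -> float:
    """Modified Bernoulli pressure gradient ``dp = 4 * v**2``.

    ``v`` in m/s gives ``dp`` in mmHg (clinical jet-velocity convention).
    """
    if velocity_m_s < 0:
        raise DomainError(f"velocity must be >= 0, got {velocity_m_s}")
    return 4.0 * velocity_m_s * velocity_m_s
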