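"""Intrinsic correction factors and leave-one-out cross-validation.

Each measurement series (repeated boluses at one phantom setting) yields
one intrinsic correction factor (iCF) per measurement: the ratio of the
flow-meter ground-truth velocity to the measurement's uncalibrated
velocity kernel (``s / FDHM`` for the FDHM technique, ``1 / (A * AUC)``
for tracer dilution).  A measurement's calibrated velocity uses the mean
of the *complementary* intrinsic factors of its series (leave-one-out
cross-validation), and its error is the standard error of the mean of
those complementary factors, propagated through the same kernel.

A series' mean factor can also be transferred to another series — e.g.
calibrating a stenotic tube with the factor of a non-stenotic one — which
is how the feasibility of non-stenotic calibration is assessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CalibrationMismatchError,
    DomainError,
    EmptyInputError,
    InsufficientSeriesError,
)
from .estimators import VelocityEstimate
from .geometry import FlowSetting, TubeGeometry

__all__ = [
    "CalibrationFactor",
    "CalibrationSeries",
    "raw_kernel",
    "intrinsic_factor",
    "loo_calibrate",
    "series_mean_factor",
    "transfer_calibration",
]

_VALID_METHODS = ("fdhm", "td")


def raw_kernel(raw_statistic: float, method: str, geometry: TubeGeometry) -> float:
    """Uncalibrated velocity kernel: velocity per unit correction factor.

    FDHM: ``s / FDHM`` (cm/s per unit c); TD: ``1 / (A * AUC)``.
    """
    if method not in _VALID_METHODS:
        raise CalibrationMismatchError(f"unknown method {method!r}")
    if raw_statistic <= 0:
        raise DomainError(f"raw statistic must be > 0, got {raw_statistic}")
    if method == "fdhm":
        return geometry.fov_length_cm / raw_statistic
    return 1.0 / (geometry.area_cm2 * raw_statistic)


def intrinsic_factor(
    raw_statistic: float, method: str, v_ref_cm_s: float, geometry: TubeGeometry
) -> float:
    """Per-measurement correction factor against ground-truth velocity.

    Inverts the velocity formula: ``c = v_ref * FDHM / s`` for FDHM,
    ``epsilon = v_ref * A * AUC`` for tracer dilution.
    """
    if v_ref_cm_s <= 0:
        raise DomainError(f"reference velocity must be > 0, got {v_ref_cm_s}")
    return v_ref_cm_s / raw_kernel(raw_statistic, method, geometry)


@dataclass(frozen=True)
class CalibrationFactor:
    """A (mean factor, SEM) pair tied to the method it calibrates."""

    value: float
    sem: float
    method: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DomainError("calibration factor must be > 0")


@dataclass
class CalibrationSeries:
    """Repeated measurements of one setting, with calibration state.

    ``raw_statistics`` and ``reference_velocities`` are per measurement;
    the remaining arrays are filled in by :func:`loo_calibrate`.
    """

    method: str
    geometry: TubeGeometry
    raw_statistics: np.ndarray
    reference_velocities: np.ndarray
    setting: FlowSetting | None = None
    intrinsic_factors: np.ndarray = field(default_factory=lambda: np.empty(0))
    loo_factors: np.ndarray = field(default_factory=lambda: np.empty(0))
    loo_sems: np.ndarray = field(default_factory=lambda: np.empty(0))
    calibrated_velocities: np.ndarray = field(default_factory=lambda: np.empty(0))
    velocity_errors: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.raw_statistics = np.asarray(self.raw_statistics, dtype=float)
        self.reference_velocities = np.asarray(self.reference_velocities, dtype=float)
        if self.method not in _VALID_METHODS:
            raise CalibrationMismatchError(f"unknown method {self.method!r}")
        if self.raw_statistics.shape != self.reference_velocities.shape:
            raise DomainError("raw statistics and reference velocities differ in length")

    def __len__(self) -> int:
        return len(self.raw_statistics)

    @property
    def kernels(self) -> np.ndarray:
        return np.array(
            [raw_kernel(r, self.method, self.geometry) for r in self.raw_statistics]
        )


def loo_calibrate(series: CalibrationSeries) -> CalibrationSeries:
    """Fill in intrinsic factors, leave-one-out means/SEMs and velocities.

    For measurement ``i`` the calibrated velocity is
    ``mean(factors except i) * kernel_i`` and its error
    ``SEM(factors except i) * kernel_i``.  The mean of the leave-one-out
    factors equals the mean of the intrinsic factors exactly.
    """
    n = len(series)
    if n < 2:
        raise InsufficientSeriesError(
            f"leave-one-out calibration needs >= 2 measurements, got {n}"
        )
    kernels = series.kernels
    factors = series.reference_velocities / kernels
    loo = np.empty(n)
    sems = np.empty(n)
    for i in range(n):
        rest = np.delete(factors, i)
        loo[i] = rest.mean()
        sems[i] = rest.std(ddof=1) / np.sqrt(len(rest)) if len(rest) > 1 else 0.0
    series.intrinsic_factors = factors
    series.loo_factors = loo
    series.loo_sems = sems
    series.calibrated_velocities = loo * kernels
    series.velocity_errors = sems * kernels
    return series


def series_mean_factor(series: CalibrationSeries) -> CalibrationFactor:
    """Mean and SEM of a series' intrinsic factors.

    Equals the mean of the leave-one-out factors.  A single-measurement
    series has no defined SEM; it is reported as 0 with a warning.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot summarize an empty series")
    if series.intrinsic_factors.size == 0:
        kernels = series.kernels
        factors = series.reference_velocities / kernels
    else:
        factors = series.intrinsic_factors
    if len(factors) == 1:
        warnings.warn("single-measurement series: SEM undefined, reported as 0")
        return CalibrationFactor(float(factors[0]), 0.0, series.method)
    sem = float(factors.std(ddof=1) / np.sqrt(len(factors)))
    return CalibrationFactor(float(factors.mean()), sem, series.method)


def transfer_calibration(
    target_raws: np.ndarray | list[float],
    method: str,
    source: CalibrationFactor,
    geometry: TubeGeometry,
) -> list[VelocityEstimate]:
    """Apply another series' mean factor to raw statistics of this one.

    Velocities are ``source.value * kernel_i``; errors propagate
    ``source.sem * kernel_i``.  The source factor must come from the same
    surveying technique.
    """
    if source.method != method:
        raise CalibrationMismatchError(
            f"source factor is for {source.method!r}, target raws are {method!r}"
        )
    estimates = []
    for raw in np.asarray(target_raws, dtype=float):
        k = raw_kernel(float(raw), method, geometry)
        estimates.append(
            VelocityEstimate(
                method=method,
                raw_statistic=float(raw),
                correction_factor=source.value,
                velocity_cm_s=source.value * k,
                velocity_error_cm_s=source.sem * k,
            )
        )
    return estimates
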