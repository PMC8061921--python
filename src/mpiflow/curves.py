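"""From 4D image sequences to analyzable time-intensity curves.

The processing order mirrors the measurement pipeline: sum each frame to a
scalar intensity, linearly interpolate the curve (factor 10 by default),
estimate and subtract the pre-arrival baseline, then run a bolus-shape
quality check.  Only curves passing QC go on to the velocity estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    BaselineStateError,
    DomainError,
    EmptyInputError,
    InvalidWindowError,
)

__all__ = [
    "ImageSequence",
    "IntensityCurve",
    "QCFlag",
    "QCReport",
    "frame_intensity_curve",
    "interpolate",
    "auto_baseline_window",
    "estimate_baseline",
    "subtract_baseline",
    "qc_bolus",
]


@dataclass
class ImageSequence:
    """A 4D intensity grid indexed (x, y, z, t) with uniform frame timing.

    x is the flow direction; a *frame* is the 3D volume at one time point.
    """

    frames: np.ndarray
    frame_interval_s: float
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise DomainError(
                f"frames must be 4-D (x, y, z, t), got shape {self.frames.shape}"
            )
        if self.frame_interval_s <= 0:
            raise DomainError("frame_interval_s must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise DomainError("frames contain non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]


@dataclass
class IntensityCurve:
    """A frame-summed signal-intensity-over-time curve.

    Baseline and interpolation state ride along with the samples so that
    downstream estimators can rely on what has already been done to the
    curve (and so that baseline subtraction is idempotent).
    ``baseline_window`` is a half-open index range on the *current* grid.
    """

    times: np.ndarray
    intensities: np.ndarray
    interpolation_factor: int = 1
    baseline_value: float | None = None
    baseline_window: tuple[int, int] | None = None
    baseline_noise_sd: float | None = None
    is_baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise DomainError("times and intensities must be equal-length 1-D")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise DomainError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise DomainError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise DomainError("curve has fewer than two samples")
        return float(self.times[1] - self.times[0])

    def copy(self) -> "IntensityCurve":
        return replace(
            self, times=self.times.copy(), intensities=self.intensities.copy()
        )


class QCFlag(str, Enum):
    MULTIPLE_PEAKS = "multiple_peaks"
    LOW_SNR = "low_snr"
    DISTORTED_SHAPE = "distorted_shape"
    TRUNCATED = "truncated"


@dataclass
class QCReport:
    """Outcome of the bolus-shape check; ``passed`` iff no reasons."""

    reasons: list[QCFlag] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def frame_intensity_curve(seq: ImageSequence) -> IntensityCurve:
    """Sum every frame's voxels into one intensity sample per time point."""
    if seq.n_frames == 0 or seq.frames.size == 0:
        raise EmptyInputError("image sequence has no frames")
    intensities = seq.frames.sum(axis=(0, 1, 2))
    times = np.arange(seq.n_frames) * seq.frame_interval_s
    return IntensityCurve(times=times, intensities=intensities)


def interpolate(curve: IntensityCurve, factor: int = 10) -> IntensityCurve:
    """Piecewise-linear resampling by an integer refinement factor.

    Output has ``(n - 1) * factor + 1`` samples; the original nodes are
    preserved exactly.  Factor 1 returns an unchanged copy.
    """
    if factor < 1 or int(factor) != factor:
        raise DomainError(f"interpolation factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return curve.copy()
    n = len(curve.times)
    if n < 2:
        raise DomainError("cannot interpolate a curve with fewer than two samples")
    fine_idx = np.arange((n - 1) * factor + 1) / factor
    coarse_idx = np.arange(n)
    times = curve.times[0] + fine_idx * curve.dt
    # exact node preservation: overwrite every factor-th sample
    intensities = np.interp(fine_idx, coarse_idx, curve.intensities)
    intensities[::factor] = curve.intensities
    out = replace(curve, times=times, intensities=intensities)
    out.interpolation_factor = curve.interpolation_factor * factor
    if curve.baseline_window is not None:
        lo, hi = curve.baseline_window
        out.baseline_window = (lo * factor, (hi - 1) * factor + 1)
    return out


def auto_baseline_window(curve: IntensityCurve, min_len: int = 3) -> tuple[int, int]:
    """Detect the pre-arrival baseline window.

    Takes the robust level (median) and spread (scaled MAD) of the first
    10% of samples and returns the longest initial run of samples that stay
    within 4x that spread of the level.  Assumes the record starts before
    bolus arrival.
    """
    x = curve.intensities
    n = len(x)
    if n < min_len:
        raise InvalidWindowError("curve too short for baseline detection")
    head = x[: max(min_len, n // 10)]
    med = float(np.median(head))
    mad = float(np.median(np.abs(head - med))) * 1.4826
    scale = max(float(np.max(np.abs(x))), 1.0)
    tol = 4.0 * max(mad, 1e-12 * scale)
    above = np.abs(x - med) > tol
    run = int(np.argmax(above)) if above.any() else n
    run = max(run, min_len)
    return (0, min(run, n))


def estimate_baseline(
    curve: IntensityCurve, window: tuple[int, int] | None = None
) -> float:
    """Mean intensity over a pre-arrival window; records baseline state.

    ``window`` is a half-open index range; if omitted it is auto-detected
    with :func:`auto_baseline_window`.  The window must not contain the
    global intensity maximum.  The sample standard deviation over the
    window is stored as the curve's noise estimate.
    """
    if window is None:
        window = auto_baseline_window(curve)
    lo, hi = int(window[0]), int(window[1])
    if hi <= lo or lo < 0 or hi > len(curve.intensities):
        raise InvalidWindowError(f"empty or out-of-range window {window}")
    values = curve.intensities[lo:hi]
    # reject windows containing a genuine bolus peak: the global maximum
    # lies inside and clearly exceeds the window's own noise band
    i_peak = int(np.argmax(curve.intensities))
    if lo <= i_peak < hi:
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med))) * 1.4826
        scale = max(float(np.max(np.abs(curve.intensities))), 1.0)
        if curve.intensities[i_peak] > med + max(4.0 * mad, 1e-9 * scale):
            raise InvalidWindowError(
                f"baseline window {window} overlaps the intensity peak "
                f"at index {i_peak}"
            )
    baseline = float(np.mean(values))
    curve.baseline_value = baseline
    curve.baseline_window = (lo, hi)
    curve.baseline_noise_sd = float(np.std(values, ddof=1)) if hi - lo > 1 else 0.0
    return baseline


def subtract_baseline(curve: IntensityCurve) -> IntensityCurve:
    """Subtract the recorded baseline level from every sample.

    Idempotent: subtraction state is recorded on the curve, so a second
    call returns the curve unchanged rather than re-estimating a baseline
    on already-subtracted data.
    """
    if curve.baseline_value is None:
        raise BaselineStateError(
            "no baseline recorded; call estimate_baseline first"
        )
    if curve.is_baseline_subtracted:
        return curve.copy()
    out = curve.copy()
    out.intensities = out.intensities - curve.baseline_value
    out.is_baseline_subtracted = True
    return out


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def qc_bolus(
    curve: IntensityCurve,
    snr_min: float = 5.0,
    decline_fraction: float = 0.33,
) -> QCReport:
    """Decide whether a curve is an analyzable single-bolus transit.

    A curve passes when, after smoothing with a moving average one original
    frame wide, (i) exactly one local maximum exceeds half the global
    maximum, (ii) the peak amplitude exceeds ``snr_min`` times the
    baseline-window noise level, and (iii) the signal falls back below
    ``decline_fraction`` of the maximum before the record ends.
    """
    report = QCReport()
    x = curve.intensities
    if len(x) < 3:
        report.reasons.append(QCFlag.TRUNCATED)
        return report

    smoothed = _smooth(x, max(1, curve.interpolation_factor))
    peak_val = float(np.max(smoothed))
    i_peak = int(np.argmax(smoothed))

    if curve.baseline_noise_sd is not None:
        noise = curve.baseline_noise_sd
    else:
        head = x[: max(3, len(x) // 10)]
        noise = float(np.std(head, ddof=1))
    baseline_ref = 0.0 if curve.is_baseline_subtracted else float(np.min(smoothed))
    amplitude = peak_val - baseline_ref
    if noise > 0 and amplitude < snr_min * noise:
        report.reasons.append(QCFlag.LOW_SNR)

    if i_peak == 0 or i_peak == len(smoothed) - 1:
        report.reasons.append(QCFlag.TRUNCATED)
        return report
    tail = smoothed[i_peak:]
    if float(np.min(tail)) > baseline_ref + decline_fraction * amplitude:
        report.reasons.append(QCFlag.TRUNCATED)

    # a prominence floor keeps residual noise ripples near the peak from
    # counting as separate maxima; a genuine second bolus peak clears it
    peaks, _ = find_peaks(
        smoothed,
        height=baseline_ref + 0.5 * amplitude,
        prominence=0.05 * amplitude,
    )
    if len(peaks) == 0:
        report.reasons.append(QCFlag.DISTORTED_SHAPE)
    elif len(peaks) > 1:
        report.reasons.append(QCFlag.MULTIPLE_PEAKS)
    return report
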