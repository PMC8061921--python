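import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_curve
from mpiflow.curves import (
    ImageSequence,
    IntensityCurve,
    QCFlag,
    auto_baseline_window,
    estimate_baseline,
    frame_intensity_curve,
    interpolate,
    qc_bolus,
    subtract_baseline,
)
from mpiflow.errors import (
    BaselineStateError,
    DomainError,
    EmptyInputError,
    InvalidWindowError,
)
from mpiflow.simulate import BolusSimConfig, simulate_curve, simulate_stack


class TestFrameSum:
    def test_all_ones(self):
        seq = ImageSequence(np.ones((28, 28, 14, 5)), frame_interval_s=0.02154)
        curve = frame_intensity_curve(seq)
        np.testing.assert_allclose(curve.intensities, 28 * 28 * 14)
        np.testing.assert_allclose(curve.times, np.arange(5) * 0.02154)

    def test_all_zero(self):
        seq = ImageSequence(np.zeros((4, 4, 4, 3)), frame_interval_s=0.1)
        assert frame_intensity_curve(seq).intensities.sum() == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5, 5, 4))
        b = rng.random((5, 5, 5, 4))
        ca = frame_intensity_curve(ImageSequence(a, 0.1)).intensities
        cb = frame_intensity_curve(ImageSequence(b, 0.1)).intensities
        cab = frame_intensity_curve(ImageSequence(2 * a + 3 * b, 0.1)).intensities
        np.testing.assert_allclose(cab, 2 * ca + 3 * cb, rtol=1e-12)

    def test_matches_simulated_curve(self, tube_4mm):
        cfg = BolusSimConfig(
            velocity_cm_s=30.0, geometry=tube_4mm, noise_sd=0.0, baseline_level=2.0
        )
        curve, _ = simulate_curve(cfg)
        stack, _ = simulate_stack(cfg)
        summed = frame_intensity_curve(stack)
        scale = float(curve.intensities.max())
        assert np.max(np.abs(summed.intensities - curve.intensities)) < 0.01 * scale

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            frame_intensity_curve(ImageSequence(np.empty((2, 2, 2, 0)), 0.1))


class TestInterpolate:
    def test_factor_one_is_identity(self):
        curve = IntensityCurve(np.arange(5.0), np.array([1.0, 3, 2, 5, 4]))
        out = interpolate(curve, 1)
        np.testing.assert_array_equal(out.intensities, curve.intensities)

    def test_linear_midpoint(self):
        curve = IntensityCurve(np.array([0.0, 1.0]), np.array([0.0, 10.0]))
        out = interpolate(curve, 10)
        assert len(out.times) == 11
        assert out.intensities[5] == pytest.approx(5.0)
        assert out.interpolation_factor == 10

    def test_nodes_preserved_and_extrema_unchanged(self):
        rng = np.random.default_rng(1)
        curve = IntensityCurve(np.arange(20.0) * 0.5, rng.random(20))
        out = interpolate(curve, 10)
        np.testing.assert_array_equal(out.intensities[::10], curve.intensities)
        assert out.intensities.max() == curve.intensities.max()
        assert out.intensities.min() == curve.intensities.min()

    def test_peak_time_preserved(self):
        curve = IntensityCurve(np.arange(10.0), np.array([0, 1, 2, 5, 3, 2, 1, 0, 0, 0.0]))
        out = interpolate(curve, 10)
        t_peak = out.times[np.argmax(out.intensities)]
        assert abs(t_peak - 3.0) <= out.dt

    @settings(derandomize=True, max_examples=30)
    @given(factor=st.integers(min_value=1, max_value=20))
    def test_output_length(self, factor):
        curve = IntensityCurve(np.arange(7.0), np.arange(7.0) ** 2)
        assert len(interpolate(curve, factor).times) == 6 * factor + 1

    def test_invalid_factor(self):
        curve = IntensityCurve(np.arange(3.0), np.ones(3))
        with pytest.raises(DomainError):
            interpolate(curve, 0)


class TestBaseline:
    def test_constant_curve(self):
        curve = IntensityCurve(np.arange(10.0), np.full(10, 5.0))
        assert estimate_baseline(curve, (0, 10)) == 5.0

    def test_single_frame_window(self):
        curve = IntensityCurve(np.arange(10.0), np.arange(10.0))
        assert estimate_baseline(curve, (2, 3)) == 2.0
        assert curve.baseline_noise_sd == 0.0

    def test_noisy_baseline_standard_error(self, tube_4mm):
        cfg = BolusSimConfig(
            velocity_cm_s=20.0,
            geometry=tube_4mm,
            noise_sd=1.0,
            baseline_level=10.0,
            seed=7,
        )
        curve, _ = simulate_curve(cfg)
        m = 40
        est = estimate_baseline(curve, (0, m))
        assert abs(est - 10.0) < 4.0 / np.sqrt(m)

    def test_window_overlapping_peak_rejected(self):
        x = np.concatenate([np.zeros(5), [10.0], np.zeros(5)])
        curve = IntensityCurve(np.arange(11.0), x)
        with pytest.raises(InvalidWindowError):
            estimate_baseline(curve, (3, 8))

    def test_auto_window_precedes_onset(self, tube_4mm):
        cfg = BolusSimConfig(
            velocity_cm_s=20.0, geometry=tube_4mm, noise_sd=0.5, baseline_level=10.0
        )
        curve, truth = simulate_curve(cfg)
        lo, hi = auto_baseline_window(curve)
        assert lo == 0
        assert curve.times[hi - 1] < truth.peak_time_s

    def test_subtract_and_restore(self):
        curve = IntensityCurve(np.arange(6.0), np.full(6, 5.0))
        estimate_baseline(curve, (0, 6))
        out = subtract_baseline(curve)
        np.testing.assert_array_equal(out.intensities, np.zeros(6))
        np.testing.assert_allclose(
            out.intensities + out.baseline_value, curve.intensities
        )

    def test_subtraction_idempotent(self):
        curve = IntensityCurve(np.arange(6.0), np.array([1, 1, 1, 8, 1, 1.0]))
        estimate_baseline(curve, (0, 3))
        once = subtract_baseline(curve)
        twice = subtract_baseline(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_subtract_requires_estimate(self):
        curve = IntensityCurve(np.arange(6.0), np.ones(6))
        with pytest.raises(BaselineStateError):
            subtract_baseline(curve)


class TestQC:
    def test_clean_simulated_bolus_passes(self, tube_4mm):
        cfg = BolusSimConfig(velocity_cm_s=20.0, geometry=tube_4mm, seed=11)
        raw, _ = simulate_curve(cfg)
        curve = interpolate(raw, 10)
        estimate_baseline(curve)
        report = qc_bolus(subtract_baseline(curve))
        assert report.passed
        assert report.reasons == []

    def test_bimodal_rejected(self):
        t = np.arange(200) * 0.05
        x = np.exp(-(((t - 3) / 0.3) ** 2)) * 0.6 + np.exp(-(((t - 6) / 0.3) ** 2))
        curve = make_curve(t, x, baseline_window=(0, 100))
        report = qc_bolus(curve)
        assert not report.passed
        assert QCFlag.MULTIPLE_PEAKS in report.reasons

    def test_pure_noise_rejected_low_snr(self):
        rng = np.random.default_rng(0)
        t = np.arange(200) * 0.05
        curve = make_curve(t, 5.0 + rng.normal(0, 0.5, 200), baseline_window=(0, 500))
        report = qc_bolus(curve)
        assert not report.passed
        assert QCFlag.LOW_SNR in report.reasons

    def test_truncated_record_rejected(self, tube_4mm):
        cfg = BolusSimConfig(velocity_cm_s=20.0, geometry=tube_4mm, noise_sd=0.0)
        raw, truth = simulate_curve(cfg)
        # cut the record just after the peak so the decline is missing
        cut = int(truth.peak_time_s / raw.dt) + 2
        clipped = IntensityCurve(raw.times[:cut], raw.intensities[:cut])
        curve = interpolate(clipped, 10)
        estimate_baseline(curve)
        report = qc_bolus(subtract_baseline(curve))
        assert QCFlag.TRUNCATED in report.reasons

    def test_invariant_under_rescaling(self, tube_4mm):
        cfg = BolusSimConfig(velocity_cm_s=25.0, geometry=tube_4mm, seed=2)
        raw, _ = simulate_curve(cfg)
        reports = []
        for scale in (1.0, 37.5):
            curve = interpolate(
                IntensityCurve(raw.times, raw.intensities * scale), 10
            )
            estimate_baseline(curve)
            reports.append(qc_bolus(subtract_baseline(curve)))
        assert reports[0].passed == reports[1].passed
        assert reports[0].reasons == reports[1].reasons
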