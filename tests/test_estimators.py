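import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_curve
from mpiflow.curves import IntensityCurve, estimate_baseline, interpolate, subtract_baseline
from mpiflow.errors import BaselineStateError, DomainError, TruncatedBolusError
from mpiflow.estimators import (
    compute_auc,
    compute_fdhm,
    flow_from_auc,
    pressure_gradient,
    velocity_from_auc,
    velocity_from_fdhm,
)
from mpiflow.geometry import TubeGeometry
from mpiflow.simulate import BolusSimConfig, simulate_curve


def rectangle_curve(width_s=2.0, dt=0.05):
    """Plateau of 1 with edges ramping over two samples, centred so the
    half-maximum width of the piecewise-linear signal is exactly
    ``width_s`` (from 1.0 s to 1.0 + width_s)."""
    t = np.arange(0, 6 + dt / 2, dt)
    rise_mid, fall_mid = 1.0, 1.0 + width_s
    ramp = 2 * dt
    x = np.clip((t - (rise_mid - dt)) / ramp, 0, 1) * np.clip(
        ((fall_mid + dt) - t) / ramp, 0, 1
    )
    return make_curve(t, x, baseline_window=(0, 5))


def triangle_curve(dt=0.05, baseline=0.0):
    t = np.arange(0, 2 + dt / 2, dt)
    x = np.where(t <= 1.0, t, 2.0 - t)
    curve = interpolate(IntensityCurve(t, x), 10)
    curve.baseline_value = baseline
    curve.baseline_noise_sd = 0.0
    curve.is_baseline_subtracted = True
    return curve


class TestFDHM:
    def test_rectangle_width(self):
        assert compute_fdhm(rectangle_curve(2.0)) == pytest.approx(2.0, abs=1e-3)

    def test_triangle(self):
        assert compute_fdhm(triangle_curve()) == pytest.approx(1.0, abs=1e-3)

    def test_gaussian_fwhm(self):
        t = np.arange(0, 12, 0.05)
        x = np.exp(-((t - 6.0) ** 2) / 2.0)  # sigma = 1 s
        curve = make_curve(t, x, baseline_window=(0, 5))
        assert compute_fdhm(curve) == pytest.approx(2.3548, abs=1e-3)

    def test_truncated_raises(self):
        t = np.arange(0, 1.05, 0.05)
        curve = make_curve(t, t, baseline_window=(0, 2))  # still rising at end
        with pytest.raises(TruncatedBolusError):
            compute_fdhm(curve)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_invariant_under_intensity_scaling(self, scale):
        base = triangle_curve()
        scaled = dataclasses.replace(base, intensities=base.intensities * scale)
        assert compute_fdhm(scaled) == pytest.approx(compute_fdhm(base), rel=1e-12)

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.3])
    def test_time_dilation(self, k):
        base = triangle_curve()
        dilated = dataclasses.replace(base, times=base.times * k)
        assert compute_fdhm(dilated) == pytest.approx(k * compute_fdhm(base), rel=1e-9)

    @pytest.mark.parametrize("velocity", [12.0, 20.0, 24.0, 40.0])
    def test_matches_simulator_oracle(self, velocity, tube_6mm):
        """On noiseless transits at the four canonical setting velocities the
        estimator agrees with the dense-quadrature oracle to within one
        refined time step."""
        cfg = BolusSimConfig(
            velocity_cm_s=velocity, geometry=tube_6mm, noise_sd=0.0, baseline_level=3.0
        )
        raw, truth = simulate_curve(cfg)
        curve = interpolate(raw, 10)
        estimate_baseline(curve)
        fdhm = compute_fdhm(subtract_baseline(curve))
        refined_step = cfg.frame_interval_s / 10
        assert abs(fdhm - truth.fdhm_true_s) <= refined_step


class TestVelocityFromFDHM:
    def test_direct_substitution(self):
        assert velocity_from_fdhm(1.0, 28.0, 1.0) == pytest.approx(2.8)

    def test_calibrated_magnitude(self):
        # correction factor of the experimental order applied to a ~2.5 s
        # transit over the 22.4 mm FOV
        assert velocity_from_fdhm(2.5, 22.4, 22.99) == pytest.approx(20.60, abs=0.005)

    def test_inverse_proportionality(self):
        assert velocity_from_fdhm(2.0, 22.4, 5.0) == pytest.approx(
            velocity_from_fdhm(1.0, 22.4, 5.0) / 2
        )

    def test_invalid(self):
        with pytest.raises(DomainError):
            velocity_from_fdhm(0.0, 22.4, 1.0)


class TestAUC:
    def test_rectangle(self):
        curve = rectangle_curve(2.0)
        curve.baseline_value = 0.1
        auc, t_start, t_end = compute_auc(curve)
        assert auc == pytest.approx(2.0, abs=0.01)
        assert t_start == pytest.approx(1.0, abs=0.05)
        assert t_end == pytest.approx(3.0, abs=0.05)

    def test_triangle_against_fine_grid_oracle(self):
        # independent brute-force oracle on a dense grid
        tt = np.linspace(0, 2, 2_000_001)
        xx = np.where(tt <= 1.0, tt, 2.0 - tt)
        t_end_oracle = tt[1_000_000 + np.argmax(xx[1_000_000:] <= 0.33)]
        mask = tt <= t_end_oracle
        auc_oracle = np.trapezoid(xx[mask], tt[mask])
        assert t_end_oracle == pytest.approx(1.67, abs=1e-4)
        assert auc_oracle == pytest.approx(0.9456, abs=1e-4)

        curve = triangle_curve(baseline=1e-9)
        auc, t_start, t_end = compute_auc(curve)
        assert t_end == pytest.approx(t_end_oracle, abs=1e-4)
        assert auc == pytest.approx(auc_oracle, abs=1e-4)

    def test_homogeneity(self):
        base = triangle_curve(baseline=0.01)
        auc0, s0, e0 = compute_auc(base)
        scaled = dataclasses.replace(base, intensities=base.intensities * 3.0)
        scaled.baseline_value = 0.03
        auc1, s1, e1 = compute_auc(scaled)
        assert auc1 == pytest.approx(3.0 * auc0, rel=1e-9)
        assert (s1, e1) == (pytest.approx(s0), pytest.approx(e0))

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_time_dilation(self, k):
        base = triangle_curve(baseline=0.01)
        auc0, s0, e0 = compute_auc(base)
        dilated = dataclasses.replace(base, times=base.times * k)
        auc1, s1, e1 = compute_auc(dilated)
        assert auc1 == pytest.approx(k * auc0, rel=1e-9)
        assert s1 == pytest.approx(k * s0, rel=1e-6)
        assert e1 == pytest.approx(k * e0, rel=1e-9)

    def test_truncated_decline_raises(self):
        t = np.arange(0, 2.05, 0.05)
        x = np.where(t <= 1.0, t, 1.0)  # never declines
        curve = interpolate(IntensityCurve(t, x), 10)
        curve.baseline_value = 0.01
        curve.is_baseline_subtracted = True
        with pytest.raises(TruncatedBolusError):
            compute_auc(curve)

    def test_requires_baseline_state(self):
        curve = interpolate(IntensityCurve(np.arange(5.0), np.array([0, 1, 2, 1, 0.0])), 2)
        with pytest.raises(BaselineStateError):
            compute_auc(curve)


class TestVelocityFromAUC:
    def test_unit_case(self):
        geo = TubeGeometry(inner_diameter_mm=11.283791671)  # area 1 cm^2
        assert geo.area_cm2 == pytest.approx(1.0, rel=1e-9)
        assert velocity_from_auc(1.0, 1.0, geo) == pytest.approx(1.0)

    def test_linear_in_epsilon(self, tube_6mm):
        v1 = velocity_from_auc(2.5, 10.0, tube_6mm)
        v2 = velocity_from_auc(2.5, 20.0, tube_6mm)
        assert v2 == pytest.approx(2 * v1)

    def test_flow_from_auc(self):
        assert flow_from_auc(2.0, 10.0) == pytest.approx(5.0)

    def test_invalid(self, tube_6mm):
        with pytest.raises(DomainError):
            velocity_from_auc(0.0, 1.0, tube_6mm)
        with pytest.raises(DomainError):
            velocity_from_auc(1.0, -1.0, tube_6mm)


@pytest.mark.parametrize("v, dp", [(0.0, 0.0), (1.0, 4.0), (2.0, 16.0)])
def test_pressure_gradient(v, dp):
    assert pressure_gradient(v) == pytest.approx(dp)


def test_pressure_gradient_negative_velocity():
    with pytest.raises(DomainError):
        pressure_gradient(-0.5)
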