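"""Smoothing, differentiation and kinematic reductions."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from ibii.kinematics import (
    SmoothingSpec,
    differentiate_acceleration,
    differentiate_strain,
    effective_strain_rate,
    section_and_surface_averages,
    smooth_spatial,
    smooth_temporal,
)


class TestSpatialSmoothing:
    spec = SmoothingSpec(spatial_radius_px=9, temporal_window=11, temporal_order=3)

    def test_constant_field_unchanged_everywhere(self):
        u = np.full((2, 40, 50), 3.7)
        np.testing.assert_allclose(smooth_spatial(u, self.spec), u, rtol=1e-12)

    def test_linear_ramp_unchanged_in_interior(self):
        x = np.arange(60.0)
        u = np.tile(2.5 * x, (1, 40, 1))
        s = smooth_spatial(u, self.spec)
        r = self.spec.spatial_radius_px
        np.testing.assert_allclose(s[0, r:-r, r:-r], u[0, r:-r, r:-r], rtol=1e-9)

    def test_radius_zero_is_identity(self):
        u = np.random.default_rng(0).normal(size=(2, 20, 20))
        np.testing.assert_array_equal(smooth_spatial(u, SmoothingSpec(0, 11, 3)), u)

    def test_white_noise_variance_reduced_by_kernel_power(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(1, 400, 400))
        s = smooth_spatial(u, self.spec)
        r = self.spec.spatial_radius_px
        sigma = r / 3.0
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        k /= k.sum()
        k2 = np.outer(k, k)
        expected = (k2**2).sum()   # noise power transmission of the 2-D kernel
        measured = s[0, r:-r, r:-r].var()
        assert measured == pytest.approx(expected, rel=0.05)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            smooth_spatial(np.zeros((1, 20, 20)), SmoothingSpec(15, 11, 3))


class TestTemporalSmoothing:
    spec = SmoothingSpec(spatial_radius_px=0, temporal_window=21, temporal_order=3)

    def test_cubic_signal_reproduced_exactly_including_edges(self):
        t = np.arange(60.0)
        u = (0.5 * t**3 - 2 * t**2 + t - 4)[:, None, None] * np.ones((1, 2, 3))
        np.testing.assert_allclose(smooth_temporal(u, self.spec), u, rtol=1e-9, atol=1e-10)

    def test_constant_unchanged(self):
        u = np.full((30, 2, 2), -1.5)
        np.testing.assert_allclose(smooth_temporal(u, self.spec), u, rtol=1e-12)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        w = 2 * np.pi * 0.06  # rad/frame
        t = np.arange(400.0)
        u = np.sin(w * t)[:, None, None] * np.ones((1, 1, 1))
        s = smooth_temporal(u, self.spec)
        c = savgol_coeffs(21, 3)
        m = np.arange(-10, 11)
        gain = float((c[::-1] * np.cos(w * m)).sum())
        mid = slice(50, 350)
        measured = np.sqrt(2.0 * (s[mid, 0, 0] ** 2).mean())
        assert measured == pytest.approx(abs(gain), rel=0.02)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError):
            smooth_temporal(np.zeros((10, 2, 2)), self.spec)


class TestDifferentiation:
    def test_linear_displacement_gives_exact_strain(self):
        px = 1e-4
        x = (np.arange(30) + 0.5) * px
        ux = np.tile(3e-3 * x, (2, 20, 1))
        uy = np.zeros_like(ux)
        exx, eyy, gxy = differentiate_strain(ux, uy, px)
        np.testing.assert_allclose(exx, 3e-3, rtol=1e-9)
        assert np.abs(eyy).max() < 1e-15 and np.abs(gxy).max() < 1e-15

    def test_rigid_rotation_gives_zero_strain(self):
        px = 1e-4
        x = (np.arange(30) + 0.5) * px
        y = (np.arange(20) + 0.5) * px
        X, Y = np.meshgrid(x, y)
        w = 1e-3
        ux = (-w * Y)[None]
        uy = (w * X)[None]
        exx, eyy, gxy = differentiate_strain(ux, uy, px)
        assert np.abs(exx).max() < 1e-12
        assert np.abs(eyy).max() < 1e-12
        assert np.abs(gxy).max() < 1e-12

    def test_polynomial_strain_error_is_second_order(self):
        def max_err(n):
            px = 1e-3 / n
            x = (np.arange(n) + 0.5) * px
            ux = np.tile(x**3, (1, 8, 1))
            exx, _, _ = differentiate_strain(ux, np.zeros_like(ux), px)
            return np.abs(exx[0, 0, 1:-1] - 3 * x[1:-1] ** 2).max()

        assert max_err(80) / max_err(160) == pytest.approx(4.0, rel=0.15)

    def test_constant_acceleration_recovered_exactly(self):
        dt = 1e-7
        t = np.arange(40) * dt
        g = 5e6
        u = (0.5 * g * t**2)[:, None, None] * np.ones((1, 3, 3))
        ax, ay = differentiate_acceleration(u, np.zeros_like(u), dt)
        # frames 0/1 and -2/-1 inherit the one-sided edge stencils
        np.testing.assert_allclose(ax[2:-2], g, rtol=1e-6)
        assert np.abs(ay).max() == 0

    def test_linear_displacement_gives_zero_acceleration(self):
        dt = 1e-7
        u = (3.0 * np.arange(40) * dt)[:, None, None] * np.ones((1, 2, 2))
        ax, _ = differentiate_acceleration(u, np.zeros_like(u), dt)
        assert np.abs(ax).max() < 1e-6

    def test_sinusoid_acceleration_matches_discrete_stencil(self):
        dt = 1e-7
        w = 2 * np.pi * 2e5
        t = np.arange(100) * dt
        u = np.sin(w * t)[:, None, None] * np.ones((1, 1, 1))
        ax, _ = differentiate_acceleration(u, np.zeros_like(u), dt)
        # double centred first difference of sin: amplitude (sin(w dt)/dt)^2
        expected = (np.sin(w * dt) / dt) ** 2
        s = np.sin(w * t[2:-2])
        a = ax[2:-2, 0, 0]
        measured = -(a * s).sum() / (s * s).sum()
        assert measured == pytest.approx(expected, rel=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            differentiate_acceleration(np.zeros((4, 2, 2)), np.zeros((4, 2, 2)), 1e-7)
        with pytest.raises(ValueError):
            differentiate_strain(np.zeros((1, 1, 5)), np.zeros((1, 1, 5)), 1e-4)


class TestEffectiveStrainRate:
    def test_two_point_hand_computation(self):
        eps = np.array([[[1e-3, 2e-3]]])
        rate = np.array([[[100.0, 200.0]]])
        assert effective_strain_rate(eps, rate) == pytest.approx(166.6667, rel=1e-4)

    def test_uniform_rate_is_returned_for_any_strain_pattern(self):
        rng = np.random.default_rng(2)
        eps = np.abs(rng.normal(1e-3, 2e-4, (4, 5, 6)))
        rate = np.full_like(eps, -321.0)
        assert effective_strain_rate(eps, rate) == pytest.approx(-321.0)

    def test_signed_result_preserved(self):
        # compressive strains with negative rates: the strain-weighted mean
        # keeps the sign of the rates, as the formula is written
        eps = np.array([[[1e-3, 2e-3]]])
        rate = np.array([[[-100.0, -200.0]]])
        assert effective_strain_rate(eps, rate) == pytest.approx(-166.6667, rel=1e-4)

    def test_zero_strain_sum_rejected(self):
        eps = np.array([[[1e-3, -1e-3]]])
        rate = np.ones_like(eps)
        with pytest.raises(ValueError):
            effective_strain_rate(eps, rate)

    def test_simulator_regime_is_order_1e3(self, truth_kin):
        rate = effective_strain_rate(truth_kin.eps_xx, truth_kin.eps_xx_rate)
        assert 2e2 < abs(rate) < 2e4


class TestSectionSurfaceAverages:
    def test_constant_field(self):
        f = np.full((3, 10, 20), 4.2)
        line, surf = section_and_surface_averages(f, 1e-3, 1e-4)
        np.testing.assert_allclose(line, 4.2)
        np.testing.assert_allclose(surf, 4.2)

    def test_linear_ramp_surface_average_is_half_x0(self):
        px = 1e-4
        x = (np.arange(50) + 0.5) * px
        f = np.tile(x, (2, 8, 1))
        x0 = 30.5 * px
        _, surf = section_and_surface_averages(f, x0, px)
        assert abs(surf[0] - x0 / 2) <= px / 2

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(3, 7, 25))
        px = 2e-4
        x0 = 11.4 * px
        line, surf = section_and_surface_averages(f, x0, px)
        j = int(x0 / px)
        np.testing.assert_array_equal(line, f[:, :, j].mean(axis=1))
        np.testing.assert_array_equal(surf, f[:, :, : j + 1].mean(axis=(1, 2)))

    def test_x0_outside_field_rejected(self):
        with pytest.raises(ValueError):
            section_and_surface_averages(np.zeros((1, 4, 10)), 2e-3, 1e-4)
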