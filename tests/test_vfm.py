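"""Virtual-fields stiffness identification: gauges, fits, optimized fields."""

import numpy as np
import pytest

from ibii.containers import FieldSequence
from ibii.vfm import (
    StressGaugeSeries,
    VirtualMesh,
    build_stress_gauge_series,
    compressive_portion,
    fit_shear_profile,
    fit_stiffness_profile,
    linear_stress_gauge,
    optimized_vf_identify,
    select_stable_median,
    shear_stress_gauge,
    stress_gauge,
)

RHO = 2000.0


class TestStressGauges:
    def test_zero_acceleration_zero_stress(self):
        ax = np.zeros((5, 10, 40))
        assert not stress_gauge(ax, RHO, 1e-3, 1e-4).any()

    def test_uniform_acceleration_constant_field_value(self):
        # rho x0 a = 2000 * 0.01 * 1e6 = 20 MPa
        px = 5e-4
        ax = np.full((3, 10, 40), 1e6)
        sg = stress_gauge(ax, RHO, 0.01, px)
        np.testing.assert_allclose(sg, 20e6, rtol=1e-12)

    def test_uniform_transverse_acceleration_shear_gauge(self):
        px = 5e-4
        ay = np.full((3, 10, 40), -2e6)
        np.testing.assert_allclose(shear_stress_gauge(ay, RHO, 0.01, px), -40e6, rtol=1e-12)

    def test_sg_matches_solver_section_stress(self, small_sim):
        """On solver ground truth the stress-gauge reproduces the
        cross-section-averaged axial stress at x0 = 0.5 L within 3% of its
        peak (camera pixels aligned with the solver mesh so the check is not
        dominated by resampling)."""
        from ibii.simulator import sample_to_camera

        fields, gt = sample_to_camera(small_sim, pixels=(120, 72))
        px = fields.pixel_size
        j = 59  # x0 = 60 px = 0.5 L exactly
        sg = stress_gauge(gt["ax"], RHO, (j + 1) * px, px)
        # the gauge section x0 = (j+1) px is the face between columns j, j+1
        truth = 0.5 * (gt["sigma_xx"][:, :, j] + gt["sigma_xx"][:, :, j + 1]).mean(axis=1)
        assert np.abs(sg - truth).max() < 0.03 * np.abs(truth).max()

    def test_linearity_in_density_and_acceleration(self):
        rng = np.random.default_rng(0)
        ax = rng.normal(size=(4, 6, 30))
        px = 1e-4
        np.testing.assert_allclose(
            stress_gauge(3 * ax, RHO, 2e-3, px), 3 * stress_gauge(ax, RHO, 2e-3, px), rtol=1e-12
        )
        np.testing.assert_allclose(
            stress_gauge(ax, 2 * RHO, 2e-3, px), 2 * stress_gauge(ax, RHO, 2e-3, px), rtol=1e-12
        )


class TestLinearStressGauge:
    def test_uniform_axial_acceleration_flat_profile_equal_to_sg(self):
        px = 5e-4
        ax = np.full((3, 10, 40), 1e6)
        ay = np.zeros_like(ax)
        lsg = linear_stress_gauge(ax, ay, RHO, 0.01, px)
        sg = stress_gauge(ax, RHO, 0.01, px)
        np.testing.assert_allclose(lsg, np.tile(sg[:, None], (1, 10)), rtol=1e-9)

    def test_height_average_identity_for_random_fields(self):
        rng = np.random.default_rng(1)
        ax = rng.normal(size=(6, 24, 50)) * 1e6
        ay = rng.normal(size=(6, 24, 50)) * 1e6
        px = 2e-4
        for x0 in (10 * px, 25 * px, 50 * px):
            lsg = linear_stress_gauge(ax, ay, RHO, x0, px)
            sg = stress_gauge(ax, RHO, x0, px)
            np.testing.assert_allclose(lsg.mean(axis=1), sg, rtol=1e-9)

    def test_lsg_matches_solver_profile_on_misaligned_run(self, truth_kin_misaligned):
        kin, gt = truth_kin_misaligned
        px = kin.pixel_size
        j = int(0.5 * kin.meta["L"] / px)
        lsg = linear_stress_gauge(kin.ax, kin.ay, RHO, (j + 1) * px, px)
        truth = gt["sigma_xx"][:, :, j]
        peak = np.abs(truth).max()
        rms = np.sqrt(((lsg - truth) ** 2).mean())
        assert rms < 0.10 * peak

    def test_y_outside_section_rejected(self):
        ax = np.zeros((2, 10, 20))
        with pytest.raises(ValueError):
            linear_stress_gauge(ax, ax, RHO, 1e-3, 1e-4, H=5e-4)


class TestStiffnessFit:
    def _synthetic_series(self, Q=25e9, nu=0.16, n=40):
        """Histories manufactured exactly from the constitutive relation."""
        t = np.linspace(0, 2 * np.pi, 60)
        eps = -1e-3 * np.sin(t / 2) ** 2  # compressive ramp and recovery
        eps_yy = -nu * eps * 0.0  # keep it uniaxial for exactness
        slices = 1 + np.arange(n, dtype=float) / n
        eps_xx = eps[None, :] * slices[:, None]
        sigma = Q * (eps_xx + nu * np.zeros_like(eps_xx))
        x0 = (6 + np.arange(n, dtype=float)) * 1e-4
        return StressGaugeSeries(
            x0=x0, cols=np.arange(n) + 6, sigma_xx=sigma, sigma_xy=np.zeros_like(sigma),
            eps_xx=eps_xx, eps_yy=np.zeros_like(eps_xx), gamma_xy=np.zeros_like(eps_xx),
            pixel_size=1e-4, L=x0[-1] + 6e-4,
        )

    def test_exact_constitutive_histories_recover_slope_everywhere(self):
        series = self._synthetic_series(Q=25e9)
        prof = fit_stiffness_profile(series, nu_assumed=0.16)
        ok = np.isfinite(prof.stiffness)
        np.testing.assert_allclose(prof.stiffness[ok], 25e9, rtol=1e-3)
        assert prof.average == pytest.approx(25e9, rel=1e-3)

    def test_solver_ground_truth_recovers_q11_within_two_percent(self, truth_kin):
        series = build_stress_gauge_series(truth_kin, RHO, margin_px=10)
        prof = fit_stiffness_profile(series, nu_assumed=0.16)
        assert prof.average == pytest.approx(26e9, rel=0.02)

    def test_compressive_portion_ends_at_zero_recrossing(self):
        sigma = np.array([0.0, -2, -5, -9, -6, -3, -0.5, 1.0, 3.0, 1.0])
        por = compressive_portion(sigma)
        assert por == slice(0, 7)

    def test_short_compressive_portion_skipped_with_warning(self):
        series = self._synthetic_series(n=5)
        series.sigma_xx = np.tile(np.array([-1.0, 1.0, 1.0, 1.0, 1.0, 1.0] * 10), (5, 1))
        with pytest.warns(UserWarning, match="skipped"):
            fit_stiffness_profile(series, nu_assumed=0.16)


class TestShearFit:
    def test_exact_shear_histories_recover_g12(self):
        G = 7e9
        t = np.linspace(0, 4 * np.pi, 80)
        gamma = 5e-4 * np.sin(t)
        n = 40
        g_xy = np.tile(gamma, (n, 1))
        series = StressGaugeSeries(
            x0=(6 + np.arange(n, dtype=float)) * 1e-4, cols=np.arange(n) + 6,
            sigma_xx=np.zeros_like(g_xy), sigma_xy=G * g_xy,
            eps_xx=np.zeros_like(g_xy), eps_yy=np.zeros_like(g_xy), gamma_xy=g_xy,
            pixel_size=1e-4, L=46e-4,
        )
        prof = fit_shear_profile(series)
        assert prof.identifiable
        assert prof.average == pytest.approx(G, rel=1e-9)

    def test_aligned_impact_not_identifiable(self, truth_kin):
        series = build_stress_gauge_series(truth_kin, RHO, margin_px=10)
        prof = fit_shear_profile(series)
        assert not prof.identifiable
        assert "below threshold" in prof.reason
        assert np.isnan(prof.average)

    def test_misaligned_impact_recovers_g12_within_ten_percent(self, truth_kin_misaligned):
        kin, _ = truth_kin_misaligned
        series = build_stress_gauge_series(kin, RHO, margin_px=10)
        prof = fit_shear_profile(series)
        assert prof.identifiable
        assert prof.average == pytest.approx(7e9, rel=0.10)


class TestOptimizedVirtualFields:
    def test_all_four_stiffnesses_recovered_from_misaligned_ground_truth(self, truth_kin_misaligned):
        kin, _ = truth_kin_misaligned
        res = optimized_vf_identify(kin, RHO)
        expected = {"Q11": 26e9, "Q22": 15e9, "Q12": 4.16e9, "Q66": 7e9}
        for i, name in enumerate(res.components):
            med = np.nanmedian(res.q_traces[:, i])
            rel = 0.03 if name in ("Q11", "Q22") else 0.10
            assert med == pytest.approx(expected[name], rel=rel), name

    def test_per_frame_trace_settles_on_true_q11(self, truth_kin):
        res = optimized_vf_identify(truth_kin, RHO)
        tr = res.q_traces[:, 0]
        settled = tr[15:40]
        assert np.isfinite(settled).all()
        assert np.abs(settled / 26e9 - 1).max() < 0.03

    def test_identification_scale_invariant_in_displacement(self, truth_kin):
        res1 = optimized_vf_identify(truth_kin, RHO, reweight=False)
        scaled = truth_kin.copy()
        for name in ("ux", "uy", "ax", "ay", "eps_xx", "eps_yy", "gamma_xy"):
            setattr(scaled, name, 2.0 * getattr(scaled, name))
        res2 = optimized_vf_identify(scaled, RHO, reweight=False)
        f = np.isfinite(res1.q_traces) & np.isfinite(res2.q_traces)
        np.testing.assert_allclose(res2.q_traces[f], res1.q_traces[f], rtol=1e-6)

    def test_featureless_frames_marked_unidentifiable(self, truth_kin):
        res = optimized_vf_identify(truth_kin, RHO)
        # before the pulse arrives there is nothing to identify
        assert np.isnan(res.q_traces[0]).all()

    def test_mesh_refinement_stability(self, truth_kin):
        meds = []
        for shape in ((4, 3), (5, 4), (6, 5)):
            res = optimized_vf_identify(truth_kin, RHO, mesh=VirtualMesh(shape))
            meds.append(np.nanmedian(res.q_traces[:, 0]))
        assert max(meds) / min(meds) - 1 < 0.05


class TestStableMedian:
    def test_constant_trace_full_range(self):
        rng, med = select_stable_median(np.full(30, 5.0))
        assert rng == (0, 30) and med == 5.0

    def test_outlier_spikes_do_not_move_median(self):
        rng_ = np.random.default_rng(0)
        trace = np.full(50, 10.0) + rng_.normal(0, 0.01, 50)
        trace[::10] = 30.0  # 10% outliers
        (lo, hi), med = select_stable_median(trace, rel_tol=0.5)
        assert med == pytest.approx(10.0, rel=0.01)

    def test_manual_range_override(self):
        trace = np.arange(40.0)
        rng, med = select_stable_median(trace, frame_range=(10, 20))
        assert rng == (10, 20) and med == 14.5

    def test_no_stable_run_raises(self):
        trace = np.array([1.0, -1.0] * 10)
        with pytest.raises(ValueError, match="stable run"):
            select_stable_median(trace)

    def test_nan_frames_excluded(self):
        trace = np.full(30, 7.0)
        trace[:10] = np.nan
        (lo, hi), med = select_stable_median(trace)
        assert lo >= 10 and med == 7.0
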