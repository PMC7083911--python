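"""MSD estimators, diffusion fits, viscosity model and Stokes-Einstein sizing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanospt import msd
from nanospt import synthdata as syn
from nanospt.tracking import Trajectory

from conftest import brownian_trajectories


def brute_force_msd(x, y, dt, max_lag):
    """Naive double-loop time-averaged MSD oracle."""
    n = len(x)
    lags, vals, counts = [], [], []
    for k in range(1, max_lag + 1):
        acc = 0.0
        m = 0
        for i in range(n - k):
            acc += (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2
            m += 1
        lags.append(k * dt)
        vals.append(acc / m)
        counts.append(m)
    return np.array(lags), np.array(vals), np.array(counts)


class TestComputeMSD:
    def test_stationary_trajectory_gives_zero_msd(self):
        tr = Trajectory(0, np.arange(10.0), np.full(10, 1.5), np.full(10, -2.0), np.ones(10))
        curve = msd.compute_msd(tr)
        np.testing.assert_allclose(curve.msd_um2, 0.0)

    def test_ballistic_motion_quadratic_msd(self):
        # x = v t with v = 1 um/s: MSD(lag) = (v lag)^2, so MSD(2 s) = 4 um^2
        t = np.arange(10.0)
        tr = Trajectory(0, t, t.copy(), np.zeros(10), np.ones(10))
        curve = msd.compute_msd(tr)
        assert curve.msd_um2[1] == pytest.approx(4.0)
        np.testing.assert_allclose(curve.msd_um2, curve.lag_s**2, rtol=1e-12)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        dt = 0.125
        tr = Trajectory(
            0, np.arange(n) * dt, rng.normal(0, 1, n), rng.normal(0, 1, n), np.ones(n)
        )
        curve = msd.compute_msd(tr)
        lags, vals, counts = brute_force_msd(tr.x_um, tr.y_um, dt, n - 1)
        np.testing.assert_allclose(curve.lag_s, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.msd_um2, vals, rtol=1e-10)
        np.testing.assert_array_equal(curve.n_pairs, counts)

    def test_single_step_estimator_uses_consecutive_steps_only(self):
        rng = np.random.default_rng(3)
        n = 50
        tr = Trajectory(0, np.arange(n) * 0.1, rng.normal(0, 1, n),
                        rng.normal(0, 1, n), np.ones(n))
        curve = msd.compute_msd(tr, estimator="single_step")
        expected = np.mean(np.diff(tr.x_um) ** 2 + np.diff(tr.y_um) ** 2)
        assert len(curve.lag_s) == 1
        assert curve.lag_s[0] == pytest.approx(0.1)
        assert curve.msd_um2[0] == pytest.approx(expected, rel=1e-12)

    def test_nonuniform_sampling_rejected(self):
        tr = Trajectory(0, [0.0, 1.0, 3.0], [0.0, 1.0, 2.0], [0.0] * 3, [1.0] * 3)
        with pytest.raises(ValueError):
            msd.compute_msd(tr)

    def test_npairs_decreasing(self):
        trajs = brownian_trajectories(1, 1e-3, 0.1, 100, seed0=5)
        curve = msd.compute_msd(trajs[0])
        assert np.all(np.diff(curve.n_pairs) < 0)


class TestFitDiffusion:
    def test_exact_line_through_origin(self):
        lag = np.arange(1, 11) * 0.5
        curve = msd.MSDCurve(lag, 4.0 * 1.0 * lag, np.arange(100, 90, -1))
        fit = msd.fit_diffusion(curve)
        assert fit.D_um2_s == pytest.approx(1.0, rel=1e-12)
        assert fit.intercept_um2 == 0.0
        assert not fit.degenerate

    def test_single_lag_direct_relation(self):
        # MSD(1 s) = 4 um^2 -> D = MSD / (4 lag) = 1 um^2/s
        curve = msd.MSDCurve(np.array([1.0]), np.array([4.0]), np.array([10]))
        fit = msd.fit_diffusion(curve)
        assert fit.D_um2_s == pytest.approx(1.0)

    def test_monte_carlo_recovery_at_small_D(self):
        # D = 1e-3 um^2/s, 1000 frames at 8 fps, 200 replicates: median within 10%
        trajs = brownian_trajectories(200, 1e-3, 0.125, 1000, seed0=300)
        d_hats = []
        for tr in trajs:
            curve = msd.compute_msd(tr, max_lag_s=25.0)
            d_hats.append(msd.fit_diffusion(curve, max_lag_s=25.0).D_um2_s)
        assert np.median(d_hats) == pytest.approx(1e-3, rel=0.10)

    def test_intercept_absorbs_localization_offset(self):
        lag = np.arange(1, 21) * 0.1
        offset = 4 * 0.05**2
        curve = msd.MSDCurve(lag, 4.0 * 0.01 * lag + offset, np.full(20, 100))
        fit = msd.fit_diffusion(curve, with_intercept=True)
        assert fit.D_um2_s == pytest.approx(0.01, rel=1e-9)
        assert fit.intercept_um2 == pytest.approx(offset, rel=1e-9)

    def test_all_zero_msd_flagged_degenerate(self):
        curve = msd.MSDCurve(np.array([1.0, 2.0]), np.zeros(2), np.array([5, 4]))
        fit = msd.fit_diffusion(curve)
        assert fit.D_um2_s == 0.0 and fit.degenerate

    def test_fit_window_excludes_long_lags(self):
        lag = np.array([1.0, 2.0, 30.0])
        vals = np.array([4.0, 8.0, 1e6])  # corrupt value outside the window
        curve = msd.MSDCurve(lag, vals, np.array([10, 9, 1]))
        fit = msd.fit_diffusion(curve, max_lag_s=25.0)
        assert fit.D_um2_s == pytest.approx(1.0, rel=1e-9)


class TestGlycerolViscosity:
    def test_pure_water_at_room_temperature(self):
        assert msd.glycerol_viscosity(293.15, 0.0) == pytest.approx(1.0e-3, rel=0.05)

    def test_pure_glycerol_at_room_temperature(self):
        # published value ~1.41 Pa*s at 20 C
        assert msd.glycerol_viscosity(293.15, 1.0) == pytest.approx(1.41, rel=0.05)

    def test_monotone_decreasing_in_temperature(self):
        temps = np.linspace(280, 360, 30)
        etas = [msd.glycerol_viscosity(t, 1.0) for t in temps]
        assert np.all(np.diff(etas) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            msd.glycerol_viscosity(250.0, 1.0)
        with pytest.raises(ValueError):
            msd.glycerol_viscosity(300.0, 1.5)


class TestStokesRadius:
    def test_direct_evaluation(self):
        res = msd.stokes_radius(4.3214e-3, 295.0, 1.0, A_correction=1.0)
        assert res.R_stokes_nm == pytest.approx(50.0, rel=1e-3)
        assert res.R_hydro_nm == res.R_stokes_nm

    def test_anisotropy_correction_scales_radius(self):
        res = msd.stokes_radius(4.3214e-3, 295.0, 1.0, A_correction=1.49)
        assert res.R_hydro_nm == pytest.approx(1.49 * res.R_stokes_nm, rel=1e-12)
        assert res.R_hydro_nm == pytest.approx(74.5, rel=2e-3)

    def test_scaling_law_in_viscosity(self):
        r1 = msd.stokes_radius(1e-3, 295.0, 1.0).R_stokes_nm
        r2 = msd.stokes_radius(1e-3, 295.0, 2.0).R_stokes_nm
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-12)

    def test_units_audit_si_vs_micron(self):
        # D in m^2/s via SI arithmetic must agree with the um^2/s path to 1e-12
        d_um = 4.3214e-3
        si = syn.K_BOLTZMANN * 295.0 / (6 * np.pi * 1.0 * d_um * 1e-12) * 1e9
        res = msd.stokes_radius(d_um, 295.0, 1.0, A_correction=1.0)
        assert res.R_stokes_nm == pytest.approx(si, rel=1e-12)

    def test_nonpositive_D_rejected(self):
        with pytest.raises(ValueError):
            msd.stokes_radius(0.0, 295.0, 1.0)


class TestOblateFriction:
    def test_sphere_limit_is_unity(self):
        assert msd.oblate_friction_ratio(0.999999) == pytest.approx(1.0, abs=1e-4)

    def test_thin_disc_limit(self):
        # orientation-averaged friction of a thin disc: f = 12 eta a,
        # ratio to equal-volume sphere diverges as p^(-1/3) * 2/pi
        p = 1e-6
        expected = (2 / np.pi) * p ** (-1 / 3)
        assert msd.oblate_friction_ratio(p) == pytest.approx(expected, rel=1e-3)


class TestSizeBrightnessCorrelation:
    def test_parameter_recovery_across_sizes(self):
        """Median recovered Stokes radius within 15% for 25-200 nm sheets."""
        eta = msd.glycerol_viscosity(295.0, 1.0)
        for r_true in (25.0, 50.0, 100.0, 200.0):
            recs = []
            for i in range(60):
                p = syn.MotionParams(
                    stokes_radius_nm=r_true, temperature_K=295.0, viscosity_Pa_s=eta,
                    frame_interval_s=0.125, n_frames=1000, seed=int(r_true) * 100 + i,
                )
                tr = syn.simulate_trajectory(p)
                fit = msd.fit_diffusion(msd.compute_msd(tr, 25.0), 25.0)
                if not fit.degenerate:
                    recs.append(msd.stokes_radius(fit.D_um2_s, 295.0, eta, 1.0).R_stokes_nm)
            assert np.median(recs) == pytest.approx(r_true, rel=0.15)

    def test_monotone_size_truth_correlation(self):
        eta = msd.glycerol_viscosity(295.0, 1.0)
        pop = syn.generate_sheet_population(150, seed=11)
        trajs, truths = [], []
        for i in range(len(pop)):
            p = syn.MotionParams(
                stokes_radius_nm=(pop.diameter_nm[i] / 2) / 1.49,
                temperature_K=295.0, viscosity_Pa_s=eta,
                frame_interval_s=0.125, n_frames=1000, seed=7000 + i,
            )
            tr = syn.simulate_trajectory(p)
            tr.particle_id = i
            tr.mass = np.full(len(tr), pop.true_brightness[i])
            trajs.append(tr)
            truths.append(pop.diameter_nm[i])
        table = msd.size_brightness_correlation(
            trajs, T_K=295.0, eta_Pa_s=eta, n_bootstrap=100, seed=2
        )
        rho, p_val = msd.spearman_size_truth(
            table.R_hydro_nm, np.asarray(truths)[table.particle_id.astype(int)]
        )
        assert rho > 0 and p_val < 0.01

    def test_imposed_unit_exponent_recovered(self):
        # brightness ~ diameter^1.0 with 20% scatter, 300 particles; long
        # (4000-frame) tracks keep regression dilution from the noisy size
        # estimates below the 0.1 tolerance
        eta = msd.glycerol_viscosity(295.0, 1.0)
        pop = syn.generate_sheet_population(
            300, brightness_exponent=1.0, noise_cv=0.2, seed=12
        )
        trajs = []
        for i in range(len(pop)):
            p = syn.MotionParams(
                stokes_radius_nm=(pop.diameter_nm[i] / 2) / 1.49,
                temperature_K=295.0, viscosity_Pa_s=eta,
                frame_interval_s=0.125, n_frames=4000, seed=9000 + i,
            )
            tr = syn.simulate_trajectory(p)
            tr.particle_id = i
            tr.mass = np.full(len(tr), pop.true_brightness[i])
            trajs.append(tr)
        table = msd.size_brightness_correlation(
            trajs, T_K=295.0, eta_Pa_s=eta, n_bootstrap=100, seed=3
        )
        assert table.exponent == pytest.approx(1.0, abs=0.1)

    def test_too_few_trajectories_rejected(self):
        trajs = brownian_trajectories(2, 1e-3, 0.1, 50, seed0=0)
        with pytest.raises(ValueError):
            msd.size_brightness_correlation(trajs, 295.0, 1.0)
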