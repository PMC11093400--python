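"""Double-gamma HRF, design matrices, GLM fits, contrasts, PSC, fixed effects."""

import numpy as np
import pytest
from scipy import stats

from gsspipe import (HRFParams, NetworkSpec, NoiseParams, VolumeGrid,
                     build_design_matrix, double_gamma_hrf, fit_glm,
                     fixed_effects_combine, make_phantom,
                     make_localizer_schedule, sample_subject_topography,
                     simulate_bold_run, t_to_z)
from gsspipe.bold import convolved_regressor

from _oracles import weighted_mean_oracle


class TestHRF:
    def test_default_kernel_shape(self):
        k = double_gamma_hrf(0.1)
        t_peak = np.argmax(k) * 0.1
        assert 4.0 <= t_peak <= 7.0
        assert k.min() < 0  # undershoot
        assert k.max() == pytest.approx(1.0, abs=1e-3)

    def test_no_undershoot_when_ratio_zero(self):
        k = double_gamma_hrf(0.1, HRFParams(undershoot_ratio=0.0))
        assert (k >= 0).all()

    def test_coarse_kernel_is_decimated_fine_kernel(self):
        fine = double_gamma_hrf(0.1)
        coarse = double_gamma_hrf(1.4)
        assert np.allclose(coarse, fine[::14][: coarse.size], atol=1e-12)

    def test_invalid_tr_rejected(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(0.0)


class TestDesignMatrix:
    def test_empty_schedule_intercept_and_highpass_only(self):
        from gsspipe.schedules import DesignSchedule
        sched = DesignSchedule((), total_duration_s=140.0, design_kind="blocked")
        dm = build_design_matrix(sched, 1.4, 100)
        assert dm.condition_cols == ()
        assert dm.labels[0] == "intercept"
        assert len(dm.highpass_cols) == int(np.floor(2 * 140 / 100))

    def test_dct_count_for_264s_run(self):
        sched = make_localizer_schedule("language", seed=0)
        dm = build_design_matrix(sched, 1.4, sched.n_volumes(1.4))
        # floor(2 * T / cutoff) with T = 189 * 1.4 = 264.6 s
        assert len(dm.highpass_cols) == 5

    def test_block_regressor_integral_matches_quadrature(self):
        # integral of the convolved regressor = (total block time) x (kernel sum x dt)
        from gsspipe.schedules import DesignSchedule, Event
        sched = DesignSchedule((Event(10.0, 18.0, "blk"),), 120.0, "blocked")
        dt = 0.05
        t, reg = convolved_regressor(sched, "blk", dt=dt)
        kernel = double_gamma_hrf(dt, duration_s=32.0)
        expected = 18.0 * kernel.sum() * dt
        assert np.trapezoid(reg, dx=dt) == pytest.approx(expected, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        sched = make_localizer_schedule("language", seed=0)
        n = sched.n_volumes(1.4)
        dup = np.ones((n, 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(sched, 1.4, n, nuisance=dup,
                                nuisance_labels=("dup_intercept",))

    def test_nuisance_columns_appended_unmodified(self, rng):
        sched = make_localizer_schedule("language", seed=0)
        n = sched.n_volumes(1.4)
        nuis = rng.normal(size=(n, 2))
        dm = build_design_matrix(sched, 1.4, n, nuisance=nuis)
        assert np.array_equal(dm.matrix[:, list(dm.nuisance_cols)], nuis)


def _noiseless_run(grid, amp=1.0, seed=0):
    center = tuple((s - 1) / 2 for s in grid.shape)
    truths = make_phantom(grid, [NetworkSpec("net", center, 2.5,
                                             {"intact": amp, "degraded": amp / 5})],
                          ["s"], seed=seed)
    topo = [sample_subject_topography(truths[0], "s", seed=seed, max_shift_vox=0)]
    sched = make_localizer_schedule("language", seed=seed)
    run = simulate_bold_run(grid, truths, topo, sched, "s", "r", seed=seed,
                            noise=NoiseParams(0.0, 0.0, 0.0))
    return run, sched, truths[0].mask


class TestGLM:
    def test_intercept_only_beta_is_mean(self, rng):
        from gsspipe.schedules import DesignSchedule
        sched = DesignSchedule((), total_duration_s=50.0, design_kind="blocked")
        data = rng.normal(10, 1, size=(3, 3, 3, 36))
        dm = build_design_matrix(sched, 1.4, 36, highpass_cutoff_s=None)
        glm = fit_glm(data, dm)
        assert np.allclose(glm.beta_[0], data.mean(axis=3))

    def test_noiseless_roundtrip_recovers_planted_amplitudes(self):
        grid = VolumeGrid((10, 10, 10))
        run, sched, mask = _noiseless_run(grid)
        glm = fit_glm(run, build_design_matrix(sched, 1.4, run.n_volumes))
        psc = glm.psc("intact")
        assert np.abs(psc[mask] - 1.0).max() < 1e-6
        assert np.abs(glm.psc("degraded")[mask] - 0.2).max() < 1e-6

    def test_equal_conditions_give_zero_contrast_z(self):
        grid = VolumeGrid((8, 8, 8))
        run, sched, mask = _noiseless_run(grid, amp=0.0)
        glm = fit_glm(run, build_design_matrix(sched, 1.4, run.n_volumes))
        z = glm.contrast_z({"intact": 1.0, "degraded": -1.0})
        assert np.allclose(z, 0.0, atol=1e-6)

    def test_white_noise_z_is_standard_normal(self):
        grid = VolumeGrid((10, 10, 10))  # 1000 voxels
        sched = make_localizer_schedule("language", seed=1)
        run = simulate_bold_run(grid, [], [], sched, "s", "r", seed=42,
                                noise=NoiseParams(1.0, 0.0, 0.0))
        glm = fit_glm(run, build_design_matrix(sched, 1.4, run.n_volumes))
        z = glm.contrast_z({"intact": 1.0, "degraded": -1.0})
        assert abs(z.mean()) < 0.1
        assert abs(z.std(ddof=1) - 1.0) < 0.1

    def test_z_equals_two_step_regression_oracle(self, rng):
        # independent oracle: explicit lstsq + residual variance + t -> z
        sched = make_localizer_schedule("language", seed=3)
        n = sched.n_volumes(1.4)
        dm = build_design_matrix(sched, 1.4, n)
        data = rng.normal(100, 1, size=(2, 2, 2, n))
        glm = fit_glm(data, dm)
        z = glm.contrast_z({"intact": 1.0, "degraded": -1.0})
        X = dm.matrix
        c = np.zeros(X.shape[1])
        c[dm.condition_cols[list(dm.conditions).index("intact")]] = 1.0
        c[dm.condition_cols[list(dm.conditions).index("degraded")]] = -1.0
        for idx in np.ndindex(2, 2, 2):
            y = data[idx]
            beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            dof = n - rank
            sigma2 = float(res[0]) / dof
            t = (c @ beta) / np.sqrt(sigma2 * c @ np.linalg.inv(X.T @ X) @ c)
            z_exp = stats.norm.isf(stats.t.sf(t, dof)) if t >= 0 else \
                -stats.norm.isf(stats.t.sf(-t, dof))
            assert z[idx] == pytest.approx(z_exp, abs=1e-8)

    def test_design_row_mismatch_rejected(self, rng):
        sched = make_localizer_schedule("language", seed=0)
        dm = build_design_matrix(sched, 1.4, sched.n_volumes(1.4))
        with pytest.raises(ValueError, match="volumes"):
            fit_glm(rng.normal(size=(2, 2, 2, 10)), dm)


class TestTToZ:
    def test_large_dof_is_identity(self):
        assert t_to_z(np.array([1.96]), 5000)[0] == pytest.approx(1.96)

    def test_finite_dof_maps_through_distributions(self):
        t = np.array([-3.0, -0.5, 0.0, 0.5, 3.0])
        z = t_to_z(t, 20)
        p = stats.t.sf(t, 20)
        assert np.allclose(stats.norm.sf(z), p, rtol=1e-10)
        assert z[2] == 0.0


class TestPSC:
    def test_zero_beta_gives_zero_psc(self):
        grid = VolumeGrid((6, 6, 6))
        run, sched, mask = _noiseless_run(grid, amp=0.0)
        glm = fit_glm(run, build_design_matrix(sched, 1.4, run.n_volumes))
        assert np.allclose(glm.psc("intact"), 0.0, atol=1e-9)

    def test_doubling_baseline_halves_psc(self):
        grid = VolumeGrid((6, 6, 6))
        center = tuple((s - 1) / 2 for s in grid.shape)
        sched = make_localizer_schedule("language", seed=0)
        truths = make_phantom(grid, [NetworkSpec("net", center, 2.0, {"intact": 1.0})],
                              ["s"], seed=0)
        topo = [sample_subject_topography(truths[0], "s", seed=0, max_shift_vox=0)]
        runs = [simulate_bold_run(grid, truths, topo, sched, "s", "r", seed=0,
                                  noise=NoiseParams(0, 0, 0), baseline=b)
                for b in (100.0, 200.0)]
        dm = build_design_matrix(sched, 1.4, runs[0].n_volumes)
        glms = [fit_glm(r, dm) for r in runs]
        m = truths[0].mask
        # the planted amplitude is relative: the raw beta doubles with the
        # baseline but PSC (beta / baseline) is invariant at 1 percent
        b1 = glms[0].condition_beta("intact")[m]
        b2 = glms[1].condition_beta("intact")[m]
        assert np.allclose(b2, 2.0 * b1)
        assert np.allclose(glms[0].psc("intact")[m], 1.0, atol=1e-9)
        assert np.allclose(glms[1].psc("intact")[m], 1.0, atol=1e-9)


class TestFixedEffects:
    def test_equal_runs_halve_variance(self):
        e = np.full((4, 4, 4), 2.0)
        v = np.full((4, 4, 4), 0.5)
        eff, var, z = fixed_effects_combine([e, e], [v, v])
        assert np.allclose(eff, 2.0)
        assert np.allclose(var, 0.25)

    def test_degenerate_run_is_ignored(self):
        e1 = np.full((3, 3, 3), 1.5)
        v1 = np.full((3, 3, 3), 0.2)
        e2 = np.zeros((3, 3, 3))
        v2 = np.full((3, 3, 3), np.inf)
        eff, var, _ = fixed_effects_combine([e1, e2], [v1, v2])
        assert np.allclose(eff, 1.5)
        assert np.allclose(var, 0.2)

    def test_three_runs_match_weighted_mean_oracle(self, rng):
        effects = [rng.normal(size=(3, 3, 3)) for _ in range(3)]
        variances = [rng.uniform(0.1, 2.0, size=(3, 3, 3)) for _ in range(3)]
        eff, var, _ = fixed_effects_combine(effects, variances)
        e_exp, v_exp = weighted_mean_oracle(effects, variances)
        assert np.allclose(eff, e_exp)
        assert np.allclose(var, v_exp)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_combine([np.zeros((2, 2, 2))], [np.ones((2, 2, 2))])
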