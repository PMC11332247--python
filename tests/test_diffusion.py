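import numpy as np
import pytest
from scipy import integrate, stats

from controlshift.diffusion import (CONGRUENT, INCONGRUENT, DDMShiftParams,
                                    DMCShiftParams, SIGMA_DMC, automatic_drift,
                                    boundary_at, simulate_condition,
                                    simulate_trial, truncnorm_ppf, without_shift)
from helpers import ddm_mean_dt_symmetric, ddm_p_upper


class TestAutomaticDrift:
    def test_zero_at_peak(self):
        assert automatic_drift(0.04, 20.0, 0.04, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_amplitude(self):
        t = np.linspace(0.001, 0.5, 50)
        assert np.allclose(automatic_drift(t, 0.0, 0.04, 2.0), 0.0)

    def test_integral_to_peak_equals_amplitude(self):
        # quadrature oracle: the pulse integrates to the peak activation
        zeta, t_peak, alpha = 17.3, 0.05, 2.0
        val, _err = integrate.quad(automatic_drift, 1e-12, t_peak,
                                   args=(zeta, t_peak, alpha))
        assert val == pytest.approx(zeta, rel=1e-6)

    @pytest.mark.parametrize("alpha", [1.7, 2.0, 3.0])
    def test_integral_other_alphas(self, alpha):
        val, _err = integrate.quad(automatic_drift, 1e-12, 0.03,
                                   args=(11.0, 0.03, alpha))
        assert val == pytest.approx(11.0, rel=1e-5)

    def test_sign_flips_with_zeta(self):
        t = 0.01
        assert automatic_drift(t, 20.0, 0.04) == pytest.approx(
            -automatic_drift(t, -20.0, 0.04))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            automatic_drift(0.01, 20.0, 0.04, alpha=1.0)
        with pytest.raises(ValueError):
            automatic_drift(0.01, 20.0, -0.1)
        with pytest.raises(ValueError):
            automatic_drift(0.0, 20.0, 0.04)


class TestBoundaryAt:
    def test_step_semantics(self):
        assert boundary_at(0.29, 75.0, 11.42, 0.3) == 75.0
        assert boundary_at(0.3, 75.0, 11.42, 0.3) == pytest.approx(86.42)
        assert boundary_at(5.0, 75.0, 11.42, 0.3) == pytest.approx(86.42)

    def test_no_shift_reductions(self):
        t = np.linspace(0, 3, 13)
        assert np.all(boundary_at(t, 0.15, 0.05, np.inf) == 0.15)
        assert np.all(boundary_at(t, 0.15, 0.0, 0.2) == 0.15)

    def test_boundary_crossing_rejected(self):
        with pytest.raises(ValueError):
            boundary_at(0.1, 75.0, -80.0, 0.3)
        with pytest.raises(ValueError):
            boundary_at(0.1, -1.0, 0.0, 0.3)


class TestParamValidation:
    def test_ddm_invalid(self):
        with pytest.raises(ValueError):
            DDMShiftParams(a=-0.1, v_congruent=0.3, v_incongruent=0.2, t0_mean=0.3)
        with pytest.raises(ValueError):
            DDMShiftParams(a=0.15, v_congruent=0.3, v_incongruent=0.2,
                           t0_mean=0.3, z_rel=1.2)
        with pytest.raises(ValueError):
            DDMShiftParams(a=0.15, v_congruent=0.3, v_incongruent=0.2,
                           t0_mean=0.3, shift_delta_congruent=-0.2)

    def test_dmc_invalid(self):
        with pytest.raises(ValueError):
            DMCShiftParams(b=75, mu_c=0.5, zeta=20, t_peak=0.04, t0_mean=0.3,
                           alpha=1.0)
        with pytest.raises(ValueError):
            DMCShiftParams(b=75, mu_c=0.5, zeta=20, t_peak=-0.01, t0_mean=0.3)
        with pytest.raises(ValueError):
            DMCShiftParams(b=75, mu_c=0.5, zeta=20, t_peak=0.04, t0_mean=0.3,
                           shift_delta_incongruent=-75.0)


class TestTruncnormPpf:
    def test_matches_scipy(self):
        u = np.linspace(0.01, 0.99, 21)
        mean, sd = 0.3, 0.1
        ours = truncnorm_ppf(u, mean, sd)
        ref = stats.truncnorm.ppf(u, -mean / sd, np.inf, loc=mean, scale=sd)
        assert np.allclose(ours, ref, atol=1e-10)

    def test_degenerate_sd(self):
        assert np.all(truncnorm_ppf(np.array([0.1, 0.9]), 0.3, 0.0) == 0.3)


class TestSimulateDDM:
    def test_zero_drift_symmetry(self):
        params = DDMShiftParams(a=0.15, v_congruent=0.0, v_incongruent=0.0,
                                t0_mean=0.3)
        res = simulate_condition(params, CONGRUENT, 100_000, 123)
        se = np.sqrt(0.25 / 100_000)
        assert res.accuracy() == pytest.approx(0.5, abs=3 * se)

    def test_matches_closed_form_accuracy_and_rt(self):
        # independent analytic oracle for the no-shift constant-drift walk
        a, v, sigma, t0 = 0.14, 0.22, 0.1, 0.30
        params = DDMShiftParams(a=a, v_congruent=v, v_incongruent=v, t0_mean=t0)
        res = simulate_condition(params, CONGRUENT, 60_000, 5)
        p = ddm_p_upper(a, a / 2, v, sigma)
        assert res.accuracy() == pytest.approx(p, abs=0.01)
        mean_dt = np.nanmean(res.rt[res.valid]) - t0
        assert mean_dt == pytest.approx(ddm_mean_dt_symmetric(a, v, sigma),
                                        abs=0.012)

    def test_boundary_monotonicity(self):
        accs, rts = [], []
        for a in (0.08, 0.14, 0.22):
            params = DDMShiftParams(a=a, v_congruent=0.2, v_incongruent=0.2,
                                    t0_mean=0.3)
            res = simulate_condition(params, CONGRUENT, 20_000, 9)
            accs.append(res.accuracy())
            rts.append(np.nanmean(res.rt[res.valid]))
        assert accs == sorted(accs)
        assert rts == sorted(rts)

    def test_early_boundary_raise_slows_and_improves(self):
        base = DDMShiftParams(a=0.12, v_congruent=0.18, v_incongruent=0.18,
                              t0_mean=0.3)
        shifted = DDMShiftParams(a=0.12, v_congruent=0.18, v_incongruent=0.18,
                                 t0_mean=0.3, shift_delta_congruent=0.08,
                                 shift_time_mean=0.0, shift_time_sd=0.0)
        r0 = simulate_condition(base, CONGRUENT, 50_000, 21)
        r1 = simulate_condition(shifted, CONGRUENT, 50_000, 22)
        assert r1.accuracy() >= r0.accuracy()
        assert np.nanmean(r1.rt[r1.valid]) >= np.nanmean(r0.rt[r0.valid])

    def test_censoring_past_deadline(self):
        params = DDMShiftParams(a=0.3, v_congruent=0.01, v_incongruent=0.01,
                                t0_mean=0.3)
        res = simulate_condition(params, CONGRUENT, 2000, 3, deadline=1.0)
        assert res.censored.any()
        # every non-censored rt respects the deadline and exceeds t0 floor
        assert np.all(res.rt[res.valid] <= 1.0)
        assert np.all(res.rt[res.valid] > 0)

    def test_determinism_and_trial_wrapper(self):
        params = DDMShiftParams(a=0.15, v_congruent=0.3, v_incongruent=0.2,
                                t0_mean=0.3, t0_sd=0.02)
        r1 = simulate_condition(params, INCONGRUENT, 500, 42)
        r2 = simulate_condition(params, INCONGRUENT, 500, 42)
        assert np.array_equal(r1.rt, r2.rt, equal_nan=True)
        assert np.array_equal(r1.response, r2.response)
        t1 = simulate_trial(params, INCONGRUENT, 42)
        one = simulate_condition(params, INCONGRUENT, 1, 42)
        assert t1.rt == one.rt[0] and t1.response == one.response[0]

    def test_se_scaling_with_n(self):
        params = DDMShiftParams(a=0.12, v_congruent=0.25, v_incongruent=0.2,
                                t0_mean=0.3)
        means_small, means_large = [], []
        for rep in range(40):
            small = simulate_condition(params, CONGRUENT, 400, 1000 + rep)
            large = simulate_condition(params, CONGRUENT, 1600, 5000 + rep)
            means_small.append(np.nanmean(small.rt[small.valid]))
            means_large.append(np.nanmean(large.rt[large.valid]))
        ratio = np.std(means_small) / np.std(means_large)
        assert 1.3 < ratio < 3.1  # expect ~2 for a 4x sample-size increase

    def test_invalid_inputs(self):
        params = DDMShiftParams(a=0.15, v_congruent=0.3, v_incongruent=0.2,
                                t0_mean=0.3)
        with pytest.raises(ValueError):
            simulate_condition(params, "weird", 10, 0)
        with pytest.raises(ValueError):
            simulate_condition(params, CONGRUENT, 0, 0)
        with pytest.raises(ValueError):
            simulate_condition(params, CONGRUENT, 10, 0, dt=-0.001)


class TestSimulateDMC:
    def test_fast_errors_on_incongruent(self):
        params = DMCShiftParams(b=60.0, mu_c=0.4, zeta=25.0, t_peak=0.04,
                                t0_mean=0.3, t0_sd=0.03)
        res = simulate_condition(params, INCONGRUENT, 30_000, 17)
        rt = res.rt[res.valid]
        correct = res.response[res.valid] == 1
        edges = np.quantile(rt, [0.2, 0.8])
        acc_fast = correct[rt <= edges[0]].mean()
        acc_slow = correct[rt >= edges[1]].mean()
        assert acc_fast < acc_slow

    def test_congruent_faster_and_more_accurate(self):
        params = DMCShiftParams(b=75.0, mu_c=0.5, zeta=20.0, t_peak=0.04,
                                t0_mean=0.3, t0_sd=0.03)
        rc = simulate_condition(params, CONGRUENT, 30_000, 8)
        ri = simulate_condition(params, INCONGRUENT, 30_000, 9)
        assert rc.accuracy() > ri.accuracy()
        assert rc.correct_rt().mean() < ri.correct_rt().mean()

    def test_zeta_zero_reduces_to_ddm(self):
        # DMC with no automatic activation == DDM with matched scaling
        b, mu_c, t0 = 70.0, 0.45, 0.3
        dmc = DMCShiftParams(b=b, mu_c=mu_c, zeta=0.0, t_peak=0.04, t0_mean=t0)
        ddm = DDMShiftParams(a=2 * b, v_congruent=mu_c * 1000.0,
                             v_incongruent=mu_c * 1000.0, t0_mean=t0,
                             sigma=SIGMA_DMC * np.sqrt(1000.0))
        s_dmc = simulate_condition(dmc, INCONGRUENT, 25_000, 33).signed_rt()
        s_ddm = simulate_condition(ddm, CONGRUENT, 25_000, 34).signed_rt()
        stat, p = stats.ks_2samp(s_dmc, s_ddm)
        assert stat < 0.02
        assert p > 0.01


class TestNoShiftReduction:
    @pytest.mark.parametrize("model", ["ddm", "dmc"])
    def test_zero_delta_matches_base(self, model):
        if model == "ddm":
            base = DDMShiftParams(a=0.13, v_congruent=0.25, v_incongruent=0.15,
                                  t0_mean=0.3, t0_sd=0.03)
        else:
            base = DMCShiftParams(b=75.0, mu_c=0.5, zeta=20.0, t_peak=0.04,
                                  t0_mean=0.3, t0_sd=0.03)
        from dataclasses import replace
        with_shift_machinery = replace(base, shift_delta_congruent=0.0,
                                       shift_delta_incongruent=0.0,
                                       shift_time_mean=0.2, shift_time_sd=0.05)
        s0 = simulate_condition(base, INCONGRUENT, 25_000, 55).signed_rt()
        s1 = simulate_condition(with_shift_machinery, INCONGRUENT, 25_000,
                                56).signed_rt()
        stat, p = stats.ks_2samp(s0, s1)
        assert stat < 0.02
        assert p > 0.01

    def test_without_shift_helper(self):
        p = DDMShiftParams(a=0.15, v_congruent=0.3, v_incongruent=0.2,
                           t0_mean=0.3, shift_delta_congruent=0.05,
                           shift_time_mean=0.2)
        q = without_shift(p)
        assert q.shift_delta_congruent == 0.0 and q.shift_time_mean == 0.0


def test_dt_convergence():
    params = DDMShiftParams(a=0.14, v_congruent=0.22, v_incongruent=0.15,
                            t0_mean=0.3, t0_sd=0.03,
                            shift_delta_congruent=0.05, shift_time_mean=0.2,
                            shift_time_sd=0.05)
    r1 = simulate_condition(params, CONGRUENT, 40_000, 71, dt=0.001)
    r2 = simulate_condition(params, CONGRUENT, 40_000, 72, dt=0.0005)
    assert abs(r1.accuracy() - r2.accuracy()) < 0.01
    assert abs(np.nanmean(r1.rt[r1.valid]) - np.nanmean(r2.rt[r2.valid])) < 0.01
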