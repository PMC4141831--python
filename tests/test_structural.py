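"""Structural model chain: covariate submodels, Cp superposition, the
turnover stage against an independent ODE oracle, and the INR transform."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from warfpop.structural import (
    CovariateSet,
    DoseRegimen,
    GenotypeProfile,
    StructuralParams,
    cl_from_covariates,
    cp_profile,
    ic50_from_covariates,
    inr_from_npt,
    lambda_from_covariates,
    npt_profile,
    simulate_individual,
)


def _cov(bsa=1.74, npt0=119.0, cyp2c9=0, vkorc1=0, cyp4f2=0):
    return CovariateSet(bsa=bsa, npt0=npt0, inr_base=1.05,
                        genotype=GenotypeProfile(cyp2c9, vkorc1, cyp4f2))


class TestCovariateSubmodels:
    @pytest.mark.parametrize("cov,expected", [
        (_cov(), 240.0),                               # reference patient
        (_cov(cyp2c9=1), 240 * 0.543),                 # CYP2C9*1/*3
        (_cov(bsa=1.80), 240 * (1.80 / 1.74) ** 2.14),
    ])
    def test_cl_formula(self, cov, expected):
        assert cl_from_covariates(240, 0.543, 2.14, cov) == pytest.approx(expected)

    @pytest.mark.parametrize("cov,expected", [
        (_cov(), 0.0725),                              # VKORC1*2/*2, CYP4F2*1/*1
        (_cov(vkorc1=1), 0.0725 * 2.07),
        (_cov(vkorc1=1, cyp4f2=1), 0.0725 * 2.07 * 1.30),
    ])
    def test_ic50_formula(self, cov, expected):
        assert ic50_from_covariates(0.0725, 2.07, 1.30, cov) == pytest.approx(expected)

    @pytest.mark.parametrize("npt0,expected", [
        (119.0, 3.48),
        (100.0, 3.48 * np.exp(0.00588 * -19)),
        (140.0, 3.48 * np.exp(0.00588 * 21)),
    ])
    def test_lambda_formula(self, npt0, expected):
        assert lambda_from_covariates(3.48, 0.00588, _cov(npt0=npt0)) == \
            pytest.approx(expected)

    def test_reference_covariates_return_theta_exactly(self):
        """All three submodels return theta at reference/median covariates."""
        assert cl_from_covariates(240, 0.543, 2.14, _cov()) == 240.0
        assert ic50_from_covariates(0.0725, 2.07, 1.30, _cov()) == 0.0725
        assert lambda_from_covariates(3.48, 0.00588, _cov()) == 3.48

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cl_from_covariates(-1, 0.543, 2.14, _cov())
        with pytest.raises(ValueError):
            CovariateSet(bsa=-1, npt0=119, inr_base=1.0)


class TestCpProfile:
    def test_single_dose_closed_form(self, typical_params):
        """5 mg racemic -> 2.5 mg S; hand-evaluated closed form at 24 h."""
        reg = DoseRegimen(np.array([0.0]), np.array([5.0]))
        assert cp_profile(reg, typical_params, [0.0])[0] == 0.0
        assert cp_profile(reg, typical_params, [24.0])[0] == pytest.approx(0.1204,
                                                                           abs=2e-4)

    def test_steady_state_average(self, typical_params):
        """Time-averaged steady-state Cp equals F*(S dose rate)/CL."""
        reg = DoseRegimen.daily([4.34] * 200)
        t = np.linspace(180 * 24, 181 * 24, 481)
        mean_cp = cp_profile(reg, typical_params, t).mean()
        assert mean_cp == pytest.approx(0.5 * 4340 / 24 / 240, rel=5e-3)

    def test_superposition_matches_ode(self, typical_params, daily_regimen):
        """Analytic superposition vs numeric integration of the
        absorption/elimination system (independent oracle)."""
        p = typical_params
        ke = p.cl_s / 1000 / p.vd

        def rhs(t, y):
            a, c = y
            return [-p.ka * a, p.ka * a / p.vd - ke * c]

        t_eval = np.array([6.0, 12.0, 24.0, 100.0, 300.0, 671.0])
        y = np.zeros(2)
        cp_ode = np.zeros_like(t_eval)
        t_prev = 0.0
        events = list(zip(daily_regimen.times, 0.5 * daily_regimen.doses_mg))
        checkpoints = sorted(set(list(t_eval) + [t for t, _ in events]))
        vals = {}
        for t_next in checkpoints:
            if t_next > t_prev:
                sol = solve_ivp(rhs, (t_prev, t_next), y, rtol=1e-11, atol=1e-14)
                y = sol.y[:, -1]
                t_prev = t_next
            vals[t_next] = y[1]
            for td, amt in events:
                if td == t_next:
                    y = y + np.array([amt, 0.0])
        cp_ode = np.array([vals[t] for t in t_eval])
        cp_ana = cp_profile(daily_regimen, p, t_eval)
        np.testing.assert_allclose(cp_ana, cp_ode, rtol=1e-6)

    def test_pk_linearity(self, typical_params, daily_regimen):
        """Doubling every dose doubles Cp at every time."""
        t = np.linspace(0, 500, 40)
        doubled = DoseRegimen(daily_regimen.times, 2 * daily_regimen.doses_mg)
        np.testing.assert_allclose(
            cp_profile(doubled, typical_params, t),
            2 * cp_profile(daily_regimen, typical_params, t), rtol=1e-12)

    def test_flip_flop_limit(self, typical_params):
        """Ka == ke handled by the analytic limit, continuous in Ka."""
        from dataclasses import replace
        ke = typical_params.cl_s / 1000 / typical_params.vd
        p_eq = replace(typical_params, ka=ke, cl_s=typical_params.cl_s)
        p_near = replace(typical_params, ka=ke * (1 + 1e-7))
        reg = DoseRegimen(np.array([0.0]), np.array([5.0]))
        t = [5.0, 50.0]
        np.testing.assert_allclose(cp_profile(reg, p_eq, t),
                                   cp_profile(reg, p_near, t), rtol=1e-4)

    def test_negative_time_rejected(self, typical_params, daily_regimen):
        with pytest.raises(ValueError):
            cp_profile(daily_regimen, typical_params, [-1.0])


class TestNptProfile:
    def test_baseline_steady_state(self, typical_params):
        """Cp == 0 keeps NPT at its baseline."""
        out = npt_profile(lambda t: np.zeros_like(np.asarray(t, float)),
                          typical_params, [0.0, 100.0, 1000.0])
        np.testing.assert_allclose(out, typical_params.npt0, rtol=1e-12)

    def test_half_inhibition_steady_state(self, typical_params):
        """Constant Cp = IC50 drives NPT to half its baseline."""
        p = typical_params
        out = npt_profile(lambda t: np.full(np.asarray(t, float).shape, p.ic50),
                          p, [4000.0])
        assert out[0] == pytest.approx(p.npt0 / 2, rel=1e-6)

    def test_turnover_half_time(self, typical_params):
        """Approach to the new steady state follows exp(-Kout t):
        closed-form linear-ODE solution under constant Cp as oracle."""
        p = typical_params
        t = np.array([25.0, 51.0, 102.0, 300.0])
        out = npt_profile(lambda tt: np.full(np.asarray(tt, float).shape, p.ic50),
                          p, t)
        expect = p.npt0 / 2 * (1 + np.exp(-p.kout * t))
        np.testing.assert_allclose(out, expect, rtol=1e-5)
        assert np.log(2) / p.kout == pytest.approx(51.0, rel=0.01)

    def test_matches_adaptive_ode_oracle(self, typical_params, daily_regimen):
        """Exponential-integrator solution vs scipy's adaptive LSODA, with
        second-order grid convergence."""
        p = typical_params
        cp_fn = lambda t: cp_profile(daily_regimen, p, np.atleast_1d(t))
        times = np.array([24.0, 96.0, 240.0, 480.0, 671.0])
        kin = p.kout * p.npt0

        def rhs(t, y):
            cp = cp_fn([t])[0]
            return kin * (1 - cp / (p.ic50 + cp)) - p.kout * y[0]

        sol = solve_ivp(rhs, (0, 671.0), [p.npt0], t_eval=times,
                        rtol=1e-10, atol=1e-8, method="LSODA")
        fine = npt_profile(cp_fn, p, times, grid_dt=0.125)
        np.testing.assert_allclose(fine, sol.y[0], rtol=2e-4)
        err_c = np.abs(npt_profile(cp_fn, p, times, grid_dt=0.5) - sol.y[0]).max()
        err_f = np.abs(fine - sol.y[0]).max()
        assert err_f < err_c / 4  # O(dt^2)

    def test_stays_within_bounds(self, typical_params, daily_regimen):
        """NPT remains in (0, NPT0] for any non-negative Cp input."""
        p = typical_params
        out = npt_profile(lambda t: cp_profile(daily_regimen, p, np.atleast_1d(t)),
                          p, np.linspace(0, 671, 200))
        assert np.all(out > 0)
        assert np.all(out <= p.npt0 + 1e-9)

    def test_negative_cp_rejected(self, typical_params):
        with pytest.raises(ValueError):
            npt_profile(lambda t: -np.ones(np.asarray(t, float).shape),
                        typical_params, [10.0])


class TestInrTransform:
    def test_endpoints(self, typical_params):
        p = typical_params
        assert inr_from_npt(p.npt0, p) == pytest.approx(p.inr_base)
        assert inr_from_npt(0.0, p) == pytest.approx(p.inr_base + 5.0)

    def test_worked_example(self):
        """INR at 78% inhibition: 1.05 + 5 * 0.78**3.48."""
        p = StructuralParams(cl_s=240, ic50=0.0725, kout=0.0136, npt0=100.0,
                             lam=3.48, inr_base=1.05)
        assert inr_from_npt(100.0 * (1 - 0.78), p) == pytest.approx(3.156, abs=5e-4)

    def test_monotone_and_bounded(self, typical_params):
        p = typical_params
        npt = np.linspace(0, p.npt0, 50)
        inr = np.asarray(inr_from_npt(npt, p))
        assert np.all(np.diff(inr) <= 1e-12)           # decreasing in NPT
        assert inr.min() >= p.inr_base - 1e-12
        assert inr.max() <= p.inr_base + p.inr_max + 1e-12

    def test_noise_above_baseline_clamped(self, typical_params):
        """Observed NPT above baseline maps to baseline INR, not a complex number."""
        out = inr_from_npt(typical_params.npt0 * 1.1, typical_params)
        assert out == pytest.approx(typical_params.inr_base)


class TestSimulateIndividual:
    def test_zero_dose_flat(self, typical_params):
        grid = np.linspace(0, 96, 97)
        empty = DoseRegimen(np.empty(0), np.empty(0))
        traj = simulate_individual(typical_params, empty, grid)
        np.testing.assert_allclose(traj.cp, 0.0)
        np.testing.assert_allclose(traj.npt, typical_params.npt0)
        np.testing.assert_allclose(traj.inr, typical_params.inr_base)

    def test_inr_rises_toward_plateau(self, typical_params):
        """Steady daily dosing: INR increases monotonically to a plateau
        within four weeks (a 3 mg/d typical patient)."""
        reg = DoseRegimen.daily([3.0] * 28)
        grid = np.arange(0.0, 28 * 24 + 1)
        traj = simulate_individual(typical_params, reg, grid)
        daily_inr = traj.inr[::24]
        assert np.all(np.diff(daily_inr) > -1e-6)
        assert daily_inr[-1] - daily_inr[-7] < 0.05 * (daily_inr[-1] - daily_inr[0])
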