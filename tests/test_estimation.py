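"""Mixed-effects engine: OFV against analytic and quadrature oracles,
degenerate parameter recovery, empirical Bayes estimates, and residuals."""

import numpy as np
import pandas as pd
import pytest

from warfpop.cohort import CohortSpec, PopulationTruth, generate_cohort
from warfpop.estimation import (
    LaplaceFitter,
    NPTStageData,
    ParamSpec,
    PKStageData,
    PopulationModel,
    StageData,
    fit_stage_inr,
    fit_stage_npt,
    fit_stage_pk,
    inr_model,
    npt_model,
    pk_model,
    weighted_residuals,
)

LOG2PI = np.log(2 * np.pi)


class ConstantStage(StageData):
    """Toy stage: every observation's prediction is the individual mu."""

    param_names = ("mu",)

    def predict(self, params):
        return np.broadcast_to(params["mu"][:, None], self.y.shape).copy()


def _toy_stage(y_rows):
    y, mask = [], []
    width = max(len(r) for r in y_rows)
    for r in y_rows:
        y.append(list(r) + [0.0] * (width - len(r)))
        mask.append([True] * len(r) + [False] * (width - len(r)))
    y = np.array(y)
    mask = np.array(mask)
    n = y.shape[0]
    cov = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    return ConstantStage(list(range(1, n + 1)), np.zeros_like(y), y, mask, cov)


def _toy_model(theta=1.0, omega=0.5, sigma=1.0, omega_free=True):
    return PopulationModel(
        stage="pk",
        params=[ParamSpec("mu", theta, omega if omega_free else 0.0)],
        sigma_init=sigma)


class TestOfvOracles:
    def test_closed_form_single_observation_no_iiv(self):
        """One patient, one observation, omega = 0: the OFV is the plain
        normal -2 log-likelihood log(2 pi sigma^2) + r^2/sigma^2."""
        theta, sigma, yobs = 2.0, 0.7, 2.9
        stage = _toy_stage([[yobs]])
        fitter = LaplaceFitter(stage, _toy_model(theta, omega_free=False,
                                                 sigma=sigma))
        x = np.array([np.log(theta), np.log(sigma)])
        r = yobs - theta
        expected = LOG2PI + np.log(sigma ** 2) + r ** 2 / sigma ** 2
        assert fitter.ofv(x) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("theta,omega,sigma", [
        (1.0, 0.4, 0.3), (2.5, 0.8, 1.0), (0.5, 0.2, 0.05)])
    def test_laplace_matches_gauss_hermite_oracle(self, theta, omega, sigma):
        """Laplace OFV vs independent high-order Gauss-Hermite integration
        of the 1-D marginal likelihood (two-observation toy)."""
        yobs = [theta * 1.3, theta * 0.8]
        stage = _toy_stage([yobs])
        fitter = LaplaceFitter(stage, _toy_model(theta, omega, sigma))
        x = np.array([np.log(theta), np.log(omega), np.log(sigma)])

        z, w = np.polynomial.hermite.hermgauss(101)     # oracle quadrature
        eta = np.sqrt(2) * omega * z
        mu = theta * np.exp(eta)
        loglik = sum(-0.5 * LOG2PI - np.log(sigma) - (yo - mu) ** 2 /
                     (2 * sigma ** 2) for yo in yobs)
        L = np.sum(w / np.sqrt(np.pi) * np.exp(loglik))
        oracle = -2 * np.log(L)
        # single-node Laplace is close even at large omega; the
        # adaptive-quadrature refinement of the same engine matches the
        # independent oracle to 1e-3
        assert fitter.ofv(x) == pytest.approx(oracle, abs=0.15)
        fitter21 = LaplaceFitter(stage, _toy_model(theta, omega, sigma),
                                 agq_nodes=21)
        assert fitter21.ofv(x) == pytest.approx(oracle, abs=1e-3)

    def test_patient_with_no_usable_info_contributes_prior_mode(self):
        """Zero observations: eta = 0 and the marginal contribution is null."""
        stage = _toy_stage([[1.0], []])
        stage.y[1] = 0.0
        fitter = LaplaceFitter(stage, _toy_model(1.0, 0.5, 1.0))
        solo = _toy_stage([[1.0]])
        f_solo = LaplaceFitter(solo, _toy_model(1.0, 0.5, 1.0))
        x = np.array([0.0, np.log(0.5), 0.0])
        assert fitter.ofv(x) == pytest.approx(f_solo.ofv(x), abs=1e-9)
        eta, params = fitter.ebes(x)
        assert eta[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_ofv_invariant_to_patient_order(self, small_cohort):
        data = PKStageData.from_dataset(small_cohort)
        fitter = LaplaceFitter(data, pk_model())
        x = fitter.x0
        v = fitter.ofv(x)
        perm = np.random.default_rng(0).permutation(data.n)
        fitter_p = LaplaceFitter(data.take(perm), pk_model())
        assert fitter_p.ofv(x) == pytest.approx(v, rel=1e-9)

    def test_nested_model_never_fits_worse(self, small_cohort):
        """Adding a covariate cannot increase the minimised OFV."""
        data = PKStageData.from_dataset(small_cohort)
        base = LaplaceFitter(data, pk_model(covariates=False)).fit(
            with_tables=False)
        full = LaplaceFitter(data, pk_model(covariates=True)).fit(
            x0=None, with_tables=False)
        assert full.ofv <= base.ofv + 1e-3


@pytest.fixture(scope="module")
def degenerate_cohort():
    """Noise-free, IIV-free 12-patient cohort for exact-recovery checks."""
    pop = PopulationTruth(omega_cl=0.0, omega_ic50=0.0, omega_kout=0.0,
                          omega_lam=0.0, sigma_cp=0.0, sigma_npt=0.0,
                          sigma_inr=0.0, sigma_inr_pre=0.0)
    return generate_cohort(spec=CohortSpec(n_patients=12,
                                           missing_npt0_rate=0.0),
                           pop=pop, seed=21)


class TestDegenerateRecovery:
    def test_pk_recovers_generating_parameters(self, degenerate_cohort):
        model = pk_model(cl=180.0, omega_cl=0.0, sigma=0.01)
        model.sigma_fixed = True
        fit = fit_stage_pk(degenerate_cohort, model=model, with_tables=True)
        assert fit.theta["cl"] == pytest.approx(240.0, rel=1e-3)
        assert np.exp(fit.betas["cl:cyp2c9_star3"]) == pytest.approx(0.543,
                                                                     rel=0.05)
        assert fit.betas["cl:bsa"] == pytest.approx(2.14, rel=0.05)

    def test_npt_and_inr_recover_generating_parameters(self, degenerate_cohort):
        pk_m = pk_model(cl=180.0, omega_cl=0.0, sigma=0.01)
        pk_m.sigma_fixed = True
        pk = fit_stage_pk(degenerate_cohort, model=pk_m, with_tables=True)
        npt_m = npt_model(ic50=0.1, kout=0.02, omega_ic50=0.0, omega_kout=0.0,
                          sigma=0.1)
        npt_m.sigma_fixed = True
        npt = fit_stage_npt(degenerate_cohort, pk, model=npt_m,
                            with_tables=True)
        assert npt.theta["ic50"] == pytest.approx(0.0725, rel=0.01)
        assert npt.theta["kout"] == pytest.approx(0.0136, rel=0.01)
        inr_m = inr_model(lam=2.5, omega_lam=0.0, sigma=0.01)
        inr_m.sigma_fixed = True
        inr = fit_stage_inr(degenerate_cohort, pk, npt, model=inr_m,
                            with_tables=True)
        assert inr.theta["lam"] == pytest.approx(3.48, rel=0.02)


@pytest.fixture(scope="module")
def pk_fit_small(small_cohort):
    return fit_stage_pk(small_cohort, with_tables=True)


class TestEbesAndResiduals:
    def test_ebe_correlates_with_truth(self, small_cohort, pk_fit_small):
        merged = pk_fit_small.ebe.merge(small_cohort.truth, on="patient_id")
        r = np.corrcoef(np.log(merged["cl"]), np.log(merged["cl_s"]))[0, 1]
        assert r > 0.8

    def test_wres_centred_and_scaled(self, pk_fit_small):
        w = weighted_residuals(pk_fit_small)["wres"]
        assert abs(w.mean()) < 0.15
        assert 0.8 < w.std() < 1.2

    def test_zero_noise_residuals_vanish(self, degenerate_cohort):
        model = pk_model(cl=180.0, omega_cl=0.0, sigma=0.01)
        model.sigma_fixed = True
        fit = fit_stage_pk(degenerate_cohort, model=model, with_tables=True)
        assert np.abs(fit.predictions["obs"]
                      - fit.predictions["pred_ind"]).max() < 1e-3

    def test_halved_sigma_doubles_residual_scale(self):
        """With sigma misspecified at half its value, weighted residuals
        have SD ~ 2 (pure scaling of the additive error model)."""
        rng = np.random.default_rng(3)
        sigma = 0.4
        y = 2.0 + sigma * rng.standard_normal((40, 5))
        stage = _toy_stage(list(y))
        model = _toy_model(2.0, omega_free=False, sigma=sigma)
        fitter = LaplaceFitter(stage, model)
        x_half = np.array([np.log(2.0), np.log(sigma / 2)])
        tbl = fitter._prediction_table(x_half, fitter._ebe_table(x_half))
        assert tbl["wres"].std() == pytest.approx(2.0, rel=0.25)


class TestSequentialFlags:
    def test_missing_npt0_patients_excluded(self, small_cohort, pk_fit_small):
        npt = fit_stage_npt(small_cohort, pk_fit_small, grid_dt=2.0,
                            maxiter=40, with_tables=True)
        excluded = set(small_cohort.missing_npt0_ids())
        assert excluded
        assert not excluded & set(npt.ebe["patient_id"])

    def test_population_sequencing_flag(self, small_cohort, pk_fit_small):
        """Population-prediction conditioning is available and differs from
        the default EBE-based sequencing."""
        a = fit_stage_npt(small_cohort, pk_fit_small, use_ebe=True,
                          grid_dt=3.0, with_tables=False, maxiter=10)
        b = fit_stage_npt(small_cohort, pk_fit_small, use_ebe=False,
                          grid_dt=3.0, with_tables=False, maxiter=10)
        assert a.ofv != b.ofv
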