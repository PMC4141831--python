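"""Synthetic cohort generator: covariate distributions, Hardy-Weinberg
genotypes, dosing protocols with titration, noise models, and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from warfpop.cohort import (
    DEFAULT_POPULATION,
    CohortSpec,
    PopulationTruth,
    SamplingDesign,
    assign_regimen,
    du_bois_bsa,
    generate_cohort,
    generate_observations,
    predicted_maintenance,
    sample_covariates,
    sample_individual_params,
    write_cohort,
)
from warfpop.dataset import read_dataset
from warfpop.structural import CovariateSet, DoseRegimen, GenotypeProfile


@pytest.fixture(scope="module")
def big():
    return sample_covariates(CohortSpec(n_patients=10000), seed=11)


class TestSampleCovariates:
    def test_genotype_frequencies_match_spec(self, big):
        """Empirical allele frequencies recover the configured MAFs."""
        assert big["cyp2c9_star3"].mean() / 2 == pytest.approx(0.056, abs=0.01)
        assert 1 - big["vkorc1_star1"].mean() / 2 == pytest.approx(0.904, abs=0.01)

    def test_hardy_weinberg_proportions(self, big):
        """Genotype class proportions follow Hardy-Weinberg at the drawn MAF."""
        q = big["vkorc1_star1"].mean() / 2
        counts = big["vkorc1_star1"].value_counts(normalize=True)
        assert counts.get(2, 0) == pytest.approx(q ** 2, abs=0.01)
        assert counts.get(1, 0) == pytest.approx(2 * q * (1 - q), abs=0.015)

    def test_zero_maf_gives_wildtype(self):
        cov = sample_covariates(CohortSpec(n_patients=200, maf_cyp2c9_star3=0.0),
                                seed=3)
        assert (cov["cyp2c9_star3"] == 0).all()

    def test_bsa_distribution_and_formula(self, big):
        """Mean BSA ~= 1.74 m^2 and matches Du Bois from height/weight."""
        assert big["bsa"].mean() == pytest.approx(1.74, abs=0.02)
        np.testing.assert_allclose(
            big["bsa"], du_bois_bsa(big["weight"], big["height"]), rtol=1e-12)

    def test_age_correlations(self, big):
        """Printed correlation structure: age vs weight, BSA and CLcr."""
        assert np.corrcoef(big.age, big.weight)[0, 1] == pytest.approx(-0.358,
                                                                       abs=0.05)
        assert np.corrcoef(big.age, big.bsa)[0, 1] == pytest.approx(-0.397, abs=0.05)
        assert np.corrcoef(big.age, big.clcr)[0, 1] == pytest.approx(-0.568,
                                                                     abs=0.05)

    def test_infeasible_correlations_rejected(self):
        spec = CohortSpec(correlations={("age", "weight"): 0.99,
                                        ("age", "height"): 0.99,
                                        ("weight", "height"): -0.99})
        with pytest.raises(ValueError):
            sample_covariates(spec, seed=0)


class TestRegimens:
    def test_standard_loading(self, wildtype_cov):
        """Standard protocol: three 5.0 mg loading days (the printed
        standard starting dose), then the titration-free maintenance."""
        reg = assign_regimen(wildtype_cov, "standard")
        assert list(reg.doses_mg[:3]) == [5.0, 5.0, 5.0]
        assert reg.times[1] - reg.times[0] == 24.0

    def test_genotype_mean_starting_dose(self):
        """Genotype-guided group mean starting dose ~= 4.1 mg/d."""
        cov = sample_covariates(CohortSpec(n_patients=4000), seed=5)
        doses = []
        for _, r in cov.iterrows():
            g = GenotypeProfile(int(r.cyp2c9_star3), int(r.vkorc1_star1),
                                int(r.cyp4f2_star3_carrier))
            m = predicted_maintenance(g, "genotype")
            doses.append(max(0.5, round(1.5 * m * 2) / 2))
        assert np.mean(doses) == pytest.approx(4.1, abs=0.3)

    def test_titration_holds_in_range(self, wildtype_cov, noise_free_population):
        """No dose changes when the simulated INR stays within 2-3."""
        p, _ = sample_individual_params(
            noise_free_population, wildtype_cov, np.random.default_rng(0))
        # a patient whose INR settles inside the target band on ~3 mg/d
        reg0 = assign_regimen(wildtype_cov, "genotype")
        rec = []
        reg = assign_regimen(wildtype_cov, "genotype", params=p,
                             rng=np.random.default_rng(1), sigma_inr=0.0,
                             inr_record=rec)
        inr_vals = [v for _, v in rec]
        in_range = [2.0 <= v <= 3.0 for v in inr_vals]
        if all(in_range):
            np.testing.assert_array_equal(reg.doses_mg, reg0.doses_mg)
        # titration INR measurements are recorded at every scheduled check
        assert len(rec) == len(SamplingDesign().titration_check_days)

    def test_unknown_protocol(self, wildtype_cov):
        with pytest.raises(ValueError):
            predicted_maintenance(wildtype_cov.genotype, "adhoc")


class TestIndividualParams:
    def test_zero_omega_returns_typical(self, wildtype_cov, noise_free_population):
        p, etas = sample_individual_params(noise_free_population, wildtype_cov,
                                           np.random.default_rng(0))
        assert p.cl_s == pytest.approx(240.0)
        assert p.ic50 == pytest.approx(0.0725)
        assert all(v == 0.0 for v in etas.values())

    def test_lognormal_iiv_recovered(self, wildtype_cov):
        """SD of log CL residuals ~= omega_CL over many draws; the median of
        the multiplicative random effect is 1 (log-normal median)."""
        rng = np.random.default_rng(2)
        draws = np.array([sample_individual_params(DEFAULT_POPULATION,
                                                   wildtype_cov, rng)[0].cl_s
                          for _ in range(4000)])
        logres = np.log(draws / 240.0)
        assert logres.std() == pytest.approx(0.399, abs=0.02)
        assert np.median(draws) == pytest.approx(240.0, rel=0.03)


class TestObservations:
    def test_zero_noise_equals_truth(self, typical_params, daily_regimen):
        pop = PopulationTruth(sigma_cp=0.0, sigma_npt=0.0, sigma_inr=0.0,
                              sigma_inr_pre=0.0)
        obs = generate_observations(typical_params, daily_regimen,
                                    SamplingDesign(), pop,
                                    np.random.default_rng(0))
        from warfpop.structural import cp_profile
        cp = obs[obs.obs_type == "CP"]
        np.testing.assert_allclose(
            cp["value"], cp_profile(daily_regimen, typical_params,
                                    cp["time_h"].to_numpy()), rtol=1e-9)
        pre = obs[(obs.obs_type == "INR") & (obs.time_h <= 0)]
        np.testing.assert_allclose(pre["value"], typical_params.inr_base)

    def test_residual_noise_magnitudes(self, typical_params):
        """Empirical residual SDs recover the generating sigmas (dosing spans
        the whole sampling window so the zero floor stays inactive)."""
        from warfpop.structural import cp_profile, inr_from_npt, npt_profile
        regimen = DoseRegimen.daily([7.5] * 3 + [5.0] * 88)
        rng = np.random.default_rng(4)
        cp_res, npt_res, inr_rel = [], [], []
        for _ in range(60):
            obs = generate_observations(typical_params, regimen,
                                        SamplingDesign(), DEFAULT_POPULATION, rng)
            cp = obs[obs.obs_type == "CP"]
            truth = cp_profile(regimen, typical_params,
                               cp["time_h"].to_numpy())
            cp_res += list(cp["value"].to_numpy() - truth)
            npt = obs[obs.obs_type == "NPT"]
            truth_n = npt_profile(
                lambda t: cp_profile(regimen, typical_params,
                                     np.atleast_1d(t)),
                typical_params, npt["time_h"].clip(lower=0).to_numpy())
            npt_res += list(npt["value"].to_numpy() - truth_n)
            inr = obs[(obs.obs_type == "INR") & (obs.time_h > 0)]
            truth_i = inr_from_npt(npt_profile(
                lambda t: cp_profile(regimen, typical_params,
                                     np.atleast_1d(t)),
                typical_params, inr["time_h"].to_numpy()), typical_params)
            inr_rel += list(inr["value"].to_numpy() / np.asarray(truth_i) - 1)
        assert np.std(cp_res) == pytest.approx(0.0697, rel=0.15)
        assert np.std(npt_res) == pytest.approx(12.2, rel=0.15)
        assert np.std(inr_rel) == pytest.approx(0.247, rel=0.15)

    def test_all_times_within_followup(self, small_cohort):
        t = small_cohort.observations["time_h"]
        assert t.min() >= -15 * 24
        assert t.max() <= 92 * 24


class TestWholeCohort:
    def test_design_counts(self, small_cohort):
        obs = small_cohort.observations
        per = obs.groupby(["patient_id", "obs_type"]).size().unstack()
        assert per["INR"].between(8, 14).all()
        assert per["CP"].between(1, 12).all()
        assert per["NPT"].between(4, 12).all()

    def test_reproducible(self):
        a = generate_cohort(spec=CohortSpec(n_patients=5), seed=9)
        b = generate_cohort(spec=CohortSpec(n_patients=5), seed=9)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_missing_npt0_count(self, small_cohort):
        assert len(small_cohort.missing_npt0_ids()) == round(0.03 * 30)

    def test_roundtrip_through_csv(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(back.covariates, small_cohort.covariates)
        pd.testing.assert_frame_equal(back.observations,
                                      small_cohort.observations)
        pd.testing.assert_frame_equal(back.dosing, small_cohort.dosing)

    def test_empty_cohort_headers_only(self, tmp_path):
        ds = generate_cohort(spec=CohortSpec(n_patients=0), seed=0)
        paths = write_cohort(ds, tmp_path)
        assert pd.read_csv(paths["observations"]).empty

    def test_full_cohort_row_counts(self):
        """99 patients: 99 covariate rows and ~1,100 INR rows (11.1/patient)."""
        ds = generate_cohort(seed=5)
        assert len(ds.covariates) == 99
        n_inr = (ds.observations.obs_type == "INR").sum()
        assert 950 <= n_inr <= 1300
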