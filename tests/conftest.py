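import numpy as np
import pytest

from warfpop.cohort import CohortSpec, PopulationTruth, SamplingDesign, generate_cohort
from warfpop.structural import CovariateSet, DoseRegimen, GenotypeProfile, StructuralParams


@pytest.fixture(scope="session")
def typical_params() -> StructuralParams:
    """Reference patient at the covariate medians."""
    return StructuralParams(cl_s=240.0, ic50=0.0725, kout=0.0136, npt0=119.0,
                            lam=3.48, inr_base=1.05)


@pytest.fixture(scope="session")
def daily_regimen() -> DoseRegimen:
    """Three 7.5 mg loading days then 5 mg/d for four weeks."""
    return DoseRegimen.daily([7.5] * 3 + [5.0] * 25)


@pytest.fixture
def wildtype_cov() -> CovariateSet:
    return CovariateSet(bsa=1.74, npt0=119.0, inr_base=1.05,
                        genotype=GenotypeProfile(0, 0, 0))


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient cohort reused by estimation-level tests."""
    return generate_cohort(spec=CohortSpec(n_patients=30), seed=7)


@pytest.fixture(scope="session")
def noise_free_population() -> PopulationTruth:
    """Degenerate generating model: no IIV, no residual noise."""
    return PopulationTruth(omega_cl=0.0, omega_ic50=0.0, omega_kout=0.0,
                           omega_lam=0.0, sigma_cp=0.0, sigma_npt=0.0,
                           sigma_inr=0.0, sigma_inr_pre=0.0)
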