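"""Synthetic cohort generator.

Emulates a 99-patient warfarin-initiation cohort: covariate distributions
and genotype frequencies of an Asian (Taiwanese) population, the two dosing
protocols (genotype-guided vs standard 5 mg/d start, both with three 1.5x
loading days and INR-driven titration toward the 2-3 target), the sparse
outpatient sampling schedule over three months of follow-up, log-normal
inter-individual variability on CL(S), IC50, Kout and lambda, and the
residual-error models (additive for Cp and NPT, relative for INR).

All randomness flows from one master seed; per-patient generators are
spawned deterministically so cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from warfpop.dataset import Dataset, validate_dataset, write_dataset
from warfpop.structural import (
    CovariateSet,
    DoseRegimen,
    GenotypeProfile,
    StructuralParams,
    cp_profile,
    inr_from_npt,
    npt_profile,
    params_from_covariates,
)


# ---------------------------------------------------------------------------
# Population truth (fixed effects, IIV, residual errors of the final model)
# ---------------------------------------------------------------------------

@dataclass
class PopulationTruth:
    """Generating population model: typical values, IIV (SD of log-scale
    random effects) and residual errors."""

    theta_cl: float = 240.0          # mL/h, reference CL(S)
    eff_cyp2c9: float = 0.543        # multiplier per CYP2C9*3 allele
    eff_bsa: float = 2.14            # power exponent on BSA/1.74
    theta_ic50: float = 0.0725       # ug/mL, VKORC1*2/*2 & CYP4F2*1/*1 reference
    eff_vkorc1: float = 2.07         # multiplier per VKORC1*1 allele
    eff_cyp4f2: float = 1.30         # multiplier for CYP4F2*3 carriers
    kout: float = 0.0136             # 1/h
    theta_lam: float = 3.48          # exponent at NPT0 = 119
    eff_npt0: float = 0.00588        # 1/(ug/mL)
    omega_cl: float = 0.399          # SD of eta_CL
    omega_ic50: float = 0.385
    omega_kout: float = 0.456
    omega_lam: float = 0.241
    sigma_cp: float = 0.0697         # ug/mL, additive
    sigma_npt: float = 12.2          # ug/mL, additive
    sigma_inr: float = 0.247         # relative (fraction of prediction)
    sigma_inr_pre: float = 0.05      # absolute SD of pre-treatment INR readings


DEFAULT_POPULATION = PopulationTruth()


# ---------------------------------------------------------------------------
# Cohort and sampling-design specifications
# ---------------------------------------------------------------------------

#: (mean, sd, lower, upper) of the truncated-normal covariate marginals
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "age": (64.5, 15.2, 20.0, 95.0),
    "weight": (68.4, 12.4, 35.0, 120.0),
    "height": (163.6, 8.2, 140.0, 190.0),
    "clcr": (73.3, 36.6, 10.0, 200.0),
    "npt0": (118.2, 22.1, 50.0, 200.0),
    "inr_base": (1.05, 0.10, 0.80, 1.50),
    "ast": (29.2, 16.3, 8.0, 120.0),
    "alt": (27.2, 17.5, 5.0, 150.0),
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "sex_female": 39 / 99,
    "diabetes": 19 / 99,
    "hypertension": 66 / 99,
    "hepatic_disease": 10 / 99,
    "ckd": 16 / 99,
    "chf": 0.10,
    "alcohol": 28 / 99,
    "smoking": 20 / 99,
    "atrial_fibrillation": 54 / 99,
    "stroke": 29 / 99,
    "dvt": 25 / 99,
}

#: Gaussian-copula correlations; age-height is calibrated so that the
#: implied age-BSA correlation comes out near the observed -0.397.
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("age", "weight"): -0.358,
    ("age", "height"): -0.17,
    ("age", "clcr"): -0.568,
}


@dataclass
class CohortSpec:
    """What cohort to generate."""

    n_patients: int = 99
    maf_cyp2c9_star3: float = 0.056
    freq_vkorc1_star2: float = 0.904          # -1639A allele; *1 freq = 1 - this
    maf_cyp4f2_star3: float = 0.278
    covariate_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS))
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    protocol_mix: float = 77 / 99             # fraction genotype-guided
    missing_npt0_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name in ("maf_cyp2c9_star3", "freq_vkorc1_star2", "maf_cyp4f2_star3",
                     "protocol_mix", "missing_npt0_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SamplingDesign:
    """Observation windows and per-type counts of the sparse outpatient design.

    Post-dose draws sit at scheduled visit days with +/- ``jitter_h`` uniform
    jitter; INR is additionally anchored at day 4 and weeks 1, 2 and 4, and
    at least five pre-treatment INR readings define the baseline.
    """

    pre_inr_days: tuple[float, ...] = (-14, -12, -10, -7, -5, -3, -1)
    n_pre_inr: tuple[int, int] = (5, 6)
    post_visit_days: tuple[float, ...] = (4, 7, 10, 14, 21, 28, 35, 42, 56, 70, 77, 84)
    n_inr_extra: tuple[int, int] = (0, 2)       # beyond the titration visits
    n_cp: tuple[int, int] = (6, 12)
    # NPT is drawn at the protocol visits: always at days 4, 7, 14 and 28,
    # optionally at later follow-ups, plus pre-treatment draws alongside the
    # baseline sample (pre-treatment blood draws included NPT measurement)
    npt_anchor_days: tuple[float, ...] = (4, 7, 14, 28)
    npt_extra_days: tuple[float, ...] = (42, 56, 70, 84)
    n_npt_extra: tuple[int, int] = (1, 3)
    n_npt_pre: tuple[int, int] = (2, 3)         # beyond the t=0 baseline
    jitter_h: float = 6.0
    followup_days: float = 91.0
    titration_check_days: tuple[float, ...] = (4, 7, 14, 28, 56)


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------

def du_bois_bsa(weight_kg: np.ndarray, height_cm: np.ndarray) -> np.ndarray:
    """Du Bois body surface area in m^2."""
    return 0.007184 * np.power(weight_kg, 0.425) * np.power(height_cm, 0.725)


def _copula_matrix(spec: CohortSpec, order: list[str]) -> np.ndarray:
    k = len(order)
    r = np.eye(k)
    for (a, b), rho in spec.correlations.items():
        i, j = order.index(a), order.index(b)
        r[i, j] = r[j, i] = rho
    evals = np.linalg.eigvalsh(r)
    if evals.min() <= 1e-10:
        raise ValueError("covariate correlation matrix is not positive definite")
    return r


def sample_covariates(spec: CohortSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw patient covariates, genotypes and protocol assignments.

    Correlated continuous covariates (age, weight, height, CLcr) come from a
    Gaussian copula with truncated-normal marginals; BSA is derived from
    height and weight (Du Bois); genotypes are Hardy-Weinberg draws at the
    specified allele frequencies; binary covariates are independent
    Bernoulli at the cohort prevalences.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_patients
    corr_vars = ["age", "weight", "height", "clcr"]
    r = _copula_matrix(spec, corr_vars)
    z = rng.multivariate_normal(np.zeros(len(corr_vars)), r, size=n,
                                method="cholesky") if n else np.empty((0, len(corr_vars)))
    cols: dict[str, np.ndarray] = {"patient_id": np.arange(1, n + 1)}

    def trunc_ppf(u, name):
        mu, sd, lo, hi = spec.covariate_distributions[name]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)

    for j, name in enumerate(corr_vars):
        cols[name] = trunc_ppf(stats.norm.cdf(z[:, j]), name)
    for name in ("npt0", "inr_base", "ast", "alt"):
        cols[name] = trunc_ppf(rng.uniform(size=n), name)
    cols["bsa"] = du_bois_bsa(cols["weight"], cols["height"])
    cols["bmi"] = cols["weight"] / (cols["height"] / 100.0) ** 2
    # genotypes: per-locus Hardy-Weinberg
    cols["cyp2c9_star3"] = rng.binomial(2, spec.maf_cyp2c9_star3, size=n)
    cols["vkorc1_star1"] = rng.binomial(2, 1.0 - spec.freq_vkorc1_star2, size=n)
    cols["cyp4f2_star3_carrier"] = (rng.binomial(2, spec.maf_cyp4f2_star3, size=n)
                                    >= 1).astype(int)
    for name, p in spec.prevalences.items():
        cols[name] = rng.binomial(1, p, size=n)
    cols["protocol"] = np.where(rng.uniform(size=n) < spec.protocol_mix,
                                "genotype", "standard")
    # deterministic count of patients with missing baseline NPT
    n_missing = int(round(spec.missing_npt0_rate * n))
    if n_missing:
        miss = rng.choice(n, size=n_missing, replace=False)
        npt0 = cols["npt0"].astype(float)
        cols["npt0_true"] = npt0.copy()
        npt0[miss] = np.nan
        cols["npt0"] = npt0
    else:
        cols["npt0_true"] = cols["npt0"].astype(float).copy()
    df = pd.DataFrame(cols)
    return df


# ---------------------------------------------------------------------------
# Dosing protocols
# ---------------------------------------------------------------------------

#: calibrated genotype-guided maintenance-dose table (mg/d): base dose for the
#: VKORC1*2/*2, CYP2C9*1/*1 patient, scaled per VKORC1*1 allele and per
#: CYP2C9*3 allele; calibration target is the observed group mean starting
#: doses (4.1 mg/d genotype-guided, 5.0 mg/d standard).
GENO_BASE_DOSE = 2.75
GENO_VKORC1_FACTOR = 1.35
GENO_CYP2C9_FACTOR = 0.60
STANDARD_LOADING = 5.0
TITRATION_STEP = 0.5


def _round_half_mg(x: float) -> float:
    return max(0.5, round(x * 2.0) / 2.0)


def predicted_maintenance(genotype: GenotypeProfile, protocol: str) -> float:
    """Protocol-predicted maintenance dose (mg/d, unrounded) before titration."""
    if protocol == "genotype":
        return (GENO_BASE_DOSE * GENO_VKORC1_FACTOR ** genotype.vkorc1_star1
                * GENO_CYP2C9_FACTOR ** genotype.cyp2c9_star3)
    if protocol == "standard":
        return STANDARD_LOADING / 1.5
    raise ValueError(f"unknown protocol {protocol!r}")


def assign_regimen(cov: CovariateSet, protocol: str,
                   params: StructuralParams | None = None,
                   rng: np.random.Generator | None = None,
                   design: SamplingDesign | None = None,
                   sigma_inr: float = DEFAULT_POPULATION.sigma_inr,
                   inr_record: list | None = None) -> DoseRegimen:
    """Daily dosing under a protocol: 3 loading days at 1.5x the predicted
    maintenance dose, then +/-0.5 mg titration driven by the measured INR
    at the scheduled visits (hold within 2-3, larger step down at INR >= 4).

    The titration decisions use noisy INR *measurements*; when
    ``inr_record`` is given, each (time_h, value) pair is appended to it so
    the very measurements that drove dosing become part of the emitted
    observation series (dose adaptation is then ignorable for estimation).
    Without ``params`` the regimen is the untitrated protocol schedule.
    """
    design = design or SamplingDesign()
    m_raw = predicted_maintenance(cov.genotype, protocol)
    loading = _round_half_mg(1.5 * m_raw)
    m = _round_half_mg(m_raw)
    n_days = int(design.followup_days)
    daily = np.full(n_days, m)
    daily[:3] = loading
    if params is not None:
        rng = rng or np.random.default_rng(0)
        dose = m
        for day in design.titration_check_days:
            day = int(day)
            if day >= n_days:
                break
            # blood draw at the visit, before that day's (possibly adjusted)
            # dose intake
            t_check = day * 24.0 - rng.uniform(0.0, design.jitter_h)
            reg = DoseRegimen.daily(daily[:day])
            npt = npt_profile(lambda tt: cp_profile(reg, params, tt), params,
                              [t_check], grid_dt=0.25)[0]
            inr_true = inr_from_npt(npt, params)
            inr_obs = inr_true * (1.0 + sigma_inr * rng.standard_normal())
            if inr_record is not None:
                inr_record.append((t_check, float(inr_obs)))
            if inr_obs >= 4.0:
                dose = max(0.5, dose - 2 * TITRATION_STEP)
            elif inr_obs > 3.0:
                dose = max(0.5, dose - TITRATION_STEP)
            elif inr_obs < 2.0:
                dose = dose + TITRATION_STEP
            daily[day:] = dose
    return DoseRegimen.daily(daily)


# ---------------------------------------------------------------------------
# Individual parameters and observations
# ---------------------------------------------------------------------------

def sample_individual_params(pop: PopulationTruth, cov: CovariateSet,
                             rng: np.random.Generator,
                             npt0_true: float | None = None,
                             ) -> tuple[StructuralParams, dict[str, float]]:
    """Individual parameters: covariate-model typical value x exp(eta)."""
    etas = {
        "eta_cl": pop.omega_cl * rng.standard_normal(),
        "eta_ic50": pop.omega_ic50 * rng.standard_normal(),
        "eta_kout": pop.omega_kout * rng.standard_normal(),
        "eta_lam": pop.omega_lam * rng.standard_normal(),
    }
    cov_eff = cov
    if npt0_true is not None and np.isnan(cov.npt0):
        from dataclasses import replace
        cov_eff = replace(cov, npt0=npt0_true)
    typ = params_from_covariates(
        cov_eff,
        theta_cl=pop.theta_cl, eff_cyp2c9=pop.eff_cyp2c9, eff_bsa=pop.eff_bsa,
        theta_ic50=pop.theta_ic50, eff_vkorc1=pop.eff_vkorc1,
        eff_cyp4f2=pop.eff_cyp4f2, kout=pop.kout,
        theta_lam=pop.theta_lam, eff_npt0=pop.eff_npt0)
    from dataclasses import replace
    p = replace(typ,
                cl_s=typ.cl_s * np.exp(etas["eta_cl"]),
                ic50=typ.ic50 * np.exp(etas["eta_ic50"]),
                kout=typ.kout * np.exp(etas["eta_kout"]),
                lam=typ.lam * np.exp(etas["eta_lam"]))
    return p, etas


def _draw_times(rng: np.random.Generator, design: SamplingDesign,
                days_pool, count_range, anchors=()) -> np.ndarray:
    lo, hi = count_range
    n_total = int(rng.integers(lo, hi + 1))
    pool = [d for d in days_pool if d not in anchors]
    n_extra = max(0, n_total - len(anchors))
    extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
    days = np.sort(np.concatenate([np.asarray(anchors, float),
                                   np.asarray(extra, float)]))
    times = days * 24.0 + rng.uniform(-design.jitter_h, design.jitter_h, size=days.size)
    return times


def generate_observations(p: StructuralParams, regimen: DoseRegimen,
                          design: SamplingDesign, pop: PopulationTruth,
                          rng: np.random.Generator,
                          titration_inr: list | None = None) -> pd.DataFrame:
    """Noisy sparse observations of Cp, NPT and INR for one individual.

    Additive Cp/NPT noise draws that would go negative are truncated at 0;
    INR uses the relative-error model. Pre-treatment INR readings scatter
    around the baseline INR with a small absolute SD, the baseline NPT is
    observed at t = 0, and the INR measurements that drove dose titration
    (``titration_inr``: (time_h, value) pairs) are emitted as observations.
    """
    rows = []
    # pre-treatment INR defines the baseline
    n_pre = int(rng.integers(design.n_pre_inr[0], design.n_pre_inr[1] + 1))
    pre_days = np.sort(rng.choice(design.pre_inr_days, size=n_pre, replace=False))
    for d in pre_days:
        t = d * 24.0 + rng.uniform(-design.jitter_h, design.jitter_h)
        val = p.inr_base + pop.sigma_inr_pre * rng.standard_normal()
        rows.append(("INR", t, max(val, 0.5)))
    for t, v in (titration_inr or []):
        rows.append(("INR", t, v))
    # additional on-treatment INR beyond the titration visits
    taken = {round(t / 24.0) for t, _ in (titration_inr or [])}
    extra_pool = [d for d in design.post_visit_days if d not in taken]
    t_inr = _draw_times(rng, design, extra_pool, design.n_inr_extra)
    t_inr = np.clip(t_inr, 1.0, None)
    # Cp(S)
    t_cp = _draw_times(rng, design, design.post_visit_days, design.n_cp)
    t_cp = np.clip(t_cp, 1.0, None)
    # NPT: pre-treatment draws, the t=0 baseline, the anchored protocol
    # visits, and optional later follow-ups
    n_npt_pre = int(rng.integers(design.n_npt_pre[0], design.n_npt_pre[1] + 1))
    npt_pre_days = rng.choice(design.pre_inr_days, size=n_npt_pre, replace=False)
    t_npt_pre = npt_pre_days * 24.0 + rng.uniform(-design.jitter_h,
                                                  design.jitter_h, n_npt_pre)
    lo, hi = design.n_npt_extra
    n_extra = int(rng.integers(lo, hi + 1))
    extra_days = rng.choice(design.npt_extra_days, size=n_extra, replace=False)
    npt_days = np.sort(np.concatenate([np.asarray(design.npt_anchor_days, float),
                                       np.asarray(extra_days, float)]))
    t_npt_post = npt_days * 24.0 + rng.uniform(-design.jitter_h, design.jitter_h,
                                               npt_days.size)
    t_npt = np.concatenate([np.sort(t_npt_pre), [0.0],
                            np.clip(t_npt_post, 1.0, None)])

    cp_fn = lambda tt: cp_profile(regimen, p, tt)
    cp_true = cp_fn(t_cp)
    # pre-treatment NPT sits at the baseline steady state
    npt_true = npt_profile(cp_fn, p, np.clip(t_npt, 0.0, None), grid_dt=0.25)
    inr_true = inr_from_npt(npt_profile(cp_fn, p, t_inr, grid_dt=0.25), p)

    for t, v in zip(t_cp, cp_true):
        rows.append(("CP", t, max(v + pop.sigma_cp * rng.standard_normal(), 0.0)))
    for t, v in zip(t_npt, npt_true):
        rows.append(("NPT", t, max(v + pop.sigma_npt * rng.standard_normal(), 0.0)))
    for t, v in zip(t_inr, np.atleast_1d(inr_true)):
        rows.append(("INR", t, v * (1.0 + pop.sigma_inr * rng.standard_normal())))
    df = pd.DataFrame(rows, columns=["obs_type", "time_h", "value"])
    return df.sort_values(["obs_type", "time_h"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec | None = None,
                    design: SamplingDesign | None = None,
                    pop: PopulationTruth | None = None,
                    seed: int = 0) -> Dataset:
    """Generate a full synthetic cohort dataset (with a truth table)."""
    spec = spec or CohortSpec()
    design = design or SamplingDesign()
    pop = pop or DEFAULT_POPULATION
    master = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(master.spawn(1)[0])
    cov_df = sample_covariates(spec, cov_rng)
    patient_streams = master.spawn(spec.n_patients)

    dosing_rows, obs_rows, truth_rows = [], [], []
    for i, (_, row) in enumerate(cov_df.iterrows()):
        rng = np.random.default_rng(patient_streams[i])
        pid = int(row["patient_id"])
        geno = GenotypeProfile(int(row["cyp2c9_star3"]), int(row["vkorc1_star1"]),
                               int(row["cyp4f2_star3_carrier"]))
        npt0_true = float(row["npt0_true"])
        cov = CovariateSet(
            bsa=float(row["bsa"]), npt0=npt0_true, inr_base=float(row["inr_base"]),
            genotype=geno, age=float(row["age"]), weight=float(row["weight"]),
            height=float(row["height"]), sex_female=int(row["sex_female"]),
            alt=float(row["alt"]), ast=float(row["ast"]), clcr=float(row["clcr"]),
            diabetes=int(row["diabetes"]), hypertension=int(row["hypertension"]),
            hepatic_disease=int(row["hepatic_disease"]), ckd=int(row["ckd"]),
            chf=int(row["chf"]), alcohol=int(row["alcohol"]),
            smoking=int(row["smoking"]),
            atrial_fibrillation=int(row["atrial_fibrillation"]),
            stroke=int(row["stroke"]), dvt=int(row["dvt"]))
        p, etas = sample_individual_params(pop, cov, rng)
        titration_inr: list = []
        regimen = assign_regimen(cov, str(row["protocol"]), params=p, rng=rng,
                                 design=design, sigma_inr=pop.sigma_inr,
                                 inr_record=titration_inr)
        for t, d in zip(regimen.times, regimen.doses_mg):
            dosing_rows.append((pid, t, d))
        obs = generate_observations(p, regimen, design, pop, rng,
                                    titration_inr=titration_inr)
        obs.insert(0, "patient_id", pid)
        obs_rows.append(obs)
        truth_rows.append({
            "patient_id": pid, "cl_s": p.cl_s, "ic50": p.ic50, "kout": p.kout,
            "lam": p.lam, "npt0_true": npt0_true, "inr_base_true": cov.inr_base,
            **etas,
            "maintenance_pred": predicted_maintenance(geno, str(row["protocol"])),
        })

    dosing = pd.DataFrame(dosing_rows, columns=["patient_id", "time_h", "dose_mg"])
    observations = (pd.concat(obs_rows, ignore_index=True)
                    [["patient_id", "time_h", "obs_type", "value"]]
                    if obs_rows else
                    pd.DataFrame(columns=["patient_id", "time_h", "obs_type", "value"]))
    truth = pd.DataFrame(truth_rows)
    cov_out = cov_df.drop(columns=["npt0_true"])
    ds = Dataset(covariates=cov_out, dosing=dosing, observations=observations,
                 truth=truth)
    return validate_dataset(ds) if spec.n_patients else ds


def write_cohort(ds: Dataset, out_dir) -> dict:
    """Write the cohort tables (dosing, observations, covariates, truth)."""
    return write_dataset(ds, out_dir)
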