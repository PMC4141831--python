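"""End-to-end orchestration: configuration, the reproducible reference run,
and report assembly.

``run_pipeline`` chains simulate -> sequential fits -> (optional) covariate
search -> (optional) bootstrap -> cohort statistics -> report.  Every random
draw flows from the config seed; two runs with the same config produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from warfpop import boot, cohortstats, covsearch
from warfpop.cohort import (
    DEFAULT_POPULATION,
    CohortSpec,
    PopulationTruth,
    SamplingDesign,
    generate_cohort,
)
from warfpop.dataset import Dataset, read_dataset, write_dataset
from warfpop.estimation import (
    FitResult,
    LaplaceFitter,
    NPTStageData,
    PKStageData,
    cl_by_patient,
    fit_stage_inr,
    fit_stage_npt,
    fit_stage_pk,
    inr_model,
    npt_model,
    pk_model,
)

logger = logging.getLogger("warfpop")


@dataclass
class RunConfig:
    """Settings of one reproducible analysis run (defaults = reference run)."""

    n_patients: int = 99
    seed: int = 1
    out_dir: str = "warfpop_run"
    protocol_mix: float = 77 / 99
    grid_dt: float = 0.5                 # h, PD integration grid
    forward_dofv: float = 3.84           # covariate entry, chi2(1) P<0.05
    backward_dofv: float = 6.63          # covariate removal, chi2(1) P<0.01
    bootstrap_n: dict = field(default_factory=lambda: {"pk": 1000, "npt": 100,
                                                       "inr": 1000})
    run_covsearch: bool = False
    run_bootstrap: bool = False
    n_starts: int = 1

    def validate(self) -> "RunConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.protocol_mix <= 1.0:
            raise ValueError("protocol_mix must be in [0, 1]")
        if self.grid_dt <= 0:
            raise ValueError("grid_dt must be positive")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text())).validate()


#: report rows: (key, unit, reference value under the generating model, scale)
def _reference_rows(pop: PopulationTruth):
    return [
        ("cl", "mL/h", pop.theta_cl),
        ("eff_bsa_on_cl", "", pop.eff_bsa),
        ("eff_cyp2c9_on_cl", "", pop.eff_cyp2c9),
        ("omega_cl", "%", pop.omega_cl * 100),
        ("sigma_cp", "ug/mL", pop.sigma_cp),
        ("ic50", "ug/mL", pop.theta_ic50),
        ("kout", "1/h", pop.kout),
        ("eff_vkorc1_on_ic50", "", pop.eff_vkorc1),
        ("eff_cyp4f2_on_ic50", "", pop.eff_cyp4f2),
        ("omega_ic50", "%", pop.omega_ic50 * 100),
        ("omega_kout", "%", pop.omega_kout * 100),
        ("sigma_npt", "ug/mL", pop.sigma_npt),
        ("inr_max", "", 5.0),
        ("lam", "", pop.theta_lam),
        ("eff_npt0_on_lam", "1/(ug/mL)", pop.eff_npt0),
        ("omega_lam", "%", pop.omega_lam * 100),
        ("sigma_inr", "%", pop.sigma_inr * 100),
    ]


def estimates_table(fits: dict[str, FitResult],
                    pop: PopulationTruth = DEFAULT_POPULATION) -> pd.DataFrame:
    """Recovered estimates next to the generating reference values."""
    pk, npt, inr = fits["pk"], fits["npt"], fits["inr"]
    est = {
        "cl": pk.theta["cl"],
        "eff_bsa_on_cl": pk.betas.get("cl:bsa", np.nan),
        "eff_cyp2c9_on_cl": (np.exp(pk.betas["cl:cyp2c9_star3"])
                             if "cl:cyp2c9_star3" in pk.betas else np.nan),
        "omega_cl": pk.omega["cl"] * 100,
        "sigma_cp": pk.sigma,
        "ic50": npt.theta["ic50"],
        "kout": npt.theta["kout"],
        "eff_vkorc1_on_ic50": (np.exp(npt.betas["ic50:vkorc1_star1"])
                               if "ic50:vkorc1_star1" in npt.betas else np.nan),
        "eff_cyp4f2_on_ic50": (np.exp(npt.betas["ic50:cyp4f2_star3_carrier"])
                               if "ic50:cyp4f2_star3_carrier" in npt.betas else np.nan),
        "omega_ic50": npt.omega["ic50"] * 100,
        "omega_kout": npt.omega["kout"] * 100,
        "sigma_npt": npt.sigma,
        "inr_max": 5.0,
        "lam": inr.theta["lam"],
        "eff_npt0_on_lam": inr.betas.get("lam:npt0", np.nan),
        "omega_lam": inr.omega["lam"] * 100,
        "sigma_inr": inr.sigma * 100,
    }
    rows = [dict(parameter=k, unit=u, estimate=est[k], reference=ref)
            for k, u, ref in _reference_rows(pop)]
    return pd.DataFrame(rows)


def fit_sequential(ds: Dataset, grid_dt: float = 0.5, n_starts: int = 1,
                   covariates: bool = True, agq_nodes_npt: int = 1,
                   agq_nodes_inr: int = 1, **fit_kw) -> dict[str, FitResult]:
    """The three sequential stage fits under the final covariate structure.

    The PD stages can refine the Laplace marginal with adaptive
    Gauss-Hermite quadrature (``agq_nodes_*`` > 1), which matters when the
    per-subject random-effect information is weak (IC50/Kout, lambda).
    """
    pk = fit_stage_pk(ds, model=pk_model(covariates=covariates),
                      n_starts=n_starts, **fit_kw)
    npt = fit_stage_npt(ds, pk, model=npt_model(covariates=covariates),
                        grid_dt=grid_dt, n_starts=n_starts,
                        agq_nodes=agq_nodes_npt, **fit_kw)
    inr = fit_stage_inr(ds, pk, npt, model=inr_model(covariates=covariates),
                        grid_dt=grid_dt, n_starts=n_starts,
                        agq_nodes=agq_nodes_inr, **fit_kw)
    return {"pk": pk, "npt": npt, "inr": inr}


def ebe_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Merged empirical-Bayes individual parameters across stages."""
    out = fits["pk"].ebe[["patient_id", "cl"]]
    out = out.merge(fits["npt"].ebe[["patient_id", "ic50", "kout"]],
                    on="patient_id", how="outer")
    out = out.merge(fits["inr"].ebe[["patient_id", "lam"]],
                    on="patient_id", how="outer")
    return out.sort_values("patient_id").reset_index(drop=True)


def cohort_statistics(ds: Dataset, fits: dict[str, FitResult]) -> dict:
    """INR>=4 analyses: EBE group comparison and stepwise logistic model."""
    flags = cohortstats.inr_ge4_flags(ds.observations)
    ebes = ebe_table(fits).set_index("patient_id")
    common = [pid for pid in ebes.index if pid in flags.index]
    ebes = ebes.loc[common]
    y = flags.loc[common].astype(int)
    complete = ebes.dropna()
    comparison = cohortstats.group_compare(complete,
                                           y.loc[complete.index].to_numpy())
    cov = ds.covariates.set_index("patient_id").loc[complete.index]
    features = pd.DataFrame({
        "cl": complete["cl"], "lam": complete["lam"],
        "log_alt": np.log(cov["alt"]),
        "age": cov["age"], "weight": cov["weight"], "bsa": cov["bsa"],
        "bmi": cov["bmi"], "ast": cov["ast"], "clcr": cov["clcr"],
        "sex_female": cov["sex_female"],
        "hepatic_disease": cov["hepatic_disease"], "ckd": cov["ckd"],
        "chf": cov["chf"], "hypertension": cov["hypertension"],
        "alcohol": cov["alcohol"], "smoking": cov["smoking"],
        "atrial_fibrillation": cov["atrial_fibrillation"],
        "stroke": cov["stroke"], "dvt": cov["dvt"],
    })
    logistic = cohortstats.stepwise_logistic(features,
                                             y.loc[complete.index].to_numpy())
    return {"flags": flags, "group_comparison": comparison, "logistic": logistic,
            "inr_ge4_rate": float(flags.mean())}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the report bundle (also on disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    logger.info("stage: simulate (n=%d, seed=%d)", config.n_patients, config.seed)
    spec = CohortSpec(n_patients=config.n_patients, protocol_mix=config.protocol_mix)
    ds = generate_cohort(spec=spec, seed=config.seed)
    write_dataset(ds, out / "data")

    logger.info("stage: sequential fits")
    fits = fit_sequential(ds, grid_dt=config.grid_dt, n_starts=config.n_starts)
    est = estimates_table(fits)
    est.to_csv(out / "estimates.csv", index=False)
    ebe_table(fits).to_csv(out / "ebe.csv", index=False)
    for name, fit in fits.items():
        fit.predictions.to_csv(out / f"predictions_{name}.csv", index=False)

    report: dict = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "ofv": {k: fits[k].ofv for k in fits},
        "converged": {k: fits[k].converged for k in fits},
        "estimates": {r["parameter"]: {"estimate": r["estimate"],
                                       "unit": r["unit"],
                                       "reference": r["reference"]}
                      for r in est.to_dict("records")},
    }

    if config.run_covsearch:
        logger.info("stage: covariate search")
        report["covsearch"] = {}
        searches = run_covariate_search(ds, config)
        for stage_name, sr in searches.items():
            sr.audit.to_csv(out / f"covsearch_{stage_name}.csv", index=False)
            report["covsearch"][stage_name] = sr.selected(
                {"pk": "cl", "npt": "ic50", "inr": "lam"}[stage_name])

    if config.run_bootstrap:
        logger.info("stage: bootstrap")
        report["bootstrap"] = {}
        for stage_name, n_rep in config.bootstrap_n.items():
            br = run_bootstrap_stage(ds, fits, stage_name, n_resamples=n_rep,
                                     seed=config.seed, grid_dt=config.grid_dt)
            br.summary.to_csv(out / f"bootstrap_{stage_name}.csv", index=False)
            report["bootstrap"][stage_name] = {
                r["parameter"]: [r["mean"], r["ci_lo"], r["ci_hi"]]
                for r in br.summary.to_dict("records")}

    logger.info("stage: cohort statistics")
    stats = cohort_statistics(ds, fits)
    stats["group_comparison"].to_csv(out / "group_comparison.csv", index=False)
    report["inr_ge4_rate"] = stats["inr_ge4_rate"]
    report["logistic"] = {
        "variables": stats["logistic"].variables,
        "coef": stats["logistic"].coef,
        "c_statistic": stats["logistic"].c_statistic,
        "sensitivity": stats["logistic"].sensitivity,
        "specificity": stats["logistic"].specificity,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=float))
    return report


def _stage_data(ds: Dataset, fits: dict[str, FitResult], stage: str,
                grid_dt: float = 0.5):
    from warfpop.estimation import INRStageData, npt_trajectories
    if stage == "pk":
        return PKStageData.from_dataset(ds)
    if stage == "npt":
        cl = cl_by_patient(ds, fits["pk"])
        return NPTStageData.from_dataset(ds, cl, grid_dt=grid_dt)
    if stage == "inr":
        traj = npt_trajectories(ds, fits["pk"], fits["npt"], grid_dt=grid_dt)
        return INRStageData.from_dataset(ds, traj)
    raise ValueError(f"unknown stage {stage!r}")


def run_bootstrap_stage(ds: Dataset, fits: dict[str, FitResult], stage: str,
                        n_resamples: int, seed: int = 0,
                        grid_dt: float = 0.5) -> boot.BootstrapResult:
    data = _stage_data(ds, fits, stage, grid_dt=grid_dt)
    return boot.bootstrap(data, fits[stage].model, fits[stage], n_resamples,
                          seed=seed)


def run_covariate_search(ds: Dataset, config: RunConfig,
                         stages=("pk", "npt", "inr")) -> dict:
    """Stage-wise stepwise search starting from covariate-free base models."""
    out = {}
    base_fits = fit_sequential(ds, grid_dt=config.grid_dt, covariates=False,
                               with_tables=True)
    targets = {"pk": "cl", "npt": "ic50", "inr": "lam"}
    models = {"pk": pk_model(covariates=False),
              "npt": npt_model(covariates=False),
              "inr": inr_model(covariates=False)}
    for stage in stages:
        data = _stage_data(ds, base_fits, stage, grid_dt=config.grid_dt)
        out[stage] = covsearch.stepwise_search(
            data, models[stage], target=targets[stage],
            forward_threshold=config.forward_dofv,
            backward_threshold=config.backward_dofv)
    return out
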