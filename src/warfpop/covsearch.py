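"""Stepwise covariate model building by objective-function value.

Forward inclusion adds, one at a time, the candidate whose inclusion drops
the OFV most, as long as the drop exceeds 3.84 (chi-squared, 1 df, P<0.05);
backward deletion then removes covariates whose deletion raises the OFV by
less than 6.63 (1 df, P<0.01).  Continuous candidates are tried in both a
power and an exponential form (centred at the cohort median) and the
better-fitting form competes; categorical candidates (and allele counts)
enter as multiplicative indicators.  Ties are broken by fixed candidate
order, so the procedure is deterministic given data and roster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from warfpop.estimation import (
    CovariateTerm,
    FitResult,
    LaplaceFitter,
    PopulationModel,
    StageData,
)

logger = logging.getLogger("warfpop")

FORWARD_DOFV = 3.84    # chi-squared(1) at P = 0.05
BACKWARD_DOFV = 6.63   # chi-squared(1) at P = 0.01

#: demographic/clinical candidates shared by every stage
CONTINUOUS_CANDIDATES = ("age", "weight", "bsa", "bmi", "ast", "alt", "clcr")
CATEGORICAL_CANDIDATES = ("sex_female", "hepatic_disease", "ckd", "chf",
                          "hypertension", "alcohol", "smoking")
#: per-stage additions: the stage's genotypes, and baseline NPT for lambda
STAGE_EXTRAS = {
    "cl": (("cyp2c9_star3", "categorical"),),
    "ic50": (("vkorc1_star1", "categorical"), ("cyp4f2_star3_carrier", "categorical")),
    "lam": (("npt0", "continuous"),),
}


@dataclass(frozen=True)
class CovariateCandidate:
    """One candidate effect: a covariate on a target structural parameter.

    ``forms`` optionally restricts which functional forms are tried for a
    continuous candidate (default: power and exponential both compete).
    """

    target: str                     # "cl" | "ic50" | "lam"
    covariate: str
    kind: str                       # "continuous" | "categorical"
    forms: tuple[str, ...] | None = None


def default_candidates(target: str,
                       continuous=CONTINUOUS_CANDIDATES,
                       categorical=CATEGORICAL_CANDIDATES,
                       include_stage_extras: bool = True,
                       ) -> list[CovariateCandidate]:
    """The candidate roster for one stage parameter."""
    cands = [CovariateCandidate(target, c, "continuous") for c in continuous]
    cands += [CovariateCandidate(target, c, "categorical") for c in categorical]
    if include_stage_extras:
        for cov, kind in STAGE_EXTRAS.get(target, ()):
            cands.append(CovariateCandidate(target, cov, kind))
    return cands


def _terms_for(cand: CovariateCandidate, data: StageData) -> list[CovariateTerm]:
    """Concrete term(s) to try for a candidate (both forms when continuous)."""
    if cand.kind == "categorical":
        return [CovariateTerm(cand.covariate, "categorical", init=0.0)]
    x = data.cov[cand.covariate].to_numpy(float)
    med = float(np.median(x))
    if not np.isfinite(med):
        raise ValueError(f"non-finite centering value for {cand.covariate!r}")
    terms = [CovariateTerm(cand.covariate, "exponential", center=med, init=0.0)]
    if med > 0 and np.all(x > 0):
        terms.insert(0, CovariateTerm(cand.covariate, "power", center=med, init=0.0))
    if cand.forms is not None:
        terms = [t for t in terms if t.form in cand.forms]
    return terms


def _with_term(model: PopulationModel, target: str, term: CovariateTerm,
               ) -> PopulationModel:
    params = []
    for p in model.params:
        if p.name == target:
            p = replace(p, terms=list(p.terms) + [term])
        params.append(p)
    return replace(model, params=params)


def _without_term(model: PopulationModel, target: str, covariate: str,
                  ) -> PopulationModel:
    params = []
    for p in model.params:
        if p.name == target:
            p = replace(p, terms=[t for t in p.terms if t.covariate != covariate])
        params.append(p)
    return replace(model, params=params)


def warm_x0(parent: FitResult, fitter: LaplaceFitter) -> np.ndarray:
    """Start a child fit from a parent's estimates (new terms start at init)."""
    parent_map = dict(zip(parent_labels(parent), parent.x))
    x0 = fitter.x0
    for i, lbl in enumerate(fitter._labels):
        if lbl in parent_map:
            x0[i] = parent_map[lbl]
    return x0


def parent_labels(fit: FitResult) -> list[str]:
    labels = []
    for p in fit.model.params:
        labels.append(f"log_{p.name}")
        labels += [f"beta_{p.name}:{t.covariate}" for t in p.terms]
    labels += [f"log_omega_{n}" for n in fit.model.random_effect_names()]
    if not fit.model.sigma_fixed:
        labels.append("log_sigma")
    return labels


def _fit_model(data: StageData, model: PopulationModel, parent: FitResult | None,
               **fit_kw) -> FitResult | None:
    try:
        fitter = LaplaceFitter(data, model)
        x0 = warm_x0(parent, fitter) if parent is not None else None
        return fitter.fit(x0=x0, with_tables=False, **fit_kw)
    except Exception as exc:                         # noqa: BLE001 - candidate skipped
        logger.warning("candidate fit failed (%s); skipped", exc)
        return None


def forward_include(data: StageData, base_model: PopulationModel,
                    candidates: list[CovariateCandidate],
                    base_fit: FitResult | None = None,
                    threshold: float = FORWARD_DOFV,
                    audit: list | None = None, **fit_kw):
    """Iterative forward inclusion; returns (model, fit, audit records)."""
    audit = audit if audit is not None else []
    model = base_model
    fit = base_fit or LaplaceFitter(data, model).fit(with_tables=False, **fit_kw)
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            for term in _terms_for(cand, data):
                trial_model = _with_term(model, cand.target, term)
                trial = _fit_model(data, trial_model, fit, **fit_kw)
                if trial is None:
                    audit.append(dict(phase="forward", step=step,
                                      candidate=cand.covariate, form=term.form,
                                      delta_ofv=np.nan, decision="fit-failed"))
                    continue
                d = fit.ofv - trial.ofv
                audit.append(dict(phase="forward", step=step,
                                  candidate=cand.covariate, form=term.form,
                                  delta_ofv=d, decision="evaluated"))
                if best is None or d > best[0]:
                    best = (d, cand, term, trial_model, trial)
        if best is None or best[0] <= threshold:
            audit.append(dict(phase="forward", step=step, candidate=None,
                              form=None, delta_ofv=best[0] if best else np.nan,
                              decision="stop"))
            break
        d, cand, term, model, fit = best
        remaining = [c for c in remaining if c.covariate != cand.covariate]
        audit.append(dict(phase="forward", step=step, candidate=cand.covariate,
                          form=term.form, delta_ofv=d, decision="included"))
    return model, fit, audit


def backward_delete(data: StageData, full_model: PopulationModel,
                    full_fit: FitResult | None = None,
                    threshold: float = BACKWARD_DOFV,
                    protected: tuple[str, ...] = (),
                    audit: list | None = None, **fit_kw):
    """Iterative backward deletion; returns (model, fit, audit records)."""
    audit = audit if audit is not None else []
    model = full_model
    fit = full_fit or LaplaceFitter(data, model).fit(with_tables=False, **fit_kw)
    step = 0
    while True:
        step += 1
        removable = [(p.name, t) for p in model.params for t in p.terms
                     if t.covariate not in protected]
        if not removable:
            break
        worst = None
        for target, term in removable:
            trial_model = _without_term(model, target, term.covariate)
            trial = _fit_model(data, trial_model, fit, **fit_kw)
            if trial is None:
                audit.append(dict(phase="backward", step=step,
                                  candidate=term.covariate, form=term.form,
                                  delta_ofv=np.nan, decision="fit-failed"))
                continue
            rise = trial.ofv - fit.ofv
            audit.append(dict(phase="backward", step=step, candidate=term.covariate,
                              form=term.form, delta_ofv=rise, decision="evaluated"))
            if worst is None or rise < worst[0]:
                worst = (rise, target, term, trial_model, trial)
        if worst is None or worst[0] >= threshold:
            audit.append(dict(phase="backward", step=step, candidate=None,
                              form=None, delta_ofv=worst[0] if worst else np.nan,
                              decision="stop"))
            break
        rise, target, term, model, fit = worst
        audit.append(dict(phase="backward", step=step, candidate=term.covariate,
                          form=term.form, delta_ofv=rise, decision="deleted"))
    return model, fit, audit


@dataclass
class SearchResult:
    """Final covariate model with its fit and the inclusion/deletion log."""

    model: PopulationModel
    fit: FitResult
    audit: pd.DataFrame

    def selected(self, target: str) -> list[str]:
        return [t.covariate for t in self.model.param(target).terms]


def stepwise_search(data: StageData, base_model: PopulationModel,
                    candidates: list[CovariateCandidate] | None = None,
                    target: str | None = None,
                    forward_threshold: float = FORWARD_DOFV,
                    backward_threshold: float = BACKWARD_DOFV,
                    base_fit: FitResult | None = None,
                    **fit_kw) -> SearchResult:
    """Forward P<0.05 then backward P<0.01 stepwise covariate search."""
    if candidates is None:
        if target is None:
            target = base_model.params[0].name
        candidates = default_candidates(target)
    audit: list = []
    model, fit, audit = forward_include(data, base_model, candidates,
                                        base_fit=base_fit,
                                        threshold=forward_threshold,
                                        audit=audit, **fit_kw)
    model, fit, audit = backward_delete(data, model, fit, audit=audit,
                                        threshold=backward_threshold, **fit_kw)
    return SearchResult(model=model, fit=fit, audit=pd.DataFrame(audit))
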