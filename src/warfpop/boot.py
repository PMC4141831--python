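"""Nonparametric bootstrap and goodness-of-fit diagnostics.

The bootstrap resamples patients with replacement (cohort size preserved),
refits the stage model with the covariate structure held fixed, and reports
the mean and the 2.5th / 97.5th values of the ranked parameter estimates.
Refits start from the original point estimates.  Failed refits are recorded
and excluded; more than 20% failures aborts with diagnostics.

Diagnostics produce observed vs population/individual prediction tables
(with identity-line regression slopes) and a visual predictive check that
compares observed percentiles with simulation-based prediction bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from warfpop.estimation import FitResult, LaplaceFitter, PopulationModel, StageData

logger = logging.getLogger("warfpop")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def rank_percentile(values: np.ndarray, pct: float) -> float:
    """The ceil(p*n)-th value of the ranked sample (rank-order definition)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    r = int(np.ceil(pct / 100.0 * v.size))
    return float(v[min(max(r, 1), v.size) - 1])


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary plus bookkeeping."""

    summary: pd.DataFrame            # parameter, point, mean, ci_lo, ci_hi
    estimates: pd.DataFrame          # one row per successful replicate
    n_resamples: int
    n_failed: int

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_resamples if self.n_resamples else 0.0


class BootstrapError(RuntimeError):
    pass


def _natural_estimates(fit: FitResult) -> dict[str, float]:
    out = dict(fit.theta)
    for key, b in fit.betas.items():
        param, cov = key.split(":")
        term = next(t for t in fit.model.param(param).terms if t.covariate == cov)
        if term.form == "categorical":
            out[f"eff_{cov}"] = float(np.exp(b))
        else:
            out[f"beta_{cov}"] = float(b)
    for name, om in fit.omega.items():
        out[f"omega_{name}"] = float(om)
    out["sigma"] = fit.sigma
    return out


def bootstrap(data: StageData, model: PopulationModel, point_fit: FitResult,
              n_resamples: int = 1000, seed: int = 0,
              max_failure_rate: float = 0.2, **fit_kw) -> BootstrapResult:
    """Patient-resampling bootstrap of one fitted stage."""
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    for b in range(n_resamples):
        idx = rng.integers(0, data.n, size=data.n)
        sub = data.take(idx)
        try:
            fitter = LaplaceFitter(sub, model)
            fit = fitter.fit(x0=point_fit.x, with_tables=False, **fit_kw)
            if not np.isfinite(fit.ofv):
                raise RuntimeError("non-finite OFV")
            rows.append(_natural_estimates(fit))
        except Exception as exc:                     # noqa: BLE001 - recorded
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            if n_failed > max_failure_rate * n_resamples:
                raise BootstrapError(
                    f"{n_failed}/{b + 1} bootstrap refits failed "
                    f"(> {max_failure_rate:.0%} of planned replicates)") from exc
    est = pd.DataFrame(rows)
    point = _natural_estimates(point_fit)
    summary = pd.DataFrame([
        dict(parameter=name, point=point.get(name, np.nan),
             mean=float(est[name].mean()),
             ci_lo=rank_percentile(est[name].to_numpy(), 2.5),
             ci_hi=rank_percentile(est[name].to_numpy(), 97.5))
        for name in est.columns])
    return BootstrapResult(summary=summary, estimates=est,
                           n_resamples=n_resamples, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Diagnostics (observed vs predicted, weighted residuals)
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsResult:
    table: pd.DataFrame
    slope_pop: float                 # obs ~ population prediction
    slope_ind: float                 # obs ~ individual prediction
    wres_trend: float                # wres ~ population prediction slope
    iwres_trend: float               # iwres ~ individual prediction slope


def diagnostics(fit: FitResult, plot_dir=None) -> DiagnosticsResult:
    """Observed/predicted/residual tables and identity-line slopes.

    ``wres_trend`` (population residuals) can drift on strongly nonlinear
    models even when well specified — an artifact of the first-order
    variance linearisation; ``iwres_trend`` (individual residuals) is the
    cleaner misspecification probe.
    """
    if fit.predictions is None:
        raise ValueError("fit carries no prediction table")
    t = fit.predictions
    slope_pop = float(sps.linregress(t["pred_pop"], t["obs"]).slope)
    slope_ind = float(sps.linregress(t["pred_ind"], t["obs"]).slope)
    wres_trend = float(sps.linregress(t["pred_pop"], t["wres"]).slope)
    iwres_trend = float(sps.linregress(t["pred_ind"], t["iwres"]).slope)
    if plot_dir is not None:
        _diagnostic_plots(fit, plot_dir)
    return DiagnosticsResult(table=t, slope_pop=slope_pop, slope_ind=slope_ind,
                             wres_trend=wres_trend, iwres_trend=iwres_trend)


def _diagnostic_plots(fit: FitResult, plot_dir) -> list:
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(plot_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = fit.predictions
    paths = []
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (xcol, ycol) in zip(axes, [("pred_pop", "obs"), ("pred_ind", "obs"),
                                       ("pred_pop", "wres")]):
        ax.scatter(t[xcol], t[ycol], s=8, alpha=0.5)
        if ycol == "obs":
            lim = [0, max(t[xcol].max(), t[ycol].max()) * 1.05]
            ax.plot(lim, lim, "k--", lw=1)
        else:
            ax.axhline(0, color="k", ls="--", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    fig.suptitle(f"stage {fit.stage}")
    p = out / f"diagnostics_{fit.stage}.png"
    fig.tight_layout()
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

def _simulate_stage(data: StageData, fitter: LaplaceFitter, x: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """One replicate of observations simulated under the fitted model."""
    log_tv, _, omega, sigma = fitter.unpack(x)
    params = {}
    for name in log_tv:
        lt = log_tv[name]
        if name in fitter.re_names:
            lt = lt + rng.normal(0.0, omega[name], size=data.n)
        params[name] = np.exp(lt)
    f = data.predict(params)
    if fitter.model.error_model == "relative":
        y = f * (1.0 + sigma * rng.standard_normal(f.shape))
    else:
        y = f + sigma * rng.standard_normal(f.shape)
    return y


def vpc(data: StageData, model: PopulationModel, fit: FitResult,
        n_sim: int = 200, seed: int = 0, n_bins: int = 8,
        percentiles=(5.0, 50.0, 95.0)) -> pd.DataFrame:
    """Visual predictive check: observed vs simulated time-binned percentiles.

    Returns one row per (time bin, percentile) with the observed percentile
    and the 5th-95th band of the same percentile across simulated replicates.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    fitter = LaplaceFitter(data, model)
    rng = np.random.default_rng(seed)
    mask = data.mask
    t = data.obs_t[mask]
    y = data.y[mask]
    edges = np.quantile(t, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    sims = np.stack([_simulate_stage(data, fitter, fit.x, rng)[mask]
                     for _ in range(n_sim)])
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not np.any(sel):
            continue
        mid = float(np.median(t[sel]))
        for p in percentiles:
            obs_p = float(np.percentile(y[sel], p))
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            rows.append(dict(bin=b, time_mid_h=mid, percentile=p, observed=obs_p,
                             sim_lo=float(np.percentile(sim_p, 5)),
                             sim_median=float(np.percentile(sim_p, 50)),
                             sim_hi=float(np.percentile(sim_p, 95))))
    return pd.DataFrame(rows)
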