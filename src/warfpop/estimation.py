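"""Nonlinear mixed-effects estimation of the three sequential PK-PD stages.

Each stage is a nonlinear mixed-effects model with log-normal
inter-individual variability and a normal residual error:

    y_ij = f_ij(phi_i) + eps_ij,   phi_i = tv_i(theta, covariates) * exp(eta_i)

with eta_i ~ N(0, Omega) (diagonal) and eps_ij ~ N(0, sigma^2) (additive)
or N(0, sigma^2 f_ij^2) (relative, with eta-interaction).  The marginal
likelihood integral over eta_i is approximated per subject by a Laplace
expansion about the conditional mode (the first-order-conditional family of
approximations), giving the objective function value

    OFV = -2 sum_i log integral p(y_i | eta) p(eta) d eta.

Stages:

* PK   — Cp(S) observations; random effect on CL(S); additive error.
* PD-1 — NPT observations; random effects on IC50 and Kout; additive error;
         individual Cp(S) profiles carried over from the PK stage.
* PD-2 — INR observations; random effect on lambda; relative error with
         interaction; individual NPT profiles carried over from PD-1.

Sequential conditioning passes empirical-Bayes (MAP) individual predictions
downstream by default; population predictions are available behind a flag
for sensitivity checks.

Covariate submodels are multiplicative on the typical value: a power form
(x/center)**beta or an exponential form exp(beta*(x - center)) for
continuous covariates, and exp(beta * indicator_or_count) for categorical
covariates and allele counts (reported as the multiplier exp(beta)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from warfpop.dataset import Dataset
from warfpop.structural import (
    BSA_REF,
    INR_MAX_FIXED,
    NPT0_REF,
    S_FRACTION,
    cp_superposition,
    npt_convolution,
)

logger = logging.getLogger("warfpop")

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class CovariateTerm:
    """One multiplicative covariate effect on a structural parameter."""

    covariate: str
    form: str                       # "power" | "exponential" | "categorical"
    center: float = 0.0
    init: float = 0.0               # initial beta (log-multiplier if categorical)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Per-subject regressor z such that the effect is exp(beta * z)."""
        if self.form == "power":
            return np.log(np.asarray(x, float) / self.center)
        if self.form == "exponential":
            return np.asarray(x, float) - self.center
        if self.form == "categorical":
            return np.asarray(x, float)
        raise ValueError(f"unknown covariate form {self.form!r}")


@dataclass
class ParamSpec:
    """One estimated structural parameter with its IIV and covariate terms."""

    name: str
    init: float
    omega_init: float = 0.3         # 0 -> random effect fixed to zero
    terms: list[CovariateTerm] = field(default_factory=list)


@dataclass
class PopulationModel:
    """Fixed-effect/covariate/variance specification for one stage."""

    stage: str                      # "pk" | "npt" | "inr"
    params: list[ParamSpec]
    sigma_init: float
    error_model: str = "additive"   # "additive" | "relative"
    sigma_fixed: bool = False

    def param(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def random_effect_names(self) -> list[str]:
        return [p.name for p in self.params if p.omega_init > 0]


def pk_model(covariates: bool = True, **inits) -> PopulationModel:
    """Stage-1 model for CL(S); final covariates CYP2C9*3 and BSA (power)."""
    terms = []
    if covariates:
        terms = [CovariateTerm("cyp2c9_star3", "categorical", init=np.log(0.6)),
                 CovariateTerm("bsa", "power", center=BSA_REF, init=1.0)]
    return PopulationModel(
        stage="pk",
        params=[ParamSpec("cl", inits.get("cl", 150.0),
                          inits.get("omega_cl", 0.3), terms)],
        sigma_init=inits.get("sigma", 0.1))


def npt_model(covariates: bool = True, **inits) -> PopulationModel:
    """Stage-2 model for IC50 and Kout; final covariates VKORC1*2, CYP4F2*3."""
    terms = []
    if covariates:
        terms = [CovariateTerm("vkorc1_star1", "categorical", init=np.log(1.5)),
                 CovariateTerm("cyp4f2_star3_carrier", "categorical", init=np.log(1.2))]
    return PopulationModel(
        stage="npt",
        params=[ParamSpec("ic50", inits.get("ic50", 0.1),
                          inits.get("omega_ic50", 0.3), terms),
                ParamSpec("kout", inits.get("kout", 0.02),
                          inits.get("omega_kout", 0.3))],
        sigma_init=inits.get("sigma", 15.0))


def inr_model(covariates: bool = True, **inits) -> PopulationModel:
    """Stage-3 model for lambda; final covariate baseline NPT (exponential)."""
    terms = []
    if covariates:
        terms = [CovariateTerm("npt0", "exponential", center=NPT0_REF, init=0.0)]
    return PopulationModel(
        stage="inr",
        params=[ParamSpec("lam", inits.get("lam", 2.5),
                          inits.get("omega_lam", 0.3), terms)],
        sigma_init=inits.get("sigma", 0.3),
        error_model="relative")


# ---------------------------------------------------------------------------
# Stage data (padded per-subject arrays)
# ---------------------------------------------------------------------------

def _pad(groups: list[np.ndarray], fill: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    n = len(groups)
    w = max((g.size for g in groups), default=0)
    out = np.full((n, max(w, 1)), fill)
    mask = np.zeros((n, max(w, 1)), dtype=bool)
    for i, g in enumerate(groups):
        out[i, :g.size] = g
        mask[i, :g.size] = True
    return out, mask


class StageData:
    """Packed observations + covariates for one stage.

    Subclasses implement ``predict`` mapping individual-parameter arrays
    (each of shape (n,)) to predictions at the observation slots (n, O).
    """

    param_names: tuple[str, ...] = ()
    _row_attrs: tuple[str, ...] = ("obs_t", "y", "mask")

    def __init__(self, ids, obs_t, y, mask, cov: pd.DataFrame):
        self.ids = list(ids)
        self.obs_t = obs_t
        self.y = y
        self.mask = mask
        self.cov = cov.reset_index(drop=True)
        self.n = len(self.ids)
        self.n_obs = int(mask.sum())

    def regressor(self, term: CovariateTerm) -> np.ndarray:
        if term.covariate not in self.cov.columns:
            raise KeyError(f"covariate {term.covariate!r} not in dataset")
        return term.encode(self.cov[term.covariate].to_numpy(float))

    def predict(self, params: dict[str, np.ndarray]) -> np.ndarray:
        raise NotImplementedError

    def take(self, rows) -> "StageData":
        """Row-resampled copy (patients renumbered); used by the bootstrap."""
        import copy

        rows = np.asarray(rows, dtype=int)
        new = copy.copy(self)
        for a in self._row_attrs:
            setattr(new, a, getattr(self, a)[rows])
        new.cov = self.cov.iloc[rows].reset_index(drop=True)
        new.ids = list(range(1, rows.size + 1))
        new.n = rows.size
        new.n_obs = int(new.mask.sum())
        return new


class PKStageData(StageData):
    """Dose events + Cp(S) observations; predicts via analytic superposition."""

    param_names = ("cl",)
    _row_attrs = StageData._row_attrs + ("dose_t", "sdose")

    def __init__(self, ids, obs_t, y, mask, cov, dose_t, sdose):
        super().__init__(ids, obs_t, y, mask, cov)
        self.dose_t = dose_t
        self.sdose = sdose

    @classmethod
    def from_dataset(cls, ds: Dataset, s_fraction: float = S_FRACTION) -> "PKStageData":
        cp = ds.obs("CP")
        ids = sorted(set(cp["patient_id"]))
        if not ids:
            raise ValueError("no Cp(S) observations in dataset")
        cov = ds.covariates.set_index("patient_id").loc[ids].reset_index()
        og = {pid: g for pid, g in cp.groupby("patient_id")}
        dg = {pid: g for pid, g in ds.dosing.groupby("patient_id")}
        obs_t, mask = _pad([og[pid]["time_h"].to_numpy(float) for pid in ids])
        yv, _ = _pad([og[pid]["value"].to_numpy(float) for pid in ids])
        dose_t, dmask = _pad([dg[pid]["time_h"].to_numpy(float)
                              if pid in dg else np.empty(0) for pid in ids], fill=1e12)
        sdose, _ = _pad([s_fraction * dg[pid]["dose_mg"].to_numpy(float)
                         if pid in dg else np.empty(0) for pid in ids])
        return cls(ids, obs_t, yv, mask, cov, dose_t, sdose)

    def predict(self, params):
        return cp_superposition(self.obs_t, self.dose_t, self.sdose, params["cl"])


class NPTStageData(StageData):
    """NPT observations with per-subject Cp(S) profiles on a shared grid."""

    param_names = ("ic50", "kout")
    _row_attrs = StageData._row_attrs + ("cp_grid", "npt0", "idx", "w")

    def __init__(self, ids, obs_t, y, mask, cov, grid, cp_grid, npt0):
        super().__init__(ids, obs_t, y, mask, cov)
        self.grid = grid
        self.cp_grid = cp_grid
        self.npt0 = npt0
        dt = grid[1] - grid[0]
        j = np.clip((obs_t / dt).astype(int), 0, grid.size - 2)
        self.idx = j
        self.w = np.clip(obs_t / dt - j, 0.0, 1.0)

    @classmethod
    def from_dataset(cls, ds: Dataset, cl_by_id: dict[int, float],
                     grid_dt: float = 0.5,
                     s_fraction: float = S_FRACTION) -> "NPTStageData":
        npt = ds.obs("NPT").copy()
        npt["time_h"] = npt["time_h"].clip(lower=0.0)
        eligible = set(ds.pd_patient_ids())
        ids = sorted(set(npt["patient_id"]) & eligible)
        if not ids:
            raise ValueError("no usable NPT observations in dataset")
        cov = ds.covariates.set_index("patient_id").loc[ids].reset_index()
        og = {pid: g for pid, g in npt.groupby("patient_id")}
        dg = {pid: g for pid, g in ds.dosing.groupby("patient_id")}
        obs_t, mask = _pad([og[pid]["time_h"].to_numpy(float) for pid in ids])
        yv, _ = _pad([og[pid]["value"].to_numpy(float) for pid in ids])
        t_end = float(obs_t.max()) + grid_dt
        grid = np.arange(0.0, t_end + grid_dt, grid_dt)
        cl = np.array([cl_by_id[pid] for pid in ids])
        cp_grid = np.empty((len(ids), grid.size))
        for lo in range(0, len(ids), 8):                     # chunked: memory
            hi = min(lo + 8, len(ids))
            dose_t, _ = _pad([dg[pid]["time_h"].to_numpy(float)
                              if pid in dg else np.empty(0)
                              for pid in ids[lo:hi]], fill=1e12)
            sdose, _ = _pad([s_fraction * dg[pid]["dose_mg"].to_numpy(float)
                             if pid in dg else np.empty(0) for pid in ids[lo:hi]])
            cp_grid[lo:hi] = cp_superposition(
                np.broadcast_to(grid, (hi - lo, grid.size)), dose_t, sdose, cl[lo:hi])
        npt0 = cov["npt0"].to_numpy(float)
        return cls(ids, obs_t, yv, mask, cov, grid, cp_grid, npt0)

    def predict(self, params):
        npt = npt_convolution(self.cp_grid, self.grid, params["kout"],
                              params["ic50"], self.npt0)
        lo = np.take_along_axis(npt, self.idx, axis=1)
        hi = np.take_along_axis(npt, self.idx + 1, axis=1)
        return lo * (1.0 - self.w) + hi * self.w


class INRStageData(StageData):
    """INR observations with fractional NPT inhibition carried from PD-1."""

    param_names = ("lam",)
    _row_attrs = StageData._row_attrs + ("frac", "base")

    def __init__(self, ids, obs_t, y, mask, cov, frac, base):
        super().__init__(ids, obs_t, y, mask, cov)
        self.frac = frac            # (n, O) fractional inhibition at obs times
        self.base = base            # (n,) baseline INR
        self.inr_max = INR_MAX_FIXED

    @classmethod
    def from_dataset(cls, ds: Dataset, npt_traj: dict[int, tuple[np.ndarray, np.ndarray]],
                     ) -> "INRStageData":
        """``npt_traj``: patient_id -> (grid, NPT-on-grid) from the PD-1 stage."""
        inr = ds.obs("INR")
        post = inr[inr["time_h"] > 0]
        eligible = set(ds.pd_patient_ids()) & set(npt_traj)
        ids = sorted(set(post["patient_id"]) & eligible)
        if not ids:
            raise ValueError("no usable INR observations in dataset")
        cov = ds.covariates.set_index("patient_id").loc[ids].reset_index()
        og = {pid: g for pid, g in post.groupby("patient_id")}
        pre = inr[inr["time_h"] <= 0]
        pre_mean = pre.groupby("patient_id")["value"].mean()
        base = np.array([float(pre_mean.get(pid, cov.set_index("patient_id")
                                            .loc[pid, "inr_base"])) for pid in ids])
        obs_t, mask = _pad([og[pid]["time_h"].to_numpy(float) for pid in ids])
        yv, _ = _pad([og[pid]["value"].to_numpy(float) for pid in ids])
        npt0 = cov["npt0"].to_numpy(float)
        frac = np.zeros_like(obs_t)
        for i, pid in enumerate(ids):
            grid, npt = npt_traj[pid]
            vals = np.interp(obs_t[i], grid, npt)
            frac[i] = np.clip((npt0[i] - vals) / npt0[i], 0.0, 1.0)
        frac[~mask] = 0.0
        return cls(ids, obs_t, yv, mask, cov, frac, base)

    def predict(self, params):
        return self.base[:, None] + self.inr_max * self.frac ** params["lam"][:, None]


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, OFV, empirical Bayes individuals and predictions."""

    stage: str
    model: PopulationModel
    theta: dict[str, float]          # natural-scale typical values
    betas: dict[str, float]          # '<param>:<covariate>' -> coefficient
    omega: dict[str, float]          # SD of log-scale random effect
    sigma: float
    ofv: float
    x: np.ndarray
    converged: bool
    message: str
    n_subjects: int
    n_obs: int
    ebe: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None
    se: dict[str, float] | None = None

    def multiplier(self, param: str, covariate: str) -> float:
        """Categorical effect reported as a multiplier exp(beta)."""
        return float(np.exp(self.betas[f"{param}:{covariate}"]))


class LaplaceFitter:
    """Laplace/FOCE-type marginal-likelihood machinery for one stage."""

    def __init__(self, data: StageData, model: PopulationModel,
                 agq_nodes: int = 1):
        if set(model.param(p).name for p in [pp.name for pp in model.params]) - set(
                data.param_names):
            raise ValueError("model parameters do not match stage data")
        self.data = data
        self.model = model
        self.re_names = model.random_effect_names()
        self.q = len(self.re_names)
        self.agq_nodes = int(agq_nodes)
        self._Z = {p.name: np.column_stack([data.regressor(t) for t in p.terms])
                   if p.terms else np.zeros((data.n, 0)) for p in model.params}
        self._eta_warm = np.zeros((data.n, self.q))
        self._labels, self._x0 = self._pack_init()

    # -- packing ------------------------------------------------------------

    def _pack_init(self):
        labels, x0 = [], []
        for p in self.model.params:
            labels.append(f"log_{p.name}")
            x0.append(np.log(p.init))
            for t in p.terms:
                labels.append(f"beta_{p.name}:{t.covariate}")
                x0.append(t.init)
        for name in self.re_names:
            labels.append(f"log_omega_{name}")
            x0.append(np.log(self.model.param(name).omega_init))
        if not self.model.sigma_fixed:
            labels.append("log_sigma")
            x0.append(np.log(self.model.sigma_init))
        return labels, np.array(x0)

    @property
    def x0(self) -> np.ndarray:
        return self._x0.copy()

    def unpack(self, x: np.ndarray):
        i = 0
        log_tv, betas = {}, {}
        for p in self.model.params:
            lt = np.full(self.data.n, x[i])
            i += 1
            for k, t in enumerate(p.terms):
                betas[f"{p.name}:{t.covariate}"] = x[i]
                lt = lt + x[i] * self._Z[p.name][:, k]
                i += 1
            log_tv[p.name] = lt
        omega = {}
        for name in self.re_names:
            omega[name] = np.exp(x[i])
            i += 1
        sigma = self.model.sigma_init if self.model.sigma_fixed else np.exp(x[i])
        return log_tv, betas, omega, sigma

    # -- likelihood ---------------------------------------------------------

    def _g_factory(self, log_tv, omega, sigma):
        """Vectorised per-subject -2 log joint (up to constants)."""
        y, mask = self.data.y, self.data.mask
        om2 = np.array([omega[n] ** 2 for n in self.re_names])
        relative = self.model.error_model == "relative"
        s2 = sigma ** 2

        def g(eta: np.ndarray) -> np.ndarray:
            params = {}
            for name in log_tv:
                lt = log_tv[name]
                if name in self.re_names:
                    lt = lt + eta[:, self.re_names.index(name)]
                params[name] = np.exp(lt)
            f = self.data.predict(params)
            if relative:
                v = s2 * np.maximum(f * f, 1e-12)
            else:
                v = np.broadcast_to(s2, f.shape)
            r2 = (y - f) ** 2
            gl = np.sum(np.where(mask, r2 / v + np.log(v), 0.0), axis=1)
            if self.q:
                gl = gl + np.sum(eta ** 2 / om2, axis=1)
            return gl

        return g

    def _inner(self, g, eta0: np.ndarray, tol: float = 1e-9, max_iter: int = 60):
        """Vectorised damped-Newton conditional-mode search.

        Returns (eta_hat, g(eta_hat), Hessian of g at eta_hat, shape (n,q,q)).
        """
        n, q = self.data.n, self.q
        if q == 0:
            e = np.zeros((n, 0))
            return e, g(e), np.zeros((n, 0, 0))
        eta = eta0.copy()
        h = 1e-4
        g0 = g(eta)
        hess = np.zeros((n, q, q))
        for _ in range(max_iter):
            grad = np.zeros((n, q))
            for k in range(q):
                ek = np.zeros(q)
                ek[k] = h
                gp = g(eta + ek)
                gm = g(eta - ek)
                grad[:, k] = (gp - gm) / (2 * h)
                hess[:, k, k] = (gp - 2 * g0 + gm) / h ** 2
            if q == 2:
                gpp = g(eta + [h, h])
                gpm = g(eta + [h, -h])
                gmp = g(eta + [-h, h])
                gmm = g(eta + [-h, -h])
                c = (gpp - gpm - gmp + gmm) / (4 * h * h)
                hess[:, 0, 1] = hess[:, 1, 0] = c
            # positive-definite safeguard
            if q == 1:
                hd = np.maximum(hess[:, 0, 0], 1e-4)
                step = -grad[:, 0] / hd
                step = step[:, None]
            else:
                a, b_, d = hess[:, 0, 0], hess[:, 0, 1], hess[:, 1, 1]
                a = np.maximum(a, 1e-4)
                d = np.maximum(d, 1e-4)
                det = a * d - b_ * b_
                bad = det < 1e-6 * a * d
                b_ = np.where(bad, 0.0, b_)
                det = a * d - b_ * b_
                step = np.stack([-(d * grad[:, 0] - b_ * grad[:, 1]) / det,
                                 -(a * grad[:, 1] - b_ * grad[:, 0]) / det], axis=1)
            norm = np.max(np.abs(step), axis=1)
            step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))[:, None]
            # backtracking acceptance
            scale = np.ones(n)
            for _bt in range(8):
                g1 = g(eta + scale[:, None] * step)
                worse = g1 > g0 + 1e-10
                if not np.any(worse):
                    break
                scale = np.where(worse, scale * 0.5, scale)
            eta = eta + scale[:, None] * step
            g0 = g(eta)
            if np.max(np.abs(scale[:, None] * step)) < tol:
                break
        return eta, g0, hess

    def ofv(self, x: np.ndarray) -> float:
        """-2 log approximate marginal likelihood at packed parameters x.

        The per-subject integral over eta uses the Laplace approximation
        about the conditional mode; with ``agq_nodes > 1`` it is refined by
        mode-centred adaptive Gauss-Hermite quadrature (tensor-product nodes
        for two random effects), which converges to the exact marginal as
        the node count grows.
        """
        log_tv, _, omega, sigma = self.unpack(x)
        g = self._g_factory(log_tv, omega, sigma)
        eta, gval, hess = self._inner(g, self._eta_warm)
        self._eta_warm = eta
        m = self.data.mask.sum(axis=1)
        total = gval + m * LOG2PI
        if self.q:
            om2 = np.array([omega[n] ** 2 for n in self.re_names])
            hess = self._pd_hessians(hess)
            if self.q == 1:
                logdet = np.log(hess[:, 0, 0])
            else:
                logdet = np.log(hess[:, 0, 0] * hess[:, 1, 1] - hess[:, 0, 1] ** 2)
            total = total + np.sum(np.log(om2)) + logdet - self.q * np.log(2.0)
            if self.agq_nodes > 1:
                total = total + self._agq_correction(g, eta, gval, hess)
        val = float(np.sum(total))
        if not np.isfinite(val):
            return 1e12
        return val

    def _pd_hessians(self, hess: np.ndarray) -> np.ndarray:
        """Clamp per-subject Hessians of g to positive definiteness."""
        h = hess.copy()
        if self.q == 1:
            h[:, 0, 0] = np.maximum(h[:, 0, 0], 1e-8)
        else:
            h[:, 0, 0] = np.maximum(h[:, 0, 0], 1e-8)
            h[:, 1, 1] = np.maximum(h[:, 1, 1], 1e-8)
            lim = 0.999 * np.sqrt(h[:, 0, 0] * h[:, 1, 1])
            h[:, 0, 1] = np.clip(h[:, 0, 1], -lim, lim)
            h[:, 1, 0] = h[:, 0, 1]
        return h

    def _agq_correction(self, g, eta_hat: np.ndarray, g_hat: np.ndarray,
                        hess: np.ndarray) -> np.ndarray:
        """Per-subject additive correction turning Laplace into adaptive
        Gauss-Hermite: -2 log of the weighted node sum relative to the
        single-node (Laplace) value."""
        z1, w1 = np.polynomial.hermite.hermgauss(self.agq_nodes)
        if self.q == 1:
            Z = z1[:, None]
            logw = np.log(w1)
        else:
            Z = np.array([[a, b] for a in z1 for b in z1])
            logw = np.add.outer(np.log(w1), np.log(w1)).ravel()
        # A = hess/2 is the Hessian of -log joint; nodes eta = eta_hat
        # + sqrt(2) * A^{-1/2} z  via the (lower) Cholesky factor of A
        A = hess / 2.0
        if self.q == 1:
            invsqrt = 1.0 / np.sqrt(A[:, 0, 0])          # (n,)
            offsets = np.sqrt(2.0) * invsqrt[:, None, None] * Z[None, :, :]
        else:
            l11 = np.sqrt(A[:, 0, 0])
            l21 = A[:, 0, 1] / l11
            l22 = np.sqrt(np.maximum(A[:, 1, 1] - l21 ** 2, 1e-12))
            # solve L^T u = z  (upper-triangular backsolve, explicit 2x2)
            u2 = Z[None, :, 1] / l22[:, None]
            u1 = (Z[None, :, 0] - l21[:, None] * u2) / l11[:, None]
            offsets = np.sqrt(2.0) * np.stack([u1, u2], axis=-1)
        vals = np.empty((self.data.n, Z.shape[0]))
        for k in range(Z.shape[0]):
            vals[:, k] = g(eta_hat + offsets[:, k, :])
        # log sum_k w_k exp(|z_k|^2 - (g_k - g_hat)/2), stabilised by the mode
        expo = (logw[None, :] + np.sum(Z ** 2, axis=1)[None, :]
                - 0.5 * (vals - g_hat[:, None]))
        mx = expo.max(axis=1)
        lse = mx + np.log(np.sum(np.exp(expo - mx[:, None]), axis=1))
        # one-node reference: log(pi^{q/2}) = (q/2) log pi
        return -2.0 * (lse - 0.5 * self.q * np.log(np.pi))

    def ofv_at(self, theta: dict[str, float], omega: dict[str, float],
               sigma: float, betas: dict[str, float] | None = None) -> float:
        """OFV at explicitly given natural-scale parameters."""
        betas = betas or {}
        x = []
        for p in self.model.params:
            x.append(np.log(theta[p.name]))
            for t in p.terms:
                x.append(betas.get(f"{p.name}:{t.covariate}", t.init))
        for name in self.re_names:
            x.append(np.log(omega[name]))
        if not self.model.sigma_fixed:
            x.append(np.log(sigma))
        return self.ofv(np.array(x))

    # -- fitting ------------------------------------------------------------

    def fit(self, x0: np.ndarray | None = None, n_starts: int = 1, seed: int = 0,
            maxiter: int = 300, ftol: float = 1e-9, with_se: bool = False,
            with_tables: bool = True) -> FitResult:
        """Maximise the Laplace marginal likelihood (multistart quasi-Newton)."""
        best = None
        rng = np.random.default_rng(seed)
        base_x0 = self._x0 if x0 is None else np.asarray(x0, float)
        for s in range(max(1, n_starts)):
            start = base_x0 if s == 0 else base_x0 + rng.normal(0, 0.3, base_x0.size)
            self._eta_warm = np.zeros((self.data.n, self.q))
            res = optimize.minimize(self.ofv, start, method="L-BFGS-B",
                                    options=dict(maxiter=maxiter, ftol=ftol,
                                                 gtol=1e-6, eps=1e-5))
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        log_tv, betas, omega, sigma = self.unpack(x)
        theta = {p.name: float(np.exp(x[self._labels.index(f"log_{p.name}")]))
                 for p in self.model.params}
        result = FitResult(
            stage=self.model.stage, model=self.model, theta=theta, betas=betas,
            omega={k: float(v) for k, v in omega.items()}, sigma=float(sigma),
            ofv=float(best.fun), x=x, converged=bool(best.success),
            message=str(best.message), n_subjects=self.data.n,
            n_obs=self.data.n_obs)
        if not best.success:
            logger.warning("stage %s fit did not report convergence: %s",
                           self.model.stage, best.message)
        if with_tables:
            result.ebe = self._ebe_table(x)
            result.predictions = self._prediction_table(x, result.ebe)
        if with_se:
            result.se = self._standard_errors(x)
        return result

    # -- post-fit -----------------------------------------------------------

    def ebes(self, x: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Conditional modes and individual parameters at packed x."""
        log_tv, _, omega, sigma = self.unpack(x)
        g = self._g_factory(log_tv, omega, sigma)
        eta, _, _ = self._inner(g, np.zeros((self.data.n, self.q)))
        params = {}
        for name in log_tv:
            lt = log_tv[name]
            if name in self.re_names:
                lt = lt + eta[:, self.re_names.index(name)]
            params[name] = np.exp(lt)
        return eta, params

    def _ebe_table(self, x: np.ndarray) -> pd.DataFrame:
        eta, params = self.ebes(x)
        out = {"patient_id": self.data.ids}
        for k, name in enumerate(self.re_names):
            out[f"eta_{name}"] = eta[:, k]
        for name, vals in params.items():
            out[name] = vals
        return pd.DataFrame(out)

    def _prediction_table(self, x: np.ndarray, ebe: pd.DataFrame) -> pd.DataFrame:
        log_tv, _, omega, sigma = self.unpack(x)
        pop_params = {n: np.exp(log_tv[n]) for n in log_tv}
        f_pop = self.data.predict(pop_params)
        ind_params = {n: ebe[n].to_numpy() for n in log_tv}
        f_ind = self.data.predict(ind_params)
        relative = self.model.error_model == "relative"

        def resvar(f):
            return sigma ** 2 * f * f if relative else np.full_like(f, sigma ** 2)

        # FO-linearised total variance for population weighted residuals
        v_tot = resvar(f_pop).copy()
        h = 1e-4
        for k, name in enumerate(self.re_names):
            e = np.zeros((self.data.n, self.q))
            e[:, k] = h
            params_p = dict(pop_params)
            params_p[name] = pop_params[name] * np.exp(h)
            params_m = dict(pop_params)
            params_m[name] = pop_params[name] * np.exp(-h)
            dfde = (self.data.predict(params_p) - self.data.predict(params_m)) / (2 * h)
            v_tot += dfde ** 2 * omega[name] ** 2
        mask = self.data.mask
        rows = []
        for i, pid in enumerate(self.data.ids):
            sel = mask[i]
            rows.append(pd.DataFrame({
                "patient_id": pid,
                "time_h": self.data.obs_t[i, sel],
                "obs": self.data.y[i, sel],
                "pred_pop": f_pop[i, sel],
                "pred_ind": f_ind[i, sel],
                "wres": ((self.data.y - f_pop) / np.sqrt(v_tot))[i, sel],
                "iwres": ((self.data.y - f_ind) / np.sqrt(resvar(f_ind)))[i, sel],
            }))
        return pd.concat(rows, ignore_index=True)

    def _standard_errors(self, x: np.ndarray) -> dict[str, float]:
        """Delta-method SEs from the numerical Hessian of OFV/2."""
        p = x.size
        h = 1e-4
        H = np.zeros((p, p))
        f0 = self.ofv(x)
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = h
            fp[i] = self.ofv(x + ei)
            fm[i] = self.ofv(x - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p)
                ei[i] = h
                ej = np.zeros(p)
                ej[j] = h
                fpp = self.ofv(x + ei + ej)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h ** 2
        try:
            cov = 2.0 * np.linalg.inv(H)
            se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_t = np.full(p, np.nan)
        out = {}
        for lbl, xi, s in zip(self._labels, x, se_t):
            if lbl.startswith(("log_",)):
                out[lbl.removeprefix("log_")] = float(np.exp(xi) * s)  # delta method
            else:
                out[lbl.removeprefix("beta_")] = float(s)
        return out


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def fit_stage_pk(ds: Dataset, model: PopulationModel | None = None,
                 agq_nodes: int = 1, **fit_kw) -> FitResult:
    """Stage 1: dose -> Cp(S); estimates CL(S) and its covariates."""
    model = model or pk_model()
    data = PKStageData.from_dataset(ds)
    return LaplaceFitter(data, model, agq_nodes=agq_nodes).fit(**fit_kw)


def cl_by_patient(ds: Dataset, pk_result: FitResult, use_ebe: bool = True) -> dict[int, float]:
    """Individual CL(S) carried into the PD-1 stage (EBE by default)."""
    out = {}
    if use_ebe and pk_result.ebe is not None:
        out = dict(zip(pk_result.ebe["patient_id"], pk_result.ebe["cl"]))
    # population prediction for anyone not in the PK fit
    mdl = pk_result.model.param("cl")
    cov = ds.covariates.set_index("patient_id")
    for pid in ds.patient_ids:
        if pid not in out:
            lt = np.log(pk_result.theta["cl"])
            for t in mdl.terms:
                z = t.encode(np.array([cov.loc[pid, t.covariate]]))[0]
                lt += pk_result.betas[f"cl:{t.covariate}"] * z
            out[pid] = float(np.exp(lt))
    return out


def fit_stage_npt(ds: Dataset, pk_result: FitResult,
                  model: PopulationModel | None = None, use_ebe: bool = True,
                  grid_dt: float = 0.5, agq_nodes: int = 1, **fit_kw) -> FitResult:
    """Stage 2: Cp(S) -> NPT; estimates IC50 (+covariates), Kout.

    Patients with missing baseline NPT are excluded, mirroring the study's
    exclusion rule.
    """
    model = model or npt_model()
    cl = cl_by_patient(ds, pk_result, use_ebe=use_ebe)
    data = NPTStageData.from_dataset(ds, cl, grid_dt=grid_dt)
    return LaplaceFitter(data, model, agq_nodes=agq_nodes).fit(**fit_kw)


def npt_trajectories(ds: Dataset, pk_result: FitResult, npt_result: FitResult,
                     use_ebe: bool = True, grid_dt: float = 0.5,
                     ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-patient NPT(t) on a grid from the PD-1 individual estimates."""
    cl = cl_by_patient(ds, pk_result, use_ebe=use_ebe)
    data = NPTStageData.from_dataset(ds, cl, grid_dt=grid_dt)
    inr_t = ds.obs("INR")["time_h"]
    t_end = max(float(inr_t.max()) if len(inr_t) else 0.0, float(data.grid[-1]))
    grid = np.arange(0.0, t_end + grid_dt, grid_dt)
    if grid.size > data.grid.size:
        # recompute Cp on the longer grid
        data = NPTStageData.from_dataset(ds, cl, grid_dt=grid_dt)
        pad = np.zeros((data.cp_grid.shape[0], grid.size - data.grid.size))
        # extend Cp by direct evaluation rather than zero-padding
        dg = {pid: g for pid, g in ds.dosing.groupby("patient_id")}
        extra_t = grid[data.grid.size:]
        for i, pid in enumerate(data.ids):
            g = dg.get(pid)
            if g is None:
                continue
            pad[i] = cp_superposition(extra_t, g["time_h"].to_numpy(float),
                                      S_FRACTION * g["dose_mg"].to_numpy(float),
                                      np.asarray(cl[pid]))
        cp_grid = np.concatenate([data.cp_grid, pad], axis=1)
    else:
        cp_grid = data.cp_grid
        grid = data.grid
    if use_ebe and npt_result.ebe is not None:
        ebe = npt_result.ebe.set_index("patient_id")
        ic50 = np.array([float(ebe.loc[pid, "ic50"]) if pid in ebe.index else np.nan
                         for pid in data.ids])
        kout = np.array([float(ebe.loc[pid, "kout"]) if pid in ebe.index else np.nan
                         for pid in data.ids])
    else:
        ic50 = np.full(len(data.ids), np.nan)
        kout = np.full(len(data.ids), np.nan)
    # fall back to population typical values where EBEs are unavailable
    fitter = LaplaceFitter(data, npt_result.model)
    log_tv, _, _, _ = fitter.unpack(npt_result.x)
    ic50 = np.where(np.isnan(ic50), np.exp(log_tv["ic50"]), ic50)
    kout = np.where(np.isnan(kout), np.exp(log_tv["kout"]), kout)
    npt = npt_convolution(cp_grid, grid, kout, ic50, data.npt0)
    return {pid: (grid, npt[i]) for i, pid in enumerate(data.ids)}


def fit_stage_inr(ds: Dataset, pk_result: FitResult, npt_result: FitResult,
                  model: PopulationModel | None = None, use_ebe: bool = True,
                  grid_dt: float = 0.5, agq_nodes: int = 1, **fit_kw) -> FitResult:
    """Stage 3: NPT -> INR; estimates lambda (+ NPT0 covariate), relative error."""
    model = model or inr_model()
    traj = npt_trajectories(ds, pk_result, npt_result, use_ebe=use_ebe,
                            grid_dt=grid_dt)
    data = INRStageData.from_dataset(ds, traj)
    return LaplaceFitter(data, model, agq_nodes=agq_nodes).fit(**fit_kw)


def weighted_residuals(fit: FitResult) -> pd.DataFrame:
    """Per-observation population weighted residuals from a completed fit."""
    if fit.predictions is None:
        raise ValueError("fit was run without prediction tables")
    return fit.predictions[["patient_id", "time_h", "obs", "pred_pop", "wres"]]
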