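"""Structural PK-PD model chain for warfarin initiation.

The chain has three deterministic stages for a single individual:

1. Dose -> Cp(S): one-compartment model with first-order absorption and
   elimination, evaluated as the analytic superposition over dose events.
   Racemic warfarin is dosed; the S-enantiomer dose entering the model is
   ``s_fraction`` (default 0.5) of the racemic amount, with bioavailability
   F fixed at 1, Ka fixed at 2 /h and Vd fixed at 13.8 L.
2. Cp(S) -> NPT: indirect-response (turnover) model.  Synthesis of normal
   prothrombin (NPT) runs at Kin = Kout * NPT0 and is inhibited by an Emax
   term with Imax fixed at 1, so
   dNPT/dt = Kin * (1 - Cp/(IC50 + Cp)) - Kout * NPT,  NPT(0) = NPT0.
   Given Cp(t) this ODE is linear in NPT; it is evaluated with the exact
   variation-of-constants solution, using a quadrature that is exact for a
   piecewise-linear inhibition input on the evaluation grid.
3. NPT -> INR: static nonlinear transform of the fractional inhibition
   x = (NPT0 - NPT)/NPT0,
   INR = INR_base + INR_max * x**lambda,  INR_max fixed at 5.

Covariate submodels (the final population model):
   CL(S)  = theta_CL  * 0.543**CYP2C9*3 * (BSA/1.74)**2.14      [mL/h]
   IC50   = theta_IC50 * 2.07**VKORC1*2 * 1.30**CYP4F2*3        [ug/mL]
   lambda = theta_lam * exp(0.00588 * (NPT0 - 119))             [-]

Units: time h, dose mg, Cp and NPT ug/mL (== mg/L), CL mL/h (converted to
L/h internally), Vd L.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("warfpop")

# ---------------------------------------------------------------------------
# Fixed constants of the final model
# ---------------------------------------------------------------------------

KA_FIXED = 2.0        # absorption rate constant, 1/h
VD_FIXED = 13.8       # volume of distribution of S-warfarin, L
F_FIXED = 1.0         # oral bioavailability
IMAX_FIXED = 1.0      # maximum fractional inhibition of NPT synthesis
INR_MAX_FIXED = 5.0   # maximum INR increase above baseline
S_FRACTION = 0.5      # S-warfarin fraction of the racemic dose

BSA_REF = 1.74        # m^2, cohort median body surface area
NPT0_REF = 119.0      # ug/mL, cohort median baseline NPT


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeProfile:
    """Genotypes at the three loci driving warfarin dose requirements.

    ``cyp2c9_star3``: number of CYP2C9*3 alleles (0 or 1 in cohort-like
    data; *3/*3 is absent from the study population but the covariate model
    extrapolates multiplicatively).
    ``vkorc1_star1``: number of VKORC1 *1 (-1639G) alleles; the reference
    genotype for the IC50 submodel is the *2/*2 homozygote (0 copies).
    ``cyp4f2_star3_carrier``: 1 if carrying at least one CYP4F2*3 allele.
    """

    cyp2c9_star3: int = 0
    vkorc1_star1: int = 0
    cyp4f2_star3_carrier: int = 0

    def __post_init__(self) -> None:
        for name in ("cyp2c9_star3", "vkorc1_star1"):
            v = getattr(self, name)
            if v not in (0, 1, 2):
                raise ValueError(f"{name} must be an allele count in {{0,1,2}}, got {v}")
        if self.cyp4f2_star3_carrier not in (0, 1):
            raise ValueError("cyp4f2_star3_carrier must be 0 or 1")


@dataclass
class CovariateSet:
    """Per-patient covariates entering the submodels and the covariate search."""

    bsa: float                      # m^2
    npt0: float                     # ug/mL, baseline NPT (nan if missing)
    inr_base: float                 # baseline INR
    genotype: GenotypeProfile = field(default_factory=GenotypeProfile)
    age: float = 64.5               # yr
    weight: float = 68.4            # kg
    height: float = 163.6           # cm
    sex_female: int = 0
    alt: float = 27.2               # IU/L
    ast: float = 29.2               # IU/L
    clcr: float = 73.3              # mL/min
    diabetes: int = 0
    hypertension: int = 0
    hepatic_disease: int = 0
    ckd: int = 0
    chf: int = 0
    alcohol: int = 0
    smoking: int = 0
    atrial_fibrillation: int = 0
    stroke: int = 0
    dvt: int = 0

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError(f"BSA must be positive, got {self.bsa}")
        if not np.isnan(self.npt0) and self.npt0 <= 0:
            raise ValueError(f"baseline NPT must be positive, got {self.npt0}")
        if self.inr_base < 0.8:
            raise ValueError(f"baseline INR must be >= 0.8, got {self.inr_base}")


@dataclass
class StructuralParams:
    """Individual structural parameters of the three-stage chain."""

    cl_s: float                     # mL/h, apparent oral clearance of S-warfarin
    ic50: float                     # ug/mL
    kout: float                     # 1/h
    npt0: float                     # ug/mL
    lam: float                      # dimensionless exponent
    inr_base: float                 # dimensionless
    vd: float = VD_FIXED
    ka: float = KA_FIXED
    f_bio: float = F_FIXED
    imax: float = IMAX_FIXED
    inr_max: float = INR_MAX_FIXED
    s_fraction: float = S_FRACTION

    def __post_init__(self) -> None:
        for name in ("cl_s", "ic50", "kout", "npt0", "vd", "ka", "f_bio", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.inr_base < 0:
            raise ValueError("inr_base must be non-negative")


@dataclass(frozen=True)
class DoseRegimen:
    """Timed racemic warfarin dose events (time in h since first dose)."""

    times: np.ndarray               # h, strictly increasing, >= 0
    doses_mg: np.ndarray            # racemic mg, > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.doses_mg, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "doses_mg", d)
        if t.shape != d.shape:
            raise ValueError("times and doses_mg must have the same length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("dose times must be non-negative and strictly increasing")
        if np.any(d <= 0):
            raise ValueError("doses must be positive")

    @classmethod
    def daily(cls, daily_doses_mg: Sequence[float], clock_h: float = 8.0) -> "DoseRegimen":
        """One dose per day at a fixed clock time; day 1 dose is at t=0."""
        doses = np.asarray(daily_doses_mg, dtype=float)
        times = np.arange(doses.size) * 24.0
        keep = doses > 0
        return cls(times[keep], doses[keep])


# ---------------------------------------------------------------------------
# Covariate submodels (Table-style typical-value formulas)
# ---------------------------------------------------------------------------

def cl_from_covariates(theta_cl: float, eff_cyp2c9: float, eff_bsa: float,
                       cov: CovariateSet) -> float:
    """Typical CL(S) in mL/h: theta * eff_cyp2c9**n(*3) * (BSA/1.74)**eff_bsa."""
    if theta_cl <= 0 or eff_cyp2c9 <= 0:
        raise ValueError("theta_cl and eff_cyp2c9 must be positive")
    if cov.bsa <= 0:
        raise ValueError("BSA must be positive")
    return theta_cl * eff_cyp2c9 ** cov.genotype.cyp2c9_star3 * (cov.bsa / BSA_REF) ** eff_bsa


def ic50_from_covariates(theta_ic50: float, eff_vkorc1: float, eff_cyp4f2: float,
                         cov: CovariateSet) -> float:
    """Typical IC50 in ug/mL; reference is the VKORC1*2/*2, CYP4F2*1/*1 patient."""
    if min(theta_ic50, eff_vkorc1, eff_cyp4f2) <= 0:
        raise ValueError("IC50 submodel multipliers must be positive")
    g = cov.genotype
    return theta_ic50 * eff_vkorc1 ** g.vkorc1_star1 * eff_cyp4f2 ** g.cyp4f2_star3_carrier


def lambda_from_covariates(theta_lam: float, eff_npt0: float, cov: CovariateSet) -> float:
    """Typical exponent lambda: theta * exp(eff_npt0 * (NPT0 - 119))."""
    if cov.npt0 <= 0 or np.isnan(cov.npt0):
        raise ValueError("baseline NPT must be positive and present")
    return theta_lam * np.exp(eff_npt0 * (cov.npt0 - NPT0_REF))


def params_from_covariates(cov: CovariateSet,
                           theta_cl: float = 240.0, eff_cyp2c9: float = 0.543,
                           eff_bsa: float = 2.14,
                           theta_ic50: float = 0.0725, eff_vkorc1: float = 2.07,
                           eff_cyp4f2: float = 1.30,
                           kout: float = 0.0136,
                           theta_lam: float = 3.48, eff_npt0: float = 0.00588,
                           ) -> StructuralParams:
    """Typical-value StructuralParams for a patient under the final model."""
    return StructuralParams(
        cl_s=cl_from_covariates(theta_cl, eff_cyp2c9, eff_bsa, cov),
        ic50=ic50_from_covariates(theta_ic50, eff_vkorc1, eff_cyp4f2, cov),
        kout=kout,
        npt0=cov.npt0,
        lam=lambda_from_covariates(theta_lam, eff_npt0, cov),
        inr_base=cov.inr_base,
    )


# ---------------------------------------------------------------------------
# Stage 1: dose -> Cp(S)
# ---------------------------------------------------------------------------

def cp_superposition(times: np.ndarray, dose_times: np.ndarray, s_doses_mg: np.ndarray,
                     cl_ml_h: np.ndarray, vd: float = VD_FIXED, ka: float = KA_FIXED,
                     f_bio: float = F_FIXED) -> np.ndarray:
    """Vectorised one-compartment oral superposition.

    Broadcasts over leading axes: ``times`` (..., T), ``dose_times`` and
    ``s_doses_mg`` (..., D), ``cl_ml_h`` (...,).  Returns Cp in ug/mL with
    shape (..., T).  Padded dose slots may carry dose 0.
    """
    t = np.asarray(times, dtype=float)
    td = np.asarray(dose_times, dtype=float)
    ds = np.asarray(s_doses_mg, dtype=float)
    cl = np.asarray(cl_ml_h, dtype=float)
    ke = cl / 1000.0 / vd                                    # 1/h
    dt = t[..., :, None] - td[..., None, :]                  # (..., T, D)
    active = dt >= 0.0
    dtc = np.where(active, dt, 0.0)
    ke_ = ke[..., None, None]
    denom = ka - ke_
    regular = np.abs(denom) > 1e-9 * ka
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = ka / (vd * denom)
        prof = coef * (np.exp(-ke_ * dtc) - np.exp(-ka * dtc))
        limit = ka * dtc * np.exp(-ka * dtc) / vd
        unit = np.where(regular, prof, limit)
    out = np.sum(np.where(active, unit, 0.0) * (f_bio * ds[..., None, :]), axis=-1)
    return out


def cp_profile(regimen: DoseRegimen, p: StructuralParams, times: Sequence[float]) -> np.ndarray:
    """Cp(S) (ug/mL) at the requested times for one individual."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("observation times must be non-negative")
    return cp_superposition(t, regimen.times, p.s_fraction * regimen.doses_mg,
                            np.asarray(p.cl_s), vd=p.vd, ka=p.ka, f_bio=p.f_bio)


# ---------------------------------------------------------------------------
# Stage 2: Cp(S) -> NPT
# ---------------------------------------------------------------------------

def npt_convolution(cp_grid: np.ndarray, grid: np.ndarray, kout: np.ndarray,
                    ic50: np.ndarray, npt0: np.ndarray,
                    imax: float = IMAX_FIXED) -> np.ndarray:
    """Exact linear-ODE solution of the turnover model on a shared time grid.

    dNPT/dt = Kout*NPT0*(1 - Imax*Cp/(IC50+Cp)) - Kout*NPT, NPT(0)=NPT0,
    solved by variation of constants:
    NPT(t) = exp(-Kout t) * [NPT0 + integral_0^t exp(Kout s) u(s) ds],
    with the synthesis rate u(s) treated as piecewise linear between grid
    nodes, for which the weighted integral has a closed form.

    Shapes: ``grid`` (T,), ``cp_grid`` (..., T), scalars/arrays ``kout``,
    ``ic50``, ``npt0`` broadcast over the leading axes.  Returns (..., T).
    """
    s = np.asarray(grid, dtype=float)
    cp = np.asarray(cp_grid, dtype=float)
    k = np.asarray(kout, dtype=float)[..., None]
    c50 = np.asarray(ic50, dtype=float)[..., None]
    n0 = np.asarray(npt0, dtype=float)[..., None]
    if np.any(cp < 0):
        raise ValueError("Cp input to the turnover model must be non-negative")
    u = k * n0 * (1.0 - imax * cp / (c50 + cp))              # synthesis rate
    h = np.diff(s)                                           # (T-1,)
    kh = k * h                                               # (..., T-1)
    ekh = np.exp(kh)
    # integral over [s_j, s_{j+1}] of exp(k*(s - s_j)) * linear-in-s u(s):
    #   i0 = int exp(k tau) dtau,  i1 = int tau exp(k tau) dtau
    a = u[..., :-1]
    b = u[..., 1:]
    i0 = np.expm1(kh) / k
    i1 = (h * ekh - i0) / k
    tiny = kh < 1e-6                                         # series to dodge cancellation
    if np.any(tiny):
        i1 = np.where(tiny, h * h * (0.5 + kh / 3.0), i1)
    seg = a * i0 + (b - a) / h * i1                          # (..., T-1)
    # NPT(s_j) = exp(-k (s_j - s_m)) * (NPT(s_m) + sum_{i=m}^{j-1} exp(k (s_i - s_m)) seg_i)
    # evaluated block-wise (exponent reference reset per block) so the
    # cumulative sums stay within float64 range for any plausible Kout.
    shape = np.broadcast_shapes(cp.shape, kh.shape[:-1] + (s.size,))
    out = np.empty(shape)
    out[..., 0] = np.broadcast_to(n0[..., 0], shape[:-1])
    kmax = float(np.max(k)) if k.size else 0.0
    span = max(1, int(np.ceil(200.0 / max(kmax * float(np.max(h, initial=1.0)), 1e-12))))
    start = 0
    npt_start = out[..., 0]
    while start < s.size - 1:
        stop = min(start + span, s.size - 1)                 # segment indices [start, stop)
        loc = s[start:stop + 1] - s[start]                   # node offsets within block
        grow = np.exp(k * loc[:-1])                          # exp(k (s_i - s_m))
        csum = np.cumsum(grow * seg[..., start:stop], axis=-1)
        vals = np.exp(-k * loc[1:]) * (npt_start[..., None] + csum)
        out[..., start + 1:stop + 1] = vals
        npt_start = vals[..., -1]
        start = stop
    return out


def npt_profile(cp_fn: Callable[[np.ndarray], np.ndarray], p: StructuralParams,
                times: Sequence[float], grid_dt: float = 0.25) -> np.ndarray:
    """NPT (ug/mL) at the requested times given a Cp(t) function.

    Integrates the turnover model from t=0 (NPT = NPT0) on an internal grid
    of spacing ``grid_dt`` hours and interpolates at ``times``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("observation times must be non-negative")
    t_end = float(t.max()) if t.size else 0.0
    grid = np.arange(0.0, t_end + grid_dt, grid_dt)
    cp = np.asarray(cp_fn(grid), dtype=float)
    npt = npt_convolution(cp, grid, p.kout, p.ic50, p.npt0, imax=p.imax)
    return np.interp(t, grid, npt)


# ---------------------------------------------------------------------------
# Stage 3: NPT -> INR
# ---------------------------------------------------------------------------

def inr_from_npt(npt: np.ndarray | float, p: StructuralParams) -> np.ndarray | float:
    """INR from NPT via the power transform of fractional NPT inhibition.

    Observed NPT can exceed baseline through assay noise; inhibition is then
    clamped to 0 (with a log message) so that lambda powers stay real.
    """
    npt_arr = np.asarray(npt, dtype=float)
    frac = (p.npt0 - npt_arr) / p.npt0
    if np.any(frac < -1e-9):
        logger.debug("NPT above baseline encountered; inhibition clamped to 0")
    frac = np.clip(frac, 0.0, 1.0)
    out = p.inr_base + p.inr_max * frac ** p.lam
    return out if np.ndim(npt) else float(out)


# ---------------------------------------------------------------------------
# Composed individual simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectories:
    """Hourly (or finer) simulated time courses for one individual."""

    grid: np.ndarray                # h
    cp: np.ndarray                  # ug/mL
    npt: np.ndarray                 # ug/mL
    inr: np.ndarray                 # dimensionless


def simulate_individual(p: StructuralParams, regimen: DoseRegimen,
                        grid: Sequence[float]) -> Trajectories:
    """Compose cp_profile -> npt_profile -> inr_from_npt on the given grid."""
    g = np.asarray(grid, dtype=float)
    if np.any(g < 0):
        raise ValueError("simulation grid must be non-negative")
    cp = cp_profile(regimen, p, g)
    npt = npt_convolution(cp, g, p.kout, p.ic50, p.npt0, imax=p.imax)
    inr = inr_from_npt(npt, p)
    return Trajectories(grid=g, cp=cp, npt=np.asarray(npt), inr=np.asarray(inr))
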