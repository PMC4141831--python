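"""Cohort-level statistics for the over-anticoagulation analysis.

Allele frequencies from genotype counts, 2x2 odds ratios with Woolf
confidence intervals, Mann-Whitney group comparisons, chi-squared/Fisher
tests, Pearson correlations, and stepwise logistic regression of the
INR >= 4 outcome (likelihood-ratio forward entry at P<0.05, backward
removal at P>=0.10) with a rank-based c-statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger("warfpop")


# ---------------------------------------------------------------------------
# Genotype counts and 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """Wild-type / heterozygote / homozygote counts at one locus."""

    wild: int
    hetero: int
    homo: int

    def __post_init__(self):
        if min(self.wild, self.hetero, self.homo) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.wild + self.hetero + self.homo


def minor_allele_freq(g: GenotypeCounts, count_complement: bool = False) -> float:
    """Frequency of the counted (variant) allele: (het + 2*homo) / (2n).

    ``count_complement`` returns the frequency of the other allele instead;
    use it when the table's orientation counts the major allele (e.g. the
    VKORC1 -1639A variant, which is the major allele in Asian cohorts).
    """
    if g.n == 0:
        raise ValueError("no genotyped patients")
    f = (g.hetero + 2 * g.homo) / (2.0 * g.n)
    return 1.0 - f if count_complement else f


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts: a,b = exposed case/noncase; c,d = unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def odds_ratio_2x2(t: TwoByTwo, alpha: float = 0.05) -> tuple[float, float, float]:
    """Odds ratio ad/(bc) with the Woolf (log-normal) confidence interval.

    Zero cells get the Haldane-Anscombe 0.5 correction (logged); an all-zero
    row or column margin is an error.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has an empty margin")
    if (arr == 0).any():
        logger.info("zero cell in 2x2 table; applying Haldane-Anscombe correction")
        arr = arr + 0.5
    a, b, c, d = arr.ravel()
    o = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return float(o), float(o * np.exp(-z * se)), float(o * np.exp(z * se))


def chi2_or_fisher(t: TwoByTwo) -> float:
    """Pearson chi-squared p (no continuity correction), or Fisher's exact
    two-sided p when any expected cell count is below 5."""
    arr = t.as_array()
    total = arr.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total
    if (expected < 5).any():
        return float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return float(sps.chi2_contingency(arr, correction=False)[1])


# ---------------------------------------------------------------------------
# Group comparisons and correlations
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p (exact enumeration for small
    tie-free samples, tie-corrected normal approximation otherwise)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment r with the t-distribution p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def c_statistic(scores, outcome) -> float:
    """Concordance (ROC area) of scores against a binary outcome, computed
    rank-based with half credit for ties."""
    s = np.asarray(scores, float)
    o = np.asarray(outcome)
    n1 = int(o.sum())
    n0 = o.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("outcome must contain both classes")
    ranks = sps.rankdata(s)
    u = ranks[o == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def group_compare(values: pd.DataFrame, outcome) -> pd.DataFrame:
    """Per-column medians with quartiles by outcome group and Mann-Whitney p.

    ``values``: one column per parameter (e.g. EBE CL(S), IC50, lambda);
    ``outcome``: aligned boolean/0-1 flag (e.g. INR >= 4 during induction).
    """
    o = np.asarray(outcome).astype(bool)
    if o.all() or (~o).all():
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for col in values.columns:
        v = values[col].to_numpy(float)
        g1, g0 = v[o], v[~o]
        _, p = mann_whitney(g1, g0)
        rows.append(dict(
            parameter=col,
            median_pos=float(np.median(g1)), q1_pos=float(np.percentile(g1, 25)),
            q3_pos=float(np.percentile(g1, 75)),
            median_neg=float(np.median(g0)), q1_neg=float(np.percentile(g0, 25)),
            q3_neg=float(np.percentile(g0, 75)),
            p_value=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stepwise logistic regression of INR >= 4
# ---------------------------------------------------------------------------

@dataclass
class LogisticModelResult:
    """Selected logistic model: coefficients, ORs, discrimination."""

    variables: list[str]
    coef: dict[str, float]                 # includes "const"
    odds_ratios: dict[str, tuple[float, float, float]]   # OR, lo, hi
    c_statistic: float
    sensitivity: float
    specificity: float
    separation_flag: bool
    screened_out: list[str]


def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with np.errstate(all="ignore"):
        return model.fit(disp=0, maxiter=200)


def stepwise_logistic(features: pd.DataFrame, outcome,
                      entry_p: float = 0.05, removal_p: float = 0.10,
                      screen_against: tuple[str, ...] = ("cl", "lam"),
                      screen_threshold: float = 0.7) -> LogisticModelResult:
    """Forward (LR P<entry) / backward (LR P>=removal) logistic selection.

    Before selection, candidates that are internally correlated with the
    PK-PD parameters named in ``screen_against`` (|r| above
    ``screen_threshold``) are dropped, mirroring the pre-screen against
    CL(S) and lambda.
    """
    y = np.asarray(outcome).astype(float)
    X = features.copy().astype(float)
    constant = [c for c in X.columns if X[c].std() == 0]
    if constant:
        logger.info("dropping constant candidate(s) %s", constant)
        X = X.drop(columns=constant)
    screened_out = []
    for ref in screen_against:
        if ref not in X.columns:
            continue
        for col in list(X.columns):
            if col == ref or col in screened_out or col in screen_against:
                continue
            r, _ = pearson_corr(X[col], X[ref])
            if abs(r) > screen_threshold:
                screened_out.append(col)
    X = X.drop(columns=screened_out)

    included: list[str] = []
    ll_cur = float(_logit_fit(X[[]], y).llf)
    changed = True
    while changed:
        changed = False
        # forward entry
        best = None
        for col in X.columns:
            if col in included:
                continue
            try:
                fit = _logit_fit(X[included + [col]], y)
            except Exception:                        # noqa: BLE001
                continue
            p = sps.chi2.sf(2 * (fit.llf - ll_cur), 1)
            if p < entry_p and (best is None or p < best[0]):
                best = (p, col, float(fit.llf))
        if best is not None:
            included.append(best[1])
            ll_cur = best[2]
            changed = True
        # backward removal
        while len(included) > 0:
            worst = None
            for col in included:
                rest = [c for c in included if c != col]
                ll_rest = float(_logit_fit(X[rest], y).llf)
                p = sps.chi2.sf(2 * (ll_cur - ll_rest), 1)
                if p >= removal_p and (worst is None or p > worst[0]):
                    worst = (p, col, ll_rest)
            if worst is None:
                break
            included.remove(worst[1])
            ll_cur = worst[2]
            changed = True

    final = _logit_fit(X[included], y)
    coefs = dict(final.params)
    ses = dict(final.bse)
    separation = bool(max((abs(v) for v in coefs.values()), default=0.0) > 20)
    if separation:
        logger.warning("possible complete separation in logistic model")
    ors = {}
    for name in included:
        b, s = coefs[name], ses[name]
        ors[name] = (float(np.exp(b)), float(np.exp(b - 1.96 * s)),
                     float(np.exp(b + 1.96 * s)))
    prob = np.asarray(final.predict(sm.add_constant(X[included], has_constant="add")))
    pred = prob >= 0.5
    pos = y == 1
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[~pos]).mean()) if (~pos).any() else np.nan
    return LogisticModelResult(
        variables=included, coef={k: float(v) for k, v in coefs.items()},
        odds_ratios=ors, c_statistic=c_statistic(prob, y) if included else 0.5,
        sensitivity=sens, specificity=spec, separation_flag=separation,
        screened_out=screened_out)


def inr_ge4_flags(observations: pd.DataFrame, threshold: float = 4.0) -> pd.Series:
    """Per-patient flag: any on-treatment INR observation >= threshold."""
    post = observations[(observations["obs_type"] == "INR")
                        & (observations["time_h"] > 0)]
    return post.groupby("patient_id")["value"].max() >= threshold
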