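# Methods

`warfpop` re-implements, as a tested pipeline, a sequential population
PK-PD analysis of warfarin initiation: daily racemic warfarin dosing drives
the plasma S-warfarin concentration Cp(S), which inhibits the synthesis of
fully carboxylated normal prothrombin (NPT), whose fractional depletion
maps nonlinearly onto the INR.  Because the original trial's patient-level
data are not public, a synthetic-cohort generator stands in for the study
population; every downstream stage (mixed-effects estimation, covariate
search, bootstrap, cohort statistics) is exercised against cohorts drawn
from the published final model.

## Structural model

**Stage 1 (PK).** One-compartment model with first-order absorption and
elimination, fixed `Ka = 2 /h`, `Vd = 13.8 L`, `F = 1`.  The S-enantiomer
dose is taken as half the racemic dose (the convention of the Hamberg-type
S-warfarin models; configurable `s_fraction`).  Cp(S) is evaluated as the
analytic superposition over dose events; `ke = CL(S)/Vd`.  The degenerate
case `Ka = ke` uses the analytic limit `D*Ka*t*exp(-Ka*t)/Vd`.

**Stage 2 (PD-1).** Indirect-response (turnover) model
`dNPT/dt = Kin*(1 - Imax*Cp/(IC50+Cp)) - Kout*NPT` with `Kin = Kout*NPT0`,
`Imax = 1`, `NPT(0) = NPT0`.  Given Cp(t) the equation is linear in NPT, so
the implementation evaluates the exact variation-of-constants solution with
a quadrature that is exact for piecewise-linear synthesis input on the
integration grid (an exponential integrator).  This is ~100x faster than a
generic adaptive solver inside the likelihood and converges at second order
in the grid spacing; `scipy.integrate.solve_ivp` serves as the independent
oracle in the test suite (agreement ~1e-4 relative at `dt = 0.25 h`,
with the expected O(dt^2) convergence).  Default grids: `dt = 0.25 h` for
simulation, `dt = 0.5 h` inside fits (discretisation error is two to three
orders of magnitude below the residual noise).

**Stage 3 (PD-2).** Static transform of fractional inhibition
`x = (NPT0 - NPT)/NPT0`, clamped to [0, 1]:
`INR = INR_base + INR_max * x**lambda` with `INR_max = 5` fixed, so INR is
bounded by `INR_base + 5` (the "maximum INR of 6" convention for a baseline
near 1 is implemented as this additive cap).

**Covariate submodels** (the final model):

    CL(S)  = theta_CL   * 0.543^CYP2C9*3 * (BSA/1.74)^2.14     [mL/h]
    IC50   = theta_IC50 * 2.07^VKORC1*2  * 1.30^CYP4F2*3       [ug/mL]
    lambda = theta_lam  * exp(0.00588 * (NPT0 - 119))          [-]

VKORC1 is coded as the count of *1 (-1639G) alleles with one multiplier per
allele; the reference is the *2/*2 homozygote (the common genotype in Asian
cohorts).  The rare *1/*1 genotype extrapolates multiplicatively (2.07^2),
as does CYP2C9*3/*3 (0.543^2) — neither occurs in a 99-patient cohort at
the configured allele frequencies except by chance.

## Synthetic cohort generator

The generator emulates the study conditions; its defaults are the study's
published values and are not tuning knobs.

* **Covariates.** Truncated-normal marginals with the published means/SDs
  (age 64.5±15.2 y, weight 68.4±12.4 kg, height 163.6±8.2 cm, CLcr
  73.3±36.6 mL/min, NPT0 118.2±22.1 ug/mL, baseline INR 1.05±0.10, AST
  29.2±16.3, ALT 27.2±17.5 IU/L), joined by a Gaussian copula carrying the
  three published correlations (age-weight -0.358, age-CLcr -0.568, and an
  age-height correlation of -0.17 calibrated so that the derived age-BSA
  correlation reproduces the published -0.397).  BSA comes from the Du Bois
  formula; BMI from weight/height.  Binary covariates are independent
  Bernoulli draws at the cohort prevalences.
* **Genotypes.** Per-locus Hardy-Weinberg draws at allele frequencies
  0.056 (CYP2C9*3), 0.904 (VKORC1 -1639A, i.e. *1 frequency 0.096), 0.278
  (CYP4F2*3).
* **Dosing.** 77.8% of patients follow a genotype-guided protocol, the rest
  a standard protocol.  Both give three loading days at 1.5x the predicted
  maintenance dose, then titrate by ±0.5 mg (−1 mg at INR ≥ 4) toward the
  2-3 INR target at visits on days 4, 7, 14, 28 and 56, with doses
  quantised to 0.5 mg.  The genotype-guided maintenance table
  `2.75 * 1.35^VKORC1*1 * 0.60^CYP2C9*3 mg/d` is a calibrated stand-in for
  the cited dosing algorithms; its calibration target is the published
  group mean starting doses (4.1 mg/d genotype-guided; standard protocol
  5.0 mg/d, i.e. a predicted maintenance of 5/1.5 mg/d).  The titration
  INR *measurements* are part of the emitted observation series — dose
  adaptation that reacts to unrecorded responses would otherwise make the
  dosing non-ignorable and visibly biases downstream estimates (this was
  confirmed empirically during development: leaving the titration INRs out
  of the dataset depressed the recovered Kout and lambda by 5-10%).
* **Sampling design.** Observations sit at scheduled visit days with ±6 h
  uniform jitter (titration draws are taken before the day's dose).  INR:
  5-6 pre-treatment readings plus the five titration visits plus 0-2 extra
  visits (≈11 points per patient, range 8-13, matching the published
  averages); Cp(S): 6-12 points (mean ≈9); NPT: a baseline sample at t=0
  plus 7-11 visit samples (mean ≈10).  3% of patients (deterministically
  round(0.03 n)) have their baseline-NPT covariate removed to exercise the
  PD-stage exclusion rule.
* **Random effects and noise.** Log-normal IIV with omega 39.9% (CL), 38.5%
  (IC50), 45.6% (Kout), 24.1% (lambda); additive residual noise 0.0697
  ug/mL (Cp) and 12.2 ug/mL (NPT), truncated at zero; 24.7% relative noise
  (on-treatment INR).  Pre-treatment INR readings get a small absolute SD
  (0.05): the large relative INR residual reflects on-treatment dynamics
  and would be unphysical for the near-constant baseline.  The baseline-NPT
  covariate is the true baseline (an idealisation; the baseline *sample* is
  still emitted with assay noise).
* **Seeding.** One master `SeedSequence`; per-patient child streams, so
  cohorts are reproducible and insensitive to generation order.

What the generator does **not** emulate: dropout, adherence lapses,
concomitant-medication effects on CL(S), assay LLOQ, R-warfarin, and any
real-data model misspecification.  Passing recovery tests therefore show
that the pipeline is a consistent estimator of its own generating model
under the study's design — not that the published model is correct.

## Estimation

Each stage is a nonlinear mixed-effects model fitted by maximising a
per-subject Laplace approximation to the marginal likelihood (the
first-order-conditional family; the INR stage's relative-error variance is
evaluated at the conditional mode, i.e. with interaction).  The
conditional modes are found by a vectorised damped Newton iteration across
all subjects simultaneously (finite-difference gradients/Hessians,
backtracking, positive-definite safeguards); the same Hessians feed the
Laplace determinant.  An optional mode-centred adaptive Gauss-Hermite
refinement (`agq_nodes`) converges to the exact marginal and is used for
the PD stages in the reference run (5 tensor nodes for IC50/Kout, 7 for
lambda), where per-subject information is weakest; it was validated against
an independently coded quadrature oracle to 1e-6.

Outer optimisation: L-BFGS-B on log-transformed thetas, omegas and sigma
(covariate coefficients untransformed), finite-difference gradients,
`ftol = 1e-9`, warm-started random-effect modes.  Multistart is available
(`n_starts`), default 1: with positivity enforced by the log transform the
stage likelihoods proved unimodal in every spot check, and single-start
determinism keeps the covariate search and bootstrap affordable.  Standard
errors, when requested, come from the numerical Hessian of the OFV with a
delta-method back-transform (the bootstrap provides the primary intervals,
mirroring the original analysis).

Sequential conditioning passes empirical-Bayes (MAP) individual parameters
downstream: individual CL(S) into the NPT stage (patients without a PK fit
fall back to their covariate-model typical value), individual NPT(t) into
the INR stage.  Population-prediction sequencing is available behind
`use_ebe=False` for sensitivity analysis.  Baseline INR per patient is the
mean of that patient's pre-treatment INR readings.  Patients with missing
baseline NPT are excluded from both PD stages.

Known behaviour at the study's design density, measured by simulation
during development (ten 99-patient replicates): CL(S) and IC50 recover
essentially unbiased (means 241.9 mL/h and 0.0727 ug/mL against generating
values 240 and 0.0725); Kout runs ~4% low (finite-sample
maximum-likelihood bias — NPT sampling starts on day 4, about 1.9 turnover
half-lives in, so the approach transient is thinly sampled) and lambda
~2% low (attenuation from carrying error-contaminated NPT trajectories
into stage 3; with true trajectories the bias vanishes).  All four
estimates still fall inside the published bootstrap 95% intervals for most
simulated cohorts (lambda in 8/10 replicates, the others 10/10).

A structural limit of stage-wise estimation under dose titration deserves
emphasis: doses adapt to measured INR, and INR responses carry information
about the PD random effects, so for the NPT stage — whose likelihood does
not include the INR data — the dose history is an informative covariate
correlated with eta.  The visible consequence is attenuation of
genotype-effect estimates on IC50 (the CYP4F2 multiplier recovers around
1.2 when generated at 1.30) and, with it, reduced stepwise-selection power
for that effect (~50% at the published effect size).  The original
analysis has the same structure, so its published multiplier is itself the
output of this feedback-attenuated estimator; simulating the published
value as the causal truth and re-estimating necessarily under-detects.
Emitting the titration INRs as observations (see the generator section)
removes the analogous problem for the INR stage, whose likelihood does see
them.  A joint (simultaneous) fit of all stages would remove it entirely
but is deliberately out of scope.

## Covariate search

Forward inclusion (ΔOFV > 3.84, chi-squared 1 df, P<0.05) then backward
deletion (ΔOFV < 6.63, P<0.01).  Continuous candidates are tried in both a
power and an exponential form centred at the cohort median, the better form
competing; each accepted term counts 1 df.  Ties break by fixed roster
order, making the procedure deterministic.  Candidate fits warm-start from
the current model's estimates; failures are logged and the candidate
skipped.  The full roster follows the published analysis plan (age, weight,
BSA, BMI, AST, ALT, CLcr; sex, liver disease, CKD, CHF, hypertension,
alcohol, smoking; the stage's genotypes; NPT0 for lambda).

## Bootstrap and diagnostics

Nonparametric bootstrap: patients resampled with replacement (cohort size
preserved), covariate structure held fixed, refits warm-started from the
point estimates; failed refits are excluded and reported, >20% failures
aborts.  Intervals are the 2.5th/97.5th values of the ranked estimates
(rank r = ceil(p*n)).  Reference replicate counts are 1,000 (Cp, INR) and
100 (NPT); the test suite runs ~200 on reduced cohorts for runtime.
Diagnostics: observed vs population/individual predictions with
identity-line slopes, FO-linearised population weighted residuals (whose
vs-prediction trend is reported but is an acknowledged linearisation
artifact on these nonlinear models; individual residuals are the clean
probe), and a visual predictive check with simulation-based percentile
bands.

## Cohort statistics

Allele frequencies from genotype counts ((het + 2 hom)/2n, with the
table's allele orientation); odds ratios ad/bc with Woolf CIs and
Haldane-Anscombe 0.5 correction for zero cells; Pearson chi-squared without
continuity correction, switching to Fisher's exact test when any expected
cell is below 5; Mann-Whitney U (exact for tie-free samples up to n=8 per
group, tie-corrected normal approximation otherwise); Pearson correlations
with t-based P values.  The INR ≥ 4 logistic model uses likelihood-ratio
forward entry (P<0.05) and backward removal (P≥0.10, the SPSS default, the
removal criterion not being stated in the source analysis), after a
pre-screen dropping candidates correlated above |r| = 0.7 with CL(S) or
lambda (the screen's threshold is configurable; the source names the screen
but not its rule).  Discrimination is the rank-based c-statistic (ties get
half credit) with sensitivity/specificity at a 0.5 probability cutoff.

## Desk-scale problem sizes

The reference run (`warfpop run --seed 1`, `scripts/acceptance.py`) uses
the full 99-patient cohort and the three sequential fits (~3-5 min on one
core).  The test suite scales stochastic checks down to keep the whole
suite within a coffee break: covariate-search recovery runs ten 99-patient
seeds against reduced candidate rosters (the stage's true covariates plus
decoy demographics — full-roster behaviour is covered once at unit level),
search fits use a 2 h PD grid and relaxed optimiser tolerances, the
false-inclusion simulation uses 50 candidate fits on null cohorts, and the
bootstrap self-consistency check uses 200 replicates.  Selection
thresholds, noise levels and acceptance bands are never scaled.

## Known limitations

* The inter-stage carry-over uses point (MAP) individual predictions;
  propagating their uncertainty (or fitting all stages simultaneously) is
  out of scope, and the resulting small attenuation of lambda is
  documented above.
* Diagonal Omega only; no inter-occasion variability; no LLOQ handling.
* The genotype-guided dose table is calibrated to the published group mean
  starting doses, not to any specific published dosing algorithm.
* The logistic INR≥4 analysis treats EBE-derived parameters as fixed
  regressors, as in the source analysis.
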