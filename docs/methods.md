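# Methods

This note documents the model, the estimator, the synthetic-trial
generator and the numerical choices in `tgikit`, including the places
where the design was genuinely open and what the package chose.

## Tumor dynamics model

SLD (sum of the longest diameters of the target lesions, in cm) follows

    dy_i/dt = r_i − E_dose,i(t) · y_i ,

a zero-order growth / first-order kill structure.  The dose takes values
in {0, 5, 10} mg/day — the only regimens that occur in the emulated trial
— and the dose-effect map is a lookup (model 1 ties E₅ ≡ E₁₀; model 2
separates them), not a continuous exposure-response curve.  Within a
constant-dose interval the solution is

    y(t) = r/E + (y_start − r/E)·exp(−E·Δt)     (E ≠ 0)
    y(t) = y_start + r·Δt                        (E = 0),

and trajectories under piecewise dosing chain these closed forms, so the
solution is exact and continuous at dose switches.  When |E| < 1e−12/day
the exponential form suffers catastrophic cancellation in (1−e^{−EΔt})/E,
so the linear branch is used; continuity across that switch is tested.
Negative individual parameters are allowed (additive normal random
effects on the natural scale, so E < 0 simply gives exponential growth);
no truncation is applied at the model level.

Individual parameters:

    r_i   = r   · (y₀,i/ŷ₀)^θ1 · Π(covariate multipliers) + η_r
    E10,i = E10 · (y₀,i/ŷ₀)^θ2 · Π(...)                   + η_E10
    E5,i  = E5  · (y₀,i/ŷ₀)^θ2 · Π(...)                   + η_E5

with θ2 shared by both drug effects and ŷ₀ = 14.4 cm (reference median
baseline).  Continuous covariates enter as (x/ref)^θ, binary ones as
θ^{0/1}.  Baseline y₀,i is fixed at the observed screening value, not
estimated.  Random effects default to a diagonal covariance; whether any
correlation among them should be retained is not settled by the source
analysis, so the diagonal is the default and the estimator is structured
around it.  Residual error is additive and homoscedastic, σ_ε in cm.

Reference parameter values used as simulation truth throughout (the
published final-model estimates of the motivating analysis): r = 46.0e−3
cm/day, E₁₀ = 3.9e−3/day, E₅ = 2.3e−3/day, θ1 = 0.4, θ2 = −0.7, ω_r =
3.5e−3, ω_E10 = 0.3e−3, ω_E5 = 0.2e−3, σ_ε = 1.1 cm.

## Estimation (FOCE / Laplace)

The marginal likelihood integrates the joint density over each patient's
η.  It is approximated by Laplace at the conditional mode; with additive
homoscedastic error the FOCE and FOCE-with-interaction objectives
coincide, and the curvature used in the log-determinant correction is the
linearized (Gauss-Newton) one, J'J/σ² + Ω⁻¹ — the convention of standard
first-order-conditional estimators.  The approximation is exact whenever
the model is linear in η; for placebo-only data the trajectory is linear
in η_r, and the test suite verifies agreement with the closed-form linear
mixed model to machine precision.

Numerical structure:

* Predictions are affine in the growth rate: y = y₀·A + r_i·B with A, B
  functions of the drug effects only.  η_r is therefore profiled in
  closed form, and the inner optimization runs over at most two
  drug-effect η dims per patient, as a damped Newton iteration vectorized
  across the cohort, with exact analytic gradients (dA/dE, dB/dE chained
  through the dose segments) and the always-positive-definite
  Gauss-Newton Hessian.  Inner convergence: max |grad| < 1e−7 in
  ω-standardized coordinates, 60 iterations cap, warm-started between
  outer iterations.
* Outer optimization: L-BFGS-B on scaled parameters; fixed effects on the
  natural (signed) scale, ω's and σ on the log scale (bounds
  log-value ∈ [−25, 5], which permits an effective collapse to zero
  variance while keeping the objective finite).  Convergence: relative
  OFV change below 1e−11, projected-gradient tolerance 1e−6.
* Standard errors come from the observed information matrix (central
  finite-difference Hessian of the OFV at the optimum; Cov = 2H⁻¹),
  delta-method-transformed to the natural scale; the fixed-effect block
  is exposed for simulation sampling.  A non-PD information matrix falls
  back to a pseudo-inverse and is flagged in the fit message.
* Initial values: a two-stage heuristic pools per-patient segment slopes
  (dose-0 slopes give r; (r − slope)/ȳ on-dose gives the effects) with
  medians; ω's start at 30% of their parameter, σ at 1 cm.  All
  overridable via `init=` and `fixed=`.
* Patients with no post-baseline assessment contribute no likelihood and
  are dropped with a logged count.  Missing covariate values are imputed
  at the reference (multiplier 1) with a logged warning.

η-shrinkage is 1 − SD(EBE)/ω̂ (sample SD, ddof = 1), reported per random
effect and undefined when ω̂ = 0.  The LRT between models 1 and 2 uses
df = 2 (one extra fixed effect, one extra variance component) against a
plain χ²; the added ω sits on the boundary of its parameter space, so the
plain reference is conservative for that component — noted in the CLI
report output.

## Covariate selection

Forward inclusion (largest significant ΔOFV at P < 0.05 enters, ties by
ΔOFV then name), backward exclusion (retention requires P < 0.001),
composed by `run_stepwise` with a replayable audit trail.  The extra
explanatory-power requirement — a kept covariate must reduce intersubject
variability — is operationalized as: the product of the tracked ω
estimates must fall by more than 0.1% relative.  The stepwise drivers
track the ω of the parameter group the candidate acts on (growth → ω_r,
effect → ω_E10) and apply the rule at inclusion time only.  Two facts
force these choices: the ω of the *other* group is weakly identified and
moves several percent between refits in either direction, and once a
genuine covariate is in the model, further likelihood gains flow through
the mean rather than the variance — so a strict "no ω may ever increase"
rule, or re-applying the rule at exclusion time, vetoes true covariates
on refit noise.  A proxy covariate (e.g. calcium correlated with baseline
SLD) still fails: it improves the likelihood but leaves its group's ω
essentially unchanged.  Candidates tested on the drug effect share one
exponent across E₁₀ and E₅, mirroring θ2; each covariate is a separate
candidate per parameter group; constant-valued candidates are rejected as
uninformative.

## Synthetic trial generator

The generator emulates the study design so that every estimator property
can be exercised without patient data: 416 patients randomized 2:1
(277 active at 10 mg, 139 placebo), assessments at screening and every 56
days, baseline SLD log-normal with median 14.4 cm and log-SD 0.5
(configurable — the source analysis prints only the median, making this
the main unidentifiable knob), additive σ = 1.1 cm residual error with
draws that would make SLD ≤ 0 resampled (rate recorded; essentially zero
at default settings), and 9/416 expected patients without an analyzable
baseline.  Progression is declared from the *noisy* series by the RECIST
rule (≥ 20% over the running nadir, baseline included) or by an exogenous
new-lesion/nontarget event with constant hazard 0.005/day — those event
types are outside the SLD model, so they enter as an independent process.
On placebo progression the patient crosses over to 10 mg with probability
0.799 (the RECIST reference resets on the new therapy, and the event
clock is redrawn); on-drug progression censors the patient.  Toxicity
reductions 10 → 5 mg hit a susceptible fraction (30%) of
everolimus-exposed patients after an exponential delay (mean 52 days —
calibrated once so the *realized* mean time at 10 mg among reduced
patients is ≈ 40 days after truncation by progression).  Patients accrue
over 420 days before a common administrative cutoff at day 560, so
maximum follow-up varies per patient.

Achieved calibration at defaults (4-seed means): ≈ 1660 total
measurements, 97 patients with a reduction, 40 days at 10 mg and 112 days
at 5 mg among them, 81% of progressing placebo patients crossing over
after a mean of ≈ 84 days on placebo.  The emulated trial's corresponding
conduct figures are 1569, 98, 40.5, 117.3, 79.9% and 96.5 days; the
placebo-duration and measurement totals are emergent quantities, not
direct parameters, and are reported by `SimulatedCohort.calibration()`.

What the generator deliberately does not emulate: the screening
measurement is noiseless (it defines the fixed y₀ of the analysis, so the
estimation contract stays exact); treatment interruptions (dose 0 on
drug) are not simulated; covariate marginals are generic clinically
plausible distributions, since the real ones are unpublished; per-lesion
anatomy, adverse-event severity and survival outcomes are out of scope.
Passing tests therefore demonstrate correctness of the estimator under
the stated model, not robustness to measurement-model misspecification in
real trials.

The informative-censoring diagnostic `followup_growth_correlation` uses
the *specific* growth rate r_i/y₀,i.  The RECIST threshold is
proportional to the nadir, so large tumors grow faster in cm/day yet need
more absolute growth to progress; the raw correlation between r_i and
follow-up length is consequently confounded by baseline size (it is
slightly positive under the default baseline spread), while the
specific-rate correlation is robustly negative — which is the
fast-growers-exit-early phenomenon of interest.

## Population simulation and VPC

`simulate_population` draws, per virtual patient, fixed effects from the
estimation uncertainty (independent normals from reported SEs, or the
fitted covariance), random effects from the ω's, and baseline SLD from an
explicit model: `"fixed"` at the median or `"lognormal"` with a stated
log-SD.  The baseline model is a *required* choice because the population
mean percent change on placebo is convex in baseline (the 1/y₀ weighting)
and rises with the baseline spread; `baseline_sd_sensitivity` sweeps the
log-SD and ships with the package.  With log-SD 0.5 the one-year means at
the reference estimates are ≈ +123%, +23% and −13% for placebo, 5 mg and
10 mg (reported between-patient SDs in the source analysis: ±98.3, ±17.2,
±11.5 around +142.1, +22.4, −15.7; the placebo mean in particular cannot
be reproduced exactly without knowing the unprinted baseline sampling
model).  Percent-change summaries exclude residual error by default
(model-predicted SLD); a flag includes it.

The VPC simulates replicate datasets under the observed design — each
patient's own visit times, dosing and censoring time are kept, only η and
ε are redrawn — for two strata: placebo observations before any nonzero
dose, and patients on constant 10 mg from day 0.  Bands are the 5th/50th/
95th percentiles per nominal visit day with 95% envelopes across
replicates (the replicate count is chosen so stratum size × replicates ≈
the requested number of virtual patients); bins with fewer than 10
observed patients are flagged.  Because simulated η's are independent of
each patient's censoring time while the observed ones are not, the
observed late-time 95th percentile in the on-drug stratum sits *above*
the simulated band: the survivors are patients riding just below their
progression threshold, whom a fresh-η simulation regresses toward typical
behavior.  The acceptance suite verifies both the early-bin coverage of
the median and this late-time underestimation, and that the bias shrinks
when progression-driven stopping is disabled in the generator.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); regeneration with the same seed is
byte-identical and the CLI writes a manifest (canonical config hash,
seed, versions, no timestamp) with every run.  The test suite exercises
parameter recovery on 10 independently generated default trials,
selection consistency on 20 replicates (confounded-covariate condition)
plus 10 null replicates, and population simulation at the full 100,000
virtual patients; smaller cohorts (n = 30–120) are used where only the
mechanics, not the power, of a procedure is under test.

## Known limitations

* The estimator supports diagonal random-effect covariances only;
  correlations were considered in the source analysis with no reported
  outcome, and are not implemented.
* SAEM/MCMC estimation, below-limit-of-quantification handling, and joint
  tumor-size/survival modeling are out of scope, as are alternative
  growth laws (Gompertz, logistic, delayed effect) and PK linkage.
* The LRT's plain-χ² reference ignores the boundary issue for the added
  variance component (documented above).
* Fixed-effect uncertainty sampling treats reported SEs as independent
  normals when a full covariance is unavailable.
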