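# tgikit — tumor growth inhibition modeling of serial SLD measurements

`tgikit` is a Python toolkit for dose-dependent tumor-dynamics analysis of
longitudinal sum-of-longest-diameters (SLD) data, of the kind collected in
RECIST-assessed oncology trials.  It re-implements, as a tested and
reusable library, the pharmacodynamic analysis developed for a phase 3
placebo-controlled trial of daily oral everolimus in metastatic renal cell
carcinoma — a trial in which placebo patients could cross over to active
drug after progression and active patients could be dose-reduced from
10 mg to 5 mg for toxicity, so each patient's daily dose is a step function
of time and the model must follow it.

## The model

For patient *i*, the SLD *y* (cm) evolves as

    dy_i/dt = r_i − E_dose,i · y_i

where *r_i* is the net placebo growth rate (cm/day) and *E_dose,i* (1/day)
is the drug-induced decay in force at the current daily dose.  Two nested
dose-effect structures are supported:

* **model 1** — one drug effect for any nonzero dose (E₅ ≡ E₁₀);
* **model 2** — separate effects for 5 mg and 10 mg (E₅ ≠ E₁₀).

Individual parameters combine fixed effects, a power-law covariate on
baseline SLD (*ŷ₀* = 14.4 cm, the reference median), and additive normal
random effects:

    r_i   = r   · (y₀,i/ŷ₀)^θ1 + N(0, ω_r)
    E10,i = E10 · (y₀,i/ŷ₀)^θ2 + N(0, ω_E10)
    E5,i  = E5  · (y₀,i/ŷ₀)^θ2 + N(0, ω_E5)
    y_obs = y(t) + N(0, σ_ε)

Baseline *y₀,i* is fixed at the observed screening SLD, not estimated.
Because the ODE is linear within a constant-dose interval, trajectories
under arbitrary piecewise dosing are chained closed forms — no numerical
integration anywhere.

Estimation is nonlinear mixed-effects by FOCE (a Laplace approximation at
each patient's conditional mode, with the linearized curvature correction;
exact for placebo-only data).  The package also provides nested-model
likelihood-ratio testing, stepwise covariate selection with the
intersubject-variability reduction rule, empirical Bayes estimates and
η-shrinkage, virtual-population dose-response simulation, and visual
predictive checks.  A synthetic-trial generator emulates the study design
(2:1 randomization of 416 patients, 8-weekly assessments, crossover after
RECIST progression, toxicity-driven dose reductions, informative
censoring), so the whole pipeline is testable without any patient data.

## Worked example

```python
from tgikit import (
    ModelVariant, TrialDesign, fit, fit_table, generate_cohort,
    likelihood_ratio_test, reference_estimates, reference_standard_errors,
    simulate_population,
)

truth = reference_estimates()          # published final-model estimates
cohort = generate_cohort(TrialDesign(), truth, seed=1)
patients = cohort.analysis_patients()  # patients with a usable baseline

m2 = fit(patients)                                        # dose-specific model
m1 = fit(patients, variant=ModelVariant.MODEL1, compute_se=False)
lrt = likelihood_ratio_test(m1, m2)
print(f"LRT: delta OFV = {lrt.delta_ofv:.1f}, df = {lrt.df}, p = {lrt.p:.2g}")

p = m2.params
print(f"r   = {p.r*1e3:5.1f} +/- {m2.se('r')*1e3:.1f}  10^-3 cm/day")
print(f"E10 = {p.e10*1e3:5.2f} +/- {m2.se('e10')*1e3:.2f} 10^-3/day")
print(f"E5  = {p.e5*1e3:5.2f} +/- {m2.se('e5')*1e3:.2f} 10^-3/day")

for dose in (0.0, 5.0, 10.0):
    s = simulate_population(
        truth, dose, n=100_000, times=(365.0,),
        baseline="lognormal", baseline_log_sd=0.5,
        fixed_se=reference_standard_errors(), seed=11,
    )
    m, sd = s.at(365.0)
    print(f"1 year at {dose:>4} mg/day: {m:+6.1f}% +/- {sd:.1f}%")
```

Output:

```
LRT: delta OFV = 239.9, df = 2, p = 7.9e-53
r   =  45.5 +/- 1.0  10^-3 cm/day
E10 =  3.90 +/- 0.09 10^-3/day
E5  =  2.20 +/- 0.10 10^-3/day
1 year at  0.0 mg/day: +122.7% +/- 45.6%
1 year at  5.0 mg/day:  +23.1% +/- 22.9%
1 year at 10.0 mg/day:  -12.7% +/- 17.2%
```

The fit recovers the generating values (r = 46.0, E₁₀ = 3.9, E₅ = 2.3 in
the same units) well within two standard errors, the likelihood ratio test
decisively separates the two nested dose-effect models even though no arm
was randomized to 5 mg, and the one-year population predictions carry the
expected signs and ordering: unchecked growth on placebo, partial control
at 5 mg, net shrinkage at 10 mg.

A `tgikit` command-line interface wraps the same functionality
(`tgikit generate | fit | lrt | stepwise | simulate | vpc | report`); each
command writes its results plus a deterministic run manifest.

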