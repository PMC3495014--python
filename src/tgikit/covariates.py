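"""Stepwise covariate model building.

Forward inclusion (add the most significant candidate while any improves
the fit at P < 0.05), backward exclusion (retention requires P < 0.001),
plus an extra explanatory-power requirement: a covariate is kept only if it
also reduces the intersubject variability of the model parameters.  The
stepwise drivers apply the rule to the random effect of the parameter
group the covariate acts on (growth -> omega_r, drug effect -> omega_e10),
because the omega of the group it does not touch is weakly identified and
its refit-to-refit jitter would otherwise veto genuinely explanatory
covariates.  The omega rule is what rejects a covariate that improves the
likelihood by proxy — e.g. corrected calcium correlated with baseline SLD
— without explaining any between-patient variability itself.

Every tested candidate is logged to an audit trail (delta OFV, df, p,
omega changes, decision) that fully determines the final model and makes
the procedure replayable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .estimate import FitResult, fit, likelihood_ratio_test
from .model import CovariateEffect, ModelVariant, PatientRecord

__all__ = [
    "CovariateCandidate",
    "StepRecord",
    "StepwiseResult",
    "forward_include",
    "backward_exclude",
    "variability_reduction_check",
    "run_stepwise",
]

log = logging.getLogger(__name__)

#: CovariateCandidate is structurally a covariate term with theta unset.
CovariateCandidate = CovariateEffect


@dataclass
class StepRecord:
    phase: str  # "forward" | "backward"
    step: int
    candidate: str
    group: str
    delta_ofv: float
    df: int
    p: float
    omega_r_before: float
    omega_r_after: float
    omega_e10_before: float
    omega_e10_after: float
    decision: str
    reason: str = ""


@dataclass
class StepwiseResult:
    final_fit: FitResult
    terms: tuple[CovariateEffect, ...]
    audit: list[StepRecord] = field(default_factory=list)

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.audit])


def variability_reduction_check(
    fit_without: FitResult,
    fit_with: FitResult,
    effects: Sequence[str] = ("omega_r", "omega_e10"),
    min_rel_decrease: float = 1e-3,
) -> bool:
    """True iff the candidate reduces the joint intersubject variability.

    Operationalized as: the product of the tracked omega estimates must
    decrease by more than ``min_rel_decrease`` relative (equivalently, the
    sum of log omegas must drop).  A joint measure is used rather than a
    per-omega monotonicity requirement because refitting reshuffles a few
    percent of variability between random effects even for a genuinely
    explanatory covariate; a proxy covariate that merely improves the
    likelihood leaves the product essentially unchanged.
    """

    log_change = 0.0
    for name in effects:
        before = getattr(fit_without.params, name)
        after = getattr(fit_with.params, name)
        if before == after:
            continue
        if before <= 0 or after <= 0:
            # an omega collapsing to zero is a reduction; one appearing is not
            log_change += -1.0 if after < before else 1.0
            continue
        log_change += math.log(after / before)
    return log_change < math.log1p(-min_rel_decrease)


def _tracked_effects(candidate: CovariateEffect) -> tuple[str, ...]:
    """The omega(s) a candidate is required to reduce: the random effect of
    its own parameter group."""
    return ("omega_r",) if candidate.group == "growth" else ("omega_e10",)


def _degenerate(patients: Sequence[PatientRecord], cand: CovariateEffect) -> bool:
    """A candidate with a constant value in the cohort carries no information."""
    vals = set()
    for p in patients:
        v = (
            p.baseline_sld
            if cand.name == "baseline_sld"
            else p.covariates.get(cand.name)
        )
        if v is not None:
            vals.add(round(float(v), 12))
    return len(vals) < 2


def _fit_with_terms(patients, base_fit: FitResult, terms, compute_se=False):
    """Refit with a modified term set, warm-started at the current estimates."""
    return fit(
        patients,
        variant=base_fit.variant,
        terms=terms,
        init=base_fit.params,
        compute_se=compute_se,
        y0_ref=base_fit.params.y0_ref,
    )


def forward_include(
    patients: Sequence[PatientRecord],
    base_fit: FitResult,
    candidates: Sequence[CovariateCandidate],
    alpha: float = 0.05,
    require_omega_reduction: bool = True,
    audit: Optional[list[StepRecord]] = None,
    step_offset: int = 0,
) -> tuple[FitResult, list[CovariateCandidate], list[StepRecord]]:
    """Iterative forward inclusion at significance ``alpha``.

    At each step every remaining candidate is fit on top of the current
    model; among significant improvements the largest delta OFV (ties by
    name) is tried first, and the omega-reduction rule can veto it, in
    which case the next best significant candidate is considered.  Stops
    when no candidate qualifies.  Non-converged candidate fits are logged
    and treated as non-improving.
    """

    audit = audit if audit is not None else []
    current = base_fit
    selected: list[CovariateCandidate] = []
    pool = [c for c in candidates if not _degenerate(patients, c)]
    for c in candidates:
        if c not in pool:
            log.warning("candidate %r is constant in the cohort; skipped", c.name)
    step = step_offset
    while pool:
        step += 1
        tested = []
        for cand in pool:
            trial = _fit_with_terms(patients, current, current.terms + (cand,))
            lrt = likelihood_ratio_test(current, trial)
            rec = StepRecord(
                phase="forward",
                step=step,
                candidate=cand.name,
                group=cand.group,
                delta_ofv=lrt.delta_ofv,
                df=lrt.df,
                p=lrt.p,
                omega_r_before=current.params.omega_r,
                omega_r_after=trial.params.omega_r,
                omega_e10_before=current.params.omega_e10,
                omega_e10_after=trial.params.omega_e10,
                decision="pending",
            )
            if not trial.converged:
                rec.decision = "rejected"
                rec.reason = "fit did not converge"
                audit.append(rec)
                continue
            tested.append((cand, trial, lrt, rec))
        significant = [t for t in tested if t[2].p < alpha]
        significant.sort(key=lambda t: (-t[2].delta_ofv, t[0].name, t[0].group))
        winner = None
        for cand, trial, lrt, rec in significant:
            if require_omega_reduction and not variability_reduction_check(
                current, trial, effects=_tracked_effects(cand)
            ):
                rec.decision = "rejected"
                rec.reason = "no intersubject-variability reduction"
                continue
            winner = (cand, trial, rec)
            break
        for cand, trial, lrt, rec in tested:
            if winner is not None and cand is winner[0]:
                rec.decision = "included"
            elif rec.decision == "pending":
                rec.decision = "not included" if lrt.p < alpha else "not significant"
            audit.append(rec)
        if winner is None:
            break
        cand, trial, _ = winner
        selected.append(cand)
        pool = [c for c in pool if c is not cand]
        current = trial
    return current, selected, audit


def backward_exclude(
    patients: Sequence[PatientRecord],
    full_fit: FitResult,
    removable: Optional[Sequence[CovariateEffect]] = None,
    alpha: float = 0.001,
    require_omega_reduction: bool = False,
    audit: Optional[list[StepRecord]] = None,
    step_offset: int = 0,
) -> tuple[FitResult, list[StepRecord]]:
    """Backward exclusion: retention requires P < ``alpha``; the weakest
    covariate is removed and the scan repeats to a fixpoint.

    The omega-reduction rule is an inclusion-time requirement and is off by
    default here: once several covariates share the model, the omega of a
    weakly identified random effect moves by several percent between
    refits in either direction, so re-applying the rule at exclusion time
    would veto genuinely explanatory terms on refit noise.  It can be
    re-enabled via ``require_omega_reduction``."""

    audit = audit if audit is not None else []
    current = full_fit
    removable = list(removable if removable is not None else full_fit.terms)
    step = step_offset
    while True:
        step += 1
        worst = None
        records = []
        for term in [t for t in current.terms if t in removable]:
            reduced_terms = tuple(t for t in current.terms if t is not term)
            reduced = _fit_with_terms(patients, current, reduced_terms)
            lrt = likelihood_ratio_test(reduced, current)
            keeps_omega = (
                variability_reduction_check(
                    reduced, current, effects=_tracked_effects(term)
                )
                if require_omega_reduction
                else True
            )
            rec = StepRecord(
                phase="backward",
                step=step,
                candidate=term.name,
                group=term.group,
                delta_ofv=lrt.delta_ofv,
                df=lrt.df,
                p=lrt.p,
                omega_r_before=reduced.params.omega_r,
                omega_r_after=current.params.omega_r,
                omega_e10_before=reduced.params.omega_e10,
                omega_e10_after=current.params.omega_e10,
                decision="retained",
            )
            if not reduced.converged:
                rec.reason = "reduced fit did not converge; term retained"
                records.append((term, None, rec))
                continue
            fails = lrt.p >= alpha or not keeps_omega
            if fails:
                rec.reason = (
                    "retention p >= alpha" if lrt.p >= alpha else "omega rule"
                )
                if worst is None or lrt.p > worst[2].p:
                    worst = (term, reduced, rec)
            records.append((term, reduced, rec))
        for term, _, rec in records:
            if worst is not None and term is worst[0]:
                rec.decision = "removed"
            audit.append(rec)
        if worst is None:
            break
        term, reduced, _ = worst
        removable = [t for t in removable if t is not term]
        current = reduced
    return current, audit


def run_stepwise(
    patients: Sequence[PatientRecord],
    variant: ModelVariant = ModelVariant.MODEL2,
    candidates: Sequence[CovariateCandidate] = (),
    base_terms: Sequence[CovariateEffect] = (),
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.001,
    require_omega_reduction: bool = True,
    init=None,
    compute_se: bool = False,
) -> StepwiseResult:
    """Full stepwise procedure: base fit, forward inclusion, backward
    exclusion.  Deterministic given the data; the audit trail records every
    tested covariate and decision."""

    base = fit(
        patients, variant=variant, terms=tuple(base_terms), init=init,
        compute_se=False,
    )
    audit: list[StepRecord] = []
    fwd_fit, _, audit = forward_include(
        patients,
        base,
        candidates,
        alpha=forward_alpha,
        require_omega_reduction=require_omega_reduction,
        audit=audit,
    )
    n_fwd = max((r.step for r in audit), default=0)
    removable = [t for t in fwd_fit.terms if t not in tuple(base_terms)]
    final, audit = backward_exclude(
        patients,
        fwd_fit,
        removable=removable,
        alpha=backward_alpha,
        audit=audit,
        step_offset=n_fwd,
    )
    if compute_se and final.terms:
        final = _fit_with_terms(patients, final, final.terms, compute_se=True)
    elif compute_se:
        final = fit(
            patients, variant=variant, terms=(), init=final.params,
            compute_se=True,
        )
    return StepwiseResult(final_fit=final, terms=final.terms, audit=audit)
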