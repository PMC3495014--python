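"""Dose-dependent tumor growth model for serial SLD measurements.

The core model describes the sum of the longest diameters (SLD) of a
patient's target lesions as a balance between a zero-order growth term and
a first-order, dose-dependent kill term::

    dy/dt = r_i - E_dose,i * y

where ``y`` is the SLD in cm, ``r_i`` the patient's net placebo growth rate
(cm/day) and ``E_dose,i`` the drug effect (1/day) of the daily dose in force
at time ``t``.  The trial this design emulates used daily oral everolimus at
10 mg with toxicity-driven reductions to 5 mg, so the dose takes values in
{0, 5, 10} mg/day and the dose-effect map is a lookup rather than a
continuous exposure-response curve.

Individual parameters combine population fixed effects, multiplicative
covariate terms and additive, normally distributed random effects::

    r_i    = r   * (y0_i / y0_ref)^theta1 * (covariate multipliers) + eta_r
    E10_i  = E10 * (y0_i / y0_ref)^theta2 * (...)                   + eta_E10
    E5_i   = E5  * (y0_i / y0_ref)^theta2 * (...)                   + eta_E5

with the baseline-SLD exponent ``theta2`` shared between the two drug
effects.  Because the random effects are additive on the natural scale,
individual parameters may be negative; the trajectory solver is valid for
any sign of ``E`` (negative ``E`` gives exponential growth).

Within a constant-dose interval the ODE has the exact solution

    y(t) = r/E + (y_start - r/E) * exp(-E * (t - t_start))    (E != 0)
    y(t) = y_start + r * (t - t_start)                        (E == 0)

and trajectories under arbitrary piecewise dosing are chained from these
closed forms, so no numerical integration is ever needed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "DOSE_LEVELS",
    "ModelVariant",
    "CovariateEffect",
    "PopulationParams",
    "IndividualParams",
    "DoseInterval",
    "DosingHistory",
    "Observation",
    "PatientRecord",
    "reference_estimates",
    "reference_standard_errors",
    "covariate_multipliers",
    "individual_from_population",
    "effect_for_dose",
    "solve_trajectory",
    "percent_change",
    "recist_progression",
]

#: Daily doses (mg) that occurred in the trial design; the dose-effect map is
#: defined only on this set.
DOSE_LEVELS = (0.0, 5.0, 10.0)

#: Below this |E| (1/day) the exponential solution is numerically degenerate
#: (catastrophic cancellation in (1-exp(-E dt))/E); the linear branch is used.
LINEAR_EFFECT_TOL = 1e-12

RECIST_PROGRESSION_FACTOR = 1.20


class ModelVariant(enum.Enum):
    """Nested dose-effect structures.

    MODEL1 ties the 5 mg and 10 mg effects (one drug-effect fixed effect and
    one drug-effect random effect, applied whenever dose > 0).  MODEL2
    estimates separate effects for the two doses.  MODEL1 is nested in
    MODEL2 (set E5 = E10), which licenses a likelihood ratio test.
    """

    MODEL1 = "model1"
    MODEL2 = "model2"


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate term on one parameter group.

    Continuous covariates enter as a power law ``(x / reference)**theta``;
    binary covariates (coded 0/1) enter as ``theta**x``.  ``group`` is either
    ``"growth"`` (multiplies r) or ``"effect"`` (multiplies both drug
    effects, mirroring the shared baseline-SLD exponent).
    """

    name: str
    group: str  # "growth" | "effect"
    kind: str  # "continuous" | "binary"
    reference: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("growth", "effect"):
            raise ValueError(f"unknown parameter group {self.group!r}")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous" and not self.reference > 0:
            raise ValueError("continuous covariates need a positive reference value")

    def multiplier(self, value: float) -> float:
        if self.kind == "continuous":
            if value <= 0:
                raise ValueError(f"covariate {self.name!r} must be positive, got {value}")
            return (value / self.reference) ** self.theta
        # binary: theta**0 = 1, theta**1 = theta
        if value not in (0, 1, 0.0, 1.0, False, True):
            raise ValueError(f"binary covariate {self.name!r} must be 0/1, got {value}")
        return self.theta ** value if value else 1.0


@dataclass
class PopulationParams:
    """Population-level estimands of the final model.

    Units: ``r`` in cm/day, ``e10``/``e5`` in 1/day, ``sigma`` (additive
    residual SD) in cm, ``y0_ref`` (reference median baseline SLD) in cm.
    ``theta1``/``theta2`` are the dimensionless baseline-SLD exponents on the
    growth rate and the drug effects.  ``omega_*`` are the SDs of the
    additive random effects, in the units of their parameter.  Signed fixed
    effects are allowed (no positivity constraint).
    """

    r: float
    e10: float
    e5: float
    theta1: float = 0.0
    theta2: float = 0.0
    omega_r: float = 0.0
    omega_e10: float = 0.0
    omega_e5: float = 0.0
    sigma: float = 1.0
    y0_ref: float = 14.4
    extra: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        for name in ("r", "e10", "e5", "theta1", "theta2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("omega_r", "omega_e10", "omega_e5"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be nonnegative")
        # sigma = 0 is allowed as the noiseless simulation limit; the
        # likelihood functions themselves require sigma > 0
        if not self.sigma >= 0:
            raise ValueError("sigma must be nonnegative")
        if not self.y0_ref > 0:
            raise ValueError("y0_ref must be positive")
        self.extra = tuple(self.extra)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([self.omega_r, self.omega_e10, self.omega_e5])

    def with_(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)


@dataclass
class IndividualParams:
    """Realized per-patient parameters (may be negative: additive normal
    random effects on the natural scale)."""

    r: float
    e10: float
    e5: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if not (
            math.isfinite(self.r) and math.isfinite(self.e10) and math.isfinite(self.e5)
        ):
            raise ValueError("individual parameters must be finite")
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("eta must be finite")


def reference_estimates() -> PopulationParams:
    """Published final-model estimates from the phase 3 everolimus mRCC
    trial analysis that motivates this package; used as the default truth of
    the synthetic-trial generator and as initial values for simulations.
    """

    return PopulationParams(
        r=46.0e-3,
        e10=3.9e-3,
        e5=2.3e-3,
        theta1=0.4,
        theta2=-0.7,
        omega_r=3.5e-3,
        omega_e10=0.3e-3,
        omega_e5=0.2e-3,
        sigma=1.1,
        y0_ref=14.4,
    )


def reference_standard_errors() -> dict[str, float]:
    """Reported standard errors accompanying :func:`reference_estimates`
    (fixed effects and random-effect SDs; no SE was reported for sigma)."""

    return {
        "r": 5.7e-3,
        "e10": 0.5e-3,
        "e5": 0.5e-3,
        "theta1": 0.2,
        "theta2": 0.2,
        "omega_r": 2.1e-3,
        "omega_e10": 0.2e-3,
        "omega_e5": 0.2e-3,
    }


class DoseInterval(NamedTuple):
    """Half-open interval [start, end) of constant daily dose (mg)."""

    start: float
    end: float
    dose: float


class Observation(NamedTuple):
    """A tumor assessment: days from baseline and SLD in cm."""

    time: float
    sld: float


class DosingHistory:
    """Ordered, contiguous, gap-free piecewise-constant dosing from day 0.

    Doses are restricted to :data:`DOSE_LEVELS`; the dose could change at
    any (not necessarily integer) day.
    """

    __slots__ = ("intervals",)

    def __init__(self, intervals: Iterable[DoseInterval | tuple]):
        ivs = [DoseInterval(*iv) for iv in intervals]
        if not ivs:
            raise ValueError("dosing history must contain at least one interval")
        if ivs[0].start != 0:
            raise ValueError("dosing history must start at day 0")
        for iv in ivs:
            if iv.dose not in DOSE_LEVELS:
                raise ValueError(
                    f"dose must be one of {DOSE_LEVELS} mg/day, got {iv.dose}"
                )
            if not iv.end > iv.start:
                raise ValueError(f"empty or inverted interval {iv}")
        for a, b in zip(ivs, ivs[1:]):
            if b.start != a.end:
                raise ValueError(f"intervals not contiguous at day {a.end}")
        self.intervals = tuple(ivs)

    @classmethod
    def constant(cls, dose: float, end: float) -> "DosingHistory":
        return cls([DoseInterval(0.0, float(end), float(dose))])

    @classmethod
    def from_changes(
        cls, changes: Sequence[tuple[float, float]], end: float
    ) -> "DosingHistory":
        """Build from (day, new_dose) change points; first change must be day 0."""
        if not changes:
            raise ValueError("need at least the day-0 dose")
        chg = sorted((float(t), float(d)) for t, d in changes)
        # collapse consecutive identical doses
        ivs = []
        for (t, d), nxt in zip(chg, list(chg[1:]) + [(float(end), None)]):
            if ivs and ivs[-1].dose == d:
                ivs[-1] = DoseInterval(ivs[-1].start, nxt[0], d)
            else:
                ivs.append(DoseInterval(t, nxt[0], d))
        return cls(ivs)

    @property
    def end(self) -> float:
        return self.intervals[-1].end

    @property
    def change_points(self) -> list[tuple[float, float]]:
        return [(iv.start, iv.dose) for iv in self.intervals]

    def dose_at(self, t: float) -> float:
        if t < 0 or t >= self.end:
            raise ValueError(f"time {t} outside dosing coverage [0, {self.end})")
        for iv in self.intervals:
            if iv.start <= t < iv.end:
                return iv.dose
        raise AssertionError("unreachable")

    def segments(self, t: float) -> list[tuple[float, float]]:
        """Decompose [0, t] into (duration, dose) pieces."""
        if t < 0:
            raise ValueError("negative time")
        if t > self.end:
            raise ValueError(f"time {t} beyond dosing coverage (end={self.end})")
        out = []
        for iv in self.intervals:
            if iv.start >= t:
                break
            out.append((min(iv.end, t) - iv.start, iv.dose))
        return out

    def extended(self, end: float) -> "DosingHistory":
        """Same history with the last interval stretched to at least `end`."""
        if end <= self.end:
            return self
        last = self.intervals[-1]
        return DosingHistory(
            self.intervals[:-1] + (DoseInterval(last.start, float(end), last.dose),)
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, DosingHistory) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"DosingHistory({list(self.intervals)!r})"


@dataclass
class PatientRecord:
    """One patient's analysis data: fixed baseline SLD (cm), covariates,
    dosing history and timed SLD observations (baseline at time 0)."""

    id: str
    baseline_sld: float
    dosing: DosingHistory
    observations: list[Observation] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)
    arm: str = ""

    def __post_init__(self) -> None:
        if not self.baseline_sld > 0:
            raise ValueError("baseline SLD must be positive")
        self.observations = [Observation(*o) for o in self.observations]
        times = [o.time for o in self.observations]
        if any(t < 0 for t in times):
            raise ValueError("observation times must be nonnegative")
        if times != sorted(times):
            raise ValueError("observations must be time-sorted")

    @property
    def post_baseline(self) -> list[Observation]:
        return [o for o in self.observations if o.time > 0]


def covariate_multipliers(
    pop: PopulationParams,
    baseline_sld: float,
    covariates: Optional[dict[str, float]] = None,
) -> tuple[float, float]:
    """Multipliers on (growth rate, drug effect) for one patient.

    Combines the baseline-SLD power laws (theta1 on growth, theta2 shared by
    both drug effects) with any additional selected covariate terms.
    """

    if not baseline_sld > 0:
        raise ValueError("baseline SLD must be positive")
    mg = (baseline_sld / pop.y0_ref) ** pop.theta1
    me = (baseline_sld / pop.y0_ref) ** pop.theta2
    for eff in pop.extra:
        if covariates is None or eff.name not in covariates:
            raise ValueError(f"missing covariate {eff.name!r}")
        m = eff.multiplier(covariates[eff.name])
        if eff.group == "growth":
            mg *= m
        else:
            me *= m
    return mg, me


def individual_from_population(
    pop: PopulationParams,
    baseline_sld: float,
    covariates: Optional[dict[str, float]] = None,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> IndividualParams:
    """Realize individual parameters from population values, covariates and
    an additive random-effect draw ``eta = (eta_r, eta_e10, eta_e5)``."""

    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,):
        raise ValueError("eta must be a 3-vector")
    mg, me = covariate_multipliers(pop, baseline_sld, covariates)
    return IndividualParams(
        r=pop.r * mg + eta[0],
        e10=pop.e10 * me + eta[1],
        e5=pop.e5 * me + eta[2],
        eta=eta,
    )


def effect_for_dose(
    variant: ModelVariant, indiv: IndividualParams, dose: float
) -> float:
    """Drug effect (1/day) in force at a given daily dose (mg)."""

    if dose not in DOSE_LEVELS:
        raise ValueError(f"dose must be one of {DOSE_LEVELS} mg/day, got {dose}")
    if dose == 0:
        return 0.0
    if variant is ModelVariant.MODEL1:
        return indiv.e10
    return indiv.e10 if dose == 10 else indiv.e5


def _step(y_start: float, r: float, effect: float, dt: float) -> float:
    """Advance the closed-form solution by dt under constant (r, E)."""
    if abs(effect) < LINEAR_EFFECT_TOL:
        return y_start + r * dt
    asymptote = r / effect
    return asymptote + (y_start - asymptote) * math.exp(-effect * dt)


def solve_trajectory(
    indiv: IndividualParams,
    variant: ModelVariant,
    dosing: DosingHistory,
    y0: float,
    times: Sequence[float],
) -> np.ndarray:
    """Exact SLD trajectory at the requested times under piecewise dosing.

    Chains the per-interval closed forms; continuous at every dose switch
    and valid for signed effects.
    """

    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and nonnegative")
    if times.size and times[-1] > dosing.end:
        raise ValueError(
            f"time {times[-1]} beyond dosing coverage (end={dosing.end})"
        )
    if not y0 > 0:
        raise ValueError("y0 must be positive")

    out = np.empty_like(times)
    y = float(y0)
    j = 0
    for iv in dosing.intervals:
        eff = effect_for_dose(variant, indiv, iv.dose)
        # a time equal to iv.end is evaluated here; by continuity the next
        # interval would give the identical value
        while j < times.size and times[j] <= iv.end:
            out[j] = _step(y, indiv.r, eff, times[j] - iv.start)
            j += 1
        if j == times.size:
            break
        y = _step(y, indiv.r, eff, iv.end - iv.start)
    return out


def percent_change(sld, baseline) -> np.ndarray | float:
    """Percent change of SLD from baseline: 100 * (sld - baseline) / baseline."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    result = 100.0 * (np.asarray(sld, dtype=float) - baseline) / baseline
    return float(result) if result.ndim == 0 else result


def recist_progression(
    observations: Sequence[Observation | tuple],
    new_lesion_times: Sequence[float] = (),
) -> Optional[float]:
    """First progression day under the RECIST target-lesion rule, or None.

    Progression is the earliest assessment at which SLD is at least 20%
    above the running nadir (smallest SLD recorded at or after baseline,
    baseline included), or an exogenous new-lesion/nontarget event day if
    that comes first.
    """

    obs = [Observation(*o) for o in observations]
    if not obs:
        raise ValueError("empty observation list")
    if [o.time for o in obs] != sorted(o.time for o in obs):
        raise ValueError("observations must be time-sorted")

    sld_day: Optional[float] = None
    nadir = obs[0].sld
    for o in obs[1:]:
        if o.sld >= RECIST_PROGRESSION_FACTOR * nadir - 1e-12:
            sld_day = o.time
            break
        nadir = min(nadir, o.sld)
    lesion_day = min(new_lesion_times) if len(new_lesion_times) else None
    candidates = [d for d in (sld_day, lesion_day) if d is not None]
    return min(candidates) if candidates else None
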