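"""Nonlinear mixed-effects estimation by FOCE/Laplace.

The marginal likelihood of each patient integrates the joint density of the
data and the additive random effects over eta.  With additive, homoscedastic
residual error the first-order-conditional (FOCE) and FOCE-with-interaction
objectives coincide, and both are computed here as a Laplace approximation
at the per-patient conditional mode:

    OFV = sum_i [ g_i(eta_hat_i) - k*log(2*pi) + log det( H_i / 2 ) ]

where g_i is the joint -2 log density, eta_hat_i its minimizer (the
empirical Bayes estimate), k the number of active random effects and H_i
the Hessian of g_i at the mode (computed in omega-standardized coordinates;
the change of variables contributes -2*sum(log omega)).  The approximation
is exact whenever the model is linear in eta — in particular for
placebo-only data, where the trajectory is linear in the growth-rate random
effect; this is used as an oracle in the test suite.

Numerical strategy
------------------
The prediction at any time is affine in the growth rate, y = y0*A + r_i*B
(see ``_engine``), so the growth random effect is profiled out in closed
form and the inner optimization runs over the drug-effect random effects
only (dimension <= 2), as a damped Newton iteration vectorized across the
whole cohort.  Variances are optimized on the log scale; fixed effects on
the natural (signed) scale.  Standard errors come from the observed
information matrix by central finite differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._engine import TrajectoryEngine
from .model import (
    CovariateEffect,
    ModelVariant,
    PatientRecord,
    PopulationParams,
    covariate_multipliers,
    individual_from_population,
    solve_trajectory,
)

__all__ = [
    "FitResult",
    "LRTResult",
    "BASELINE_GROWTH",
    "BASELINE_EFFECT",
    "DEFAULT_TERMS",
    "joint_neg2ll",
    "marginal_neg2ll",
    "fit",
    "initial_estimates",
    "eta_shrinkage",
    "likelihood_ratio_test",
    "individual_predictions",
]

log = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

#: Baseline SLD as a covariate on the growth rate / the drug effects; these
#: two terms constitute the final covariate model.
BASELINE_GROWTH = CovariateEffect("baseline_sld", "growth", "continuous", 14.4)
BASELINE_EFFECT = CovariateEffect("baseline_sld", "effect", "continuous", 14.4)
DEFAULT_TERMS = (BASELINE_GROWTH, BASELINE_EFFECT)

_INNER_GTOL = 1e-7
_INNER_MAXITER = 60


# --------------------------------------------------------------------------
# reference (scalar) joint density, used directly in tests and small tools
# --------------------------------------------------------------------------


def joint_neg2ll(
    pop: PopulationParams,
    patient: PatientRecord,
    variant: ModelVariant = ModelVariant.MODEL2,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> float:
    """Joint -2 log density of one patient's post-baseline data and eta.

    Random-effect prior terms are included for every effect with a positive
    omega (for MODEL1 the tied drug effect uses ``eta[1]``/``omega_e10``;
    ``eta[2]`` is inert).  Patients contribute one Gaussian term per
    post-baseline observation with mean given by the exact trajectory.
    """

    if not pop.sigma > 0:
        raise ValueError("sigma must be positive")
    obs = patient.post_baseline
    indiv = individual_from_population(
        pop, patient.baseline_sld, patient.covariates, eta
    )
    times = np.array([o.time for o in obs])
    y = np.array([o.sld for o in obs])
    dosing = patient.dosing.extended(times[-1] if times.size else 0.0)
    pred = solve_trajectory(indiv, variant, dosing, patient.baseline_sld, times)
    sig2 = pop.sigma**2
    g = times.size * math.log(2 * math.pi * sig2) + float(
        np.sum((y - pred) ** 2)
    ) / sig2
    active = [pop.omega_r, pop.omega_e10]
    etas = [eta[0], eta[1]]
    if variant is ModelVariant.MODEL2:
        active.append(pop.omega_e5)
        etas.append(eta[2])
    for w, e in zip(active, etas):
        if w > 0:
            g += math.log(2 * math.pi * w**2) + (e / w) ** 2
    return g


# --------------------------------------------------------------------------
# batched Laplace core
# --------------------------------------------------------------------------


class _LaplaceCore:
    """Batched inner problem for one cohort design and model variant.

    Random-effect layout: the growth effect plus, for MODEL2, separate
    10 mg and 5 mg drug effects or, for MODEL1, a single tied drug effect.
    Dims whose omega is exactly zero are inactive (eta fixed at 0).

    The conditional modes are found by damped Newton over the drug-effect
    etas only — the growth eta is profiled in closed form because the
    prediction is affine in it — using exact analytic gradients and a
    Gauss-Newton curvature (positive definite by construction).  The
    log-det correction uses the same linearized curvature, which is the
    FOCE convention and exact whenever the model is linear in eta.
    """

    def __init__(self, engine: TrajectoryEngine, variant: ModelVariant):
        self.engine = engine
        self.variant = variant
        self.n_pat = engine.n_pat
        self.warm: Optional[np.ndarray] = None
        self.inner_failures = 0

    def _edims(self, omegas):
        w_r, w_10, w_5 = omegas
        if self.variant is ModelVariant.MODEL1:
            return ["e"] if w_10 > 0 else []
        return [d for d, w in (("e10", w_10), ("e5", w_5)) if w > 0]

    def _eval(self, u_e, mus, omegas, sigma, edims, want_grad=False):
        """Profiled joint -2ll per patient; optionally analytic gradient,
        Gauss-Newton Newton matrix over the drug-effect dims, and the
        linearized curvature M = J'J/sigma^2 + I over all active dims."""
        r_mu, e10_mu, e5_mu = mus
        w_r, w_10, w_5 = omegas
        eng = self.engine
        eta10 = np.zeros(self.n_pat)
        eta5 = np.zeros(self.n_pat)
        for j, d in enumerate(edims):
            if d in ("e10", "e"):
                eta10 = w_10 * u_e[:, j]
            else:
                eta5 = w_5 * u_e[:, j]
        if self.variant is ModelVariant.MODEL1:
            e10_i = e5_i = e10_mu + eta10
        else:
            e10_i, e5_i = e10_mu + eta10, e5_mu + eta5

        if want_grad:
            A, B, dA10, dB10, dA5, dB5 = eng.AB_grad(e10_i, e5_i)
        else:
            A, B = eng.AB(e10_i, e5_i)
        res0 = eng.y - (eng.y0_obs * A + r_mu[eng.pat] * B)
        sig2 = sigma**2
        Sbb = eng.sum_by_patient(B * B)
        Sbr = eng.sum_by_patient(B * res0)
        Srr = eng.sum_by_patient(res0 * res0)
        if w_r > 0:
            eta_r = (Sbr / sig2) / (Sbb / sig2 + 1.0 / w_r**2)
        else:
            eta_r = np.zeros(self.n_pat)
        rss = Srr - 2.0 * eta_r * Sbr + eta_r**2 * Sbb
        g = eng.n_per_pat * math.log(2 * math.pi * sig2) + rss / sig2
        if w_r > 0:
            g = g + math.log(2 * math.pi * w_r**2) + (eta_r / w_r) ** 2
        for j, d in enumerate(edims):
            w = w_10 if d in ("e10", "e") else w_5
            g = g + math.log(2 * math.pi * w**2) + u_e[:, j] ** 2
        if not want_grad:
            return g, eta_r

        # per-observation derivatives of the prediction w.r.t. each active
        # eta dim, standardized by its omega
        r_obs = (r_mu + eta_r)[eng.pat]
        res = res0 - eta_r[eng.pat] * B
        D = []
        dims = []
        if w_r > 0:
            D.append(w_r * B)
            dims.append("r")
        for d in edims:
            if d == "e10":
                D.append(w_10 * (eng.y0_obs * dA10 + r_obs * dB10))
            elif d == "e5":
                D.append(w_5 * (eng.y0_obs * dA5 + r_obs * dB5))
            else:  # tied effect
                D.append(
                    w_10
                    * (eng.y0_obs * (dA10 + dA5) + r_obs * (dB10 + dB5))
                )
            dims.append(d)
        k = len(dims)
        M = np.empty((self.n_pat, k, k))
        for a in range(k):
            for b in range(a, k):
                s = eng.sum_by_patient(D[a] * D[b]) / sig2
                M[:, a, b] = s
                M[:, b, a] = s
        M += np.eye(k)

        ke = len(edims)
        off = k - ke
        grad = np.empty((self.n_pat, ke))
        for j in range(ke):
            grad[:, j] = (
                -2.0 * eng.sum_by_patient(res * D[off + j]) / sig2
                + 2.0 * u_e[:, j]
            )
        # profile out the growth dim from the Newton matrix (Schur)
        H_e = 2.0 * M[:, off:, off:]
        if off:
            cross = M[:, off:, :off]
            H_e = H_e - 2.0 * np.einsum(
                "nij,njk->nik", cross, cross.transpose(0, 2, 1)
            ) / M[:, :1, :1]
        return g, eta_r, grad, H_e, M

    def _inner_solve(self, mus, omegas, sigma, edims, u0):
        cheap = lambda u: self._eval(u, mus, omegas, sigma, edims)[0]
        u = u0.copy()
        g, _, grad, H, _ = self._eval(u, mus, omegas, sigma, edims, True)
        for _ in range(_INNER_MAXITER):
            gnorm = np.max(np.abs(grad), axis=1)
            todo = gnorm > _INNER_GTOL
            if not np.any(todo):
                break
            step = _newton_step(grad, H)
            scale = np.where(todo, 1.0, 0.0)
            for _ls in range(15):
                u_t = u + scale[:, None] * step
                g_t = cheap(u_t)
                worse = todo & (g_t > g + 1e-13)
                if not np.any(worse):
                    break
                scale = np.where(worse, scale * 0.5, scale)
            improved = g_t <= g + 1e-13
            u = np.where(improved[:, None], u_t, u)
            g, _, grad, H, _ = self._eval(u, mus, omegas, sigma, edims, True)
        else:
            self.inner_failures += int(np.sum(gnorm > 10 * _INNER_GTOL))
        return u

    def solve(self, mus, omegas, sigma, want_detail=False):
        """Cohort OFV (and optionally EBEs) at the given population values."""
        w_r, w_10, w_5 = omegas
        edims = self._edims(omegas)
        ke = len(edims)
        if ke:
            if self.warm is None or self.warm.shape[1] != ke:
                self.warm = np.zeros((self.n_pat, ke))
            u_e = self._inner_solve(mus, omegas, sigma, edims, self.warm)
            self.warm = u_e.copy()
        else:
            u_e = np.zeros((self.n_pat, 0))
        g_mode, eta_r, _, _, M = self._eval(
            u_e, mus, omegas, sigma, edims, want_grad=True
        )

        dims = (["r"] if w_r > 0 else []) + edims
        k = len(dims)
        if k == 0:
            ofv = float(np.sum(g_mode))
            if want_detail:
                return ofv, np.zeros((self.n_pat, 3)), g_mode
            return ofv

        M = np.nan_to_num(M, nan=1e150, posinf=1e150, neginf=-1e150)
        sign, logdet = np.linalg.slogdet(M)  # M is PD: I + PSD
        wsum = sum(
            math.log(w_r if d == "r" else (w_10 if d in ("e10", "e") else w_5))
            for d in dims
        )
        # -2 log of the Laplace/FOCE integral: the Gaussian volume factor
        # contributes -k log 2pi, the standardized curvature H_u/2 = M, and
        # the change of variables u = eta/omega contributes -2 sum(log omega)
        ofv_i = g_mode - k * LOG_2PI + logdet - 2.0 * wsum
        ofv = float(np.sum(ofv_i))
        if not math.isfinite(ofv):
            ofv = 1e12  # reject the region; the outer optimizer backtracks
        if want_detail:
            etas = np.zeros((self.n_pat, 3))
            etas[:, 0] = eta_r
            for j, d in enumerate(edims):
                if d == "e":
                    etas[:, 1] = w_10 * u_e[:, j]
                    etas[:, 2] = etas[:, 1]
                elif d == "e10":
                    etas[:, 1] = w_10 * u_e[:, j]
                else:
                    etas[:, 2] = w_5 * u_e[:, j]
            return ofv, etas, ofv_i
        return ofv


# --------------------------------------------------------------------------
# public cohort objective
# --------------------------------------------------------------------------


def _newton_step(grad: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Damped per-patient Newton step -H^{-1}g for k in {1, 2}, in closed
    form with non-finite and near-singular guards.  The Gauss-Newton H is
    PD in exact arithmetic; overflow during wild outer-parameter
    excursions can still corrupt individual patients, who then get a
    benign small step that the line search is free to reject."""
    grad = np.nan_to_num(grad, nan=0.0, posinf=0.0, neginf=0.0)
    H = np.nan_to_num(H, nan=0.0, posinf=1e12, neginf=-1e12)
    k = grad.shape[1]
    if k == 1:
        h = np.maximum(H[:, 0, 0], 1e-8)
        return -grad / h[:, None]
    a = np.maximum(H[:, 0, 0], 1e-8)
    c = np.maximum(H[:, 1, 1], 1e-8)
    b = H[:, 0, 1]
    det = a * c - b * b
    bad = det <= 1e-12 * a * c
    b = np.where(bad, 0.0, b)
    det = np.where(bad, a * c, det)
    sx = -(c * grad[:, 0] - b * grad[:, 1]) / det
    sy = -(a * grad[:, 1] - b * grad[:, 0]) / det
    return np.stack([sx, sy], axis=1)


def _cohort_mus(pop: PopulationParams, patients: Sequence[PatientRecord]):
    mg = np.empty(len(patients))
    me = np.empty(len(patients))
    for i, p in enumerate(patients):
        mg[i], me[i] = covariate_multipliers(pop, p.baseline_sld, p.covariates)
    return pop.r * mg, pop.e10 * me, pop.e5 * me


def marginal_neg2ll(
    pop: PopulationParams,
    patients: Sequence[PatientRecord],
    variant: ModelVariant = ModelVariant.MODEL2,
) -> float:
    """FOCE/Laplace cohort objective (-2 approximate marginal log-likelihood).

    Deterministic given inputs; exact for models linear in eta (placebo-only
    data) and additive over patients.
    """

    if not pop.sigma > 0:
        raise ValueError("sigma must be positive")
    usable = [p for p in patients if p.post_baseline]
    core = _LaplaceCore(TrajectoryEngine(usable), variant)
    mus = _cohort_mus(pop, usable)
    omegas = (pop.omega_r, pop.omega_e10, pop.omega_e5)
    return core.solve(mus, omegas, pop.sigma)


# --------------------------------------------------------------------------
# maximum likelihood fit
# --------------------------------------------------------------------------


@dataclass
class LRTResult:
    delta_ofv: float
    df: int
    p: float
    ok: bool = True


@dataclass
class FitResult:
    """Converged (or best-found) population fit."""

    variant: ModelVariant
    terms: tuple[CovariateEffect, ...]
    params: PopulationParams
    ofv: float
    n_params: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    cov_fixed: Optional[np.ndarray] = None
    fixed_names: tuple[str, ...] = ()
    ebes: Optional[np.ndarray] = None  # (n_pat, 3): eta_r, eta_e10, eta_e5
    patient_ids: tuple = ()
    shrinkage: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    n_dropped: int = 0
    n_patients: int = 0
    n_obs: int = 0
    message: str = ""

    def se(self, name: str) -> float:
        return self.standard_errors.get(name, float("nan"))


class _ParamPack:
    """Maps between the free parameter vector (scaled) and model values.

    Fixed effects live on the natural scale; omegas and sigma on the log
    scale; binary covariate effects on the log scale (positive multiplier).
    """

    _SCALES = {"r": 0.01, "e10": 0.001, "e5": 0.001, "beta": 0.2, "log": 0.5}

    def __init__(self, variant, terms, init: PopulationParams, fixed):
        self.variant = variant
        self.terms = tuple(terms)
        fixed = dict(fixed or {})
        # friendly aliases
        alias = {
            "theta1": "beta_growth_baseline_sld",
            "theta2": "beta_effect_baseline_sld",
            "omega_r": "log_omega_r",
            "omega_e10": "log_omega_e10",
            "omega_e5": "log_omega_e5",
            "sigma": "log_sigma",
        }
        self.fixed = {alias.get(k, k): v for k, v in fixed.items()}

        names = ["r", "e10"]
        if variant is ModelVariant.MODEL2:
            names.append("e5")
        for t in self.terms:
            names.append(f"beta_{t.group}_{t.name}")
        names.append("log_omega_r")
        names.append("log_omega_e10")
        if variant is ModelVariant.MODEL2:
            names.append("log_omega_e5")
        names.append("log_sigma")
        self.all_names = names
        self.free_names = [n for n in names if n not in self.fixed]
        self.scales = np.array([self._scale(n) for n in self.free_names])
        self._init_values = self._values_from_params(init)

    def _scale(self, name):
        if name.startswith("log_"):
            return self._SCALES["log"]
        if name.startswith("beta_"):
            return self._SCALES["beta"]
        return self._SCALES[name]

    def _term_init(self, t: CovariateEffect, init: PopulationParams) -> float:
        if t.name == "baseline_sld":
            th = init.theta1 if t.group == "growth" else init.theta2
            return th
        for e in init.extra:
            if e.name == t.name and e.group == t.group:
                return math.log(e.theta) if t.kind == "binary" else e.theta
        return 0.0

    def _values_from_params(self, init: PopulationParams) -> dict[str, float]:
        floor = 1e-8
        vals = {
            "r": init.r,
            "e10": init.e10,
            "e5": init.e5,
            "log_omega_r": math.log(max(init.omega_r, floor)),
            "log_omega_e10": math.log(max(init.omega_e10, floor)),
            "log_omega_e5": math.log(max(init.omega_e5, floor)),
            "log_sigma": math.log(init.sigma),
        }
        for t in self.terms:
            vals[f"beta_{t.group}_{t.name}"] = self._term_init(t, init)
        return vals

    def x0(self) -> np.ndarray:
        return np.array(
            [self._init_values[n] for n in self.free_names]
        ) / self.scales

    def bounds(self):
        out = []
        for n in self.free_names:
            if n.startswith("log_"):
                s = self._scale(n)
                out.append((-25.0 / s, 5.0 / s))
            else:
                out.append((None, None))
        return out

    def values(self, x: np.ndarray) -> dict[str, float]:
        vals = dict(self._init_values)
        for n, xi, s in zip(self.free_names, x, self.scales):
            vals[n] = xi * s
        for n, v in self.fixed.items():
            if n.startswith("log_"):
                vals[n] = math.log(v) if v > 0 else -math.inf
            else:
                vals[n] = v
        return vals

    def to_params(self, vals: dict[str, float], y0_ref: float) -> PopulationParams:
        def w(name):
            v = vals[name]
            return 0.0 if v == -math.inf else math.exp(v)

        theta1 = theta2 = 0.0
        extra = []
        for t in self.terms:
            b = vals[f"beta_{t.group}_{t.name}"]
            th = math.exp(b) if t.kind == "binary" else b
            if t.name == "baseline_sld":
                if t.group == "growth":
                    theta1 = th
                else:
                    theta2 = th
            else:
                extra.append(
                    CovariateEffect(t.name, t.group, t.kind, t.reference, th)
                )
        e5 = vals["e5"] if self.variant is ModelVariant.MODEL2 else vals["e10"]
        w5 = (
            w("log_omega_e5")
            if self.variant is ModelVariant.MODEL2
            else w("log_omega_e10")
        )
        return PopulationParams(
            r=vals["r"],
            e10=vals["e10"],
            e5=e5,
            theta1=theta1,
            theta2=theta2,
            omega_r=w("log_omega_r"),
            omega_e10=w("log_omega_e10"),
            omega_e5=w5,
            sigma=max(w("log_sigma"), 1e-12),
            y0_ref=y0_ref,
            extra=tuple(extra),
        )


def _covariate_design(patients, terms):
    """Per-term covariate regressors z_i: log(x/ref) for continuous terms,
    the 0/1 indicator for binary ones.  Missing values are imputed at the
    reference (z = 0) with a logged warning."""
    zg, ze = [], []
    for t in terms:
        z = np.zeros(len(patients))
        n_missing = 0
        for i, p in enumerate(patients):
            if t.name == "baseline_sld":
                x = p.baseline_sld
            elif t.name in p.covariates:
                x = p.covariates[t.name]
            else:
                n_missing += 1
                continue
            z[i] = math.log(x / t.reference) if t.kind == "continuous" else float(x)
        if n_missing:
            log.warning(
                "covariate %r missing for %d patients; imputed at reference",
                t.name,
                n_missing,
            )
        (zg if t.group == "growth" else ze).append(z)
    return zg, ze


def initial_estimates(
    patients: Sequence[PatientRecord], variant: ModelVariant = ModelVariant.MODEL2
) -> PopulationParams:
    """Two-stage starting values: pooled medians of per-segment slopes.

    Consecutive observation pairs with no intervening dose change give a
    growth-rate estimate on dose 0 (the raw slope) and a drug-effect
    estimate on dose (r0 - slope) / mean(y).  Crude, but lands within a
    factor of a few of typical values, which is all the optimizer needs.
    """

    slopes0, eff10, eff5 = [], [], []
    for p in patients:
        obs = [o for o in p.observations]
        for a, b in zip(obs, obs[1:]):
            if b.time <= a.time:
                continue
            if any(a.time < t < b.time for t, _ in p.dosing.change_points):
                continue
            dose = p.dosing.dose_at(a.time) if a.time < p.dosing.end else 0.0
            slope = (b.sld - a.sld) / (b.time - a.time)
            ybar = 0.5 * (a.sld + b.sld)
            if dose == 0:
                slopes0.append(slope)
            elif dose == 10:
                eff10.append((slope, ybar))
            else:
                eff5.append((slope, ybar))
    r0 = float(np.median(slopes0)) if slopes0 else 0.02
    if not (1e-4 < r0 < 1.0):
        r0 = 0.02

    def eff(pairs, fallback):
        if not pairs:
            return fallback
        vals = [(r0 - s) / y for s, y in pairs]
        v = float(np.median(vals))
        return v if v > 1e-4 else fallback

    e10_0 = eff(eff10, 2e-3)
    e5_0 = eff(eff5, 0.6 * e10_0)
    return PopulationParams(
        r=r0,
        e10=e10_0,
        e5=e5_0,
        omega_r=0.3 * abs(r0),
        omega_e10=0.3 * abs(e10_0),
        omega_e5=0.3 * abs(e5_0),
        sigma=1.0,
    )


def fit(
    patients: Sequence[PatientRecord],
    variant: ModelVariant = ModelVariant.MODEL2,
    terms: Sequence[CovariateEffect] = DEFAULT_TERMS,
    init: Optional[PopulationParams] = None,
    fixed: Optional[dict[str, float]] = None,
    compute_se: bool = True,
    y0_ref: float = 14.4,
    maxiter: int = 400,
) -> FitResult:
    """Maximum-likelihood fit of the population model by FOCE/Laplace.

    Patients without a post-baseline observation contribute no likelihood
    terms and are dropped with a logged count.  Non-convergence is reported
    in the result flags, never raised.
    """

    usable = [p for p in patients if p.post_baseline]
    n_dropped = len(patients) - len(usable)
    if n_dropped:
        log.info("dropped %d patients without post-baseline assessments", n_dropped)
    if not usable:
        raise ValueError("no patients with post-baseline observations")

    if init is None:
        init = initial_estimates(usable, variant)
    pack = _ParamPack(variant, terms, init, fixed)
    engine = TrajectoryEngine(usable)
    core = _LaplaceCore(engine, variant)
    zg, ze = _covariate_design(usable, pack.terms)
    bg = [f"beta_{t.group}_{t.name}" for t in pack.terms if t.group == "growth"]
    be = [f"beta_{t.group}_{t.name}" for t in pack.terms if t.group == "effect"]

    def mus_from(vals):
        lg = np.zeros(engine.n_pat)
        le = np.zeros(engine.n_pat)
        for nm, z in zip(bg, zg):
            lg += vals[nm] * z
        for nm, z in zip(be, ze):
            le += vals[nm] * z
        mg = np.exp(lg)
        me = np.exp(le)
        return vals["r"] * mg, vals["e10"] * me, (
            vals["e5"] if variant is ModelVariant.MODEL2 else vals["e10"]
        ) * me

    def unpack(vals):
        def w(name, tied=None):
            v = vals.get(name)
            if v is None and tied:
                v = vals[tied]
            return 0.0 if v == -math.inf else math.exp(v)

        w5 = (
            w("log_omega_e5")
            if variant is ModelVariant.MODEL2
            else w("log_omega_e10")
        )
        return (
            (w("log_omega_r"), w("log_omega_e10"), w5),
            max(math.exp(vals["log_sigma"]), 1e-12),
        )

    def objective(x):
        vals = pack.values(x)
        omegas, sigma = unpack(vals)
        return core.solve(mus_from(vals), omegas, sigma)

    x0 = pack.x0()
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=pack.bounds(),
        options={
            "maxiter": maxiter,
            "ftol": 1e-11,
            "gtol": 1e-6,
            "eps": 1e-4,
            "maxcor": 20,
        },
    )
    xhat = res.x
    vals = pack.values(xhat)
    omegas, sigma = unpack(vals)
    ofv, etas, _ = core.solve(mus_from(vals), omegas, sigma, want_detail=True)
    params = pack.to_params(vals, y0_ref)

    result = FitResult(
        variant=variant,
        terms=pack.terms,
        params=params,
        ofv=float(ofv),
        n_params=len(pack.free_names),
        ebes=etas,
        patient_ids=tuple(p.id for p in usable),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_dropped=n_dropped,
        n_patients=len(usable),
        n_obs=engine.n_obs,
        message=str(res.message),
    )
    result.shrinkage = eta_shrinkage(result)

    if compute_se:
        _attach_standard_errors(result, pack, objective, xhat, ofv)
    return result


def _attach_standard_errors(result, pack, objective, xhat, f0):
    """SEs from the observed information (central FD Hessian of the OFV)."""
    p = len(xhat)
    h = 5e-4
    H = np.zeros((p, p))
    fp = np.zeros(p)
    fm = np.zeros(p)
    for a in range(p):
        ea = np.zeros(p)
        ea[a] = h
        fp[a] = objective(xhat + ea)
        fm[a] = objective(xhat - ea)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h**2
    for a in range(p):
        ea = np.zeros(p)
        ea[a] = h
        for b in range(a + 1, p):
            eb = np.zeros(p)
            eb[b] = h
            H[a, b] = H[b, a] = (
                objective(xhat + ea + eb)
                - objective(xhat + ea - eb)
                - objective(xhat - ea + eb)
                + objective(xhat - ea - eb)
            ) / (4 * h**2)
    # OFV = -2 logL, so observed information = H/2 and Cov = 2 H^{-1}
    try:
        cov_x = 2.0 * np.linalg.inv(H)
        if np.any(np.diag(cov_x) <= 0):
            raise np.linalg.LinAlgError("non-PD information")
    except np.linalg.LinAlgError:
        cov_x = 2.0 * np.linalg.pinv(H)
        result.message += "; information matrix not PD, pseudo-inverse SEs"
    S = np.diag(pack.scales)
    cov_v = S @ cov_x @ S  # covariance of the internal-scale values
    se_int = np.sqrt(np.abs(np.diag(cov_v)))

    vals = pack.values(xhat)
    ses: dict[str, float] = {}
    jac = np.ones(len(pack.free_names))  # internal -> natural scale
    for i, n in enumerate(pack.free_names):
        if n.startswith("log_"):
            nat = math.exp(vals[n])
            ses[n[4:]] = nat * se_int[i]  # delta method
            jac[i] = nat
        elif n.startswith("beta_"):
            t = next(
                t for t in pack.terms if f"beta_{t.group}_{t.name}" == n
            )
            if t.kind == "binary":
                th = math.exp(vals[n])
                ses[_theta_key(t)] = th * se_int[i]
                jac[i] = th
            else:
                ses[_theta_key(t)] = se_int[i]
        else:
            ses[n] = se_int[i]
    result.standard_errors = ses

    fixed_idx = [
        i
        for i, n in enumerate(pack.free_names)
        if not n.startswith("log_")
    ]
    J = np.diag(jac)
    cov_nat = J @ cov_v @ J
    result.cov_fixed = cov_nat[np.ix_(fixed_idx, fixed_idx)]
    result.fixed_names = tuple(
        _natural_name(pack, pack.free_names[i]) for i in fixed_idx
    )


def _theta_key(t: CovariateEffect) -> str:
    if t.name == "baseline_sld":
        return "theta1" if t.group == "growth" else "theta2"
    return f"theta_{t.group}_{t.name}"


def _natural_name(pack, name: str) -> str:
    if name.startswith("beta_"):
        t = next(t for t in pack.terms if f"beta_{t.group}_{t.name}" == name)
        return _theta_key(t)
    return name


def eta_shrinkage(fit_result: FitResult) -> dict[str, float]:
    """Per-random-effect eta-shrinkage: 1 - SD(EBEs) / omega_hat.

    Near 1 when the data carry little information about an effect (e.g. a
    5-mg drug effect in a cohort where few patients ever receive 5 mg).
    Undefined (nan) when omega_hat is zero.
    """

    p = fit_result.params
    ebes = fit_result.ebes
    if ebes is None:
        raise ValueError("fit has no EBEs")
    out = {}
    pairs = [("eta_r", 0, p.omega_r), ("eta_e10", 1, p.omega_e10)]
    if fit_result.variant is ModelVariant.MODEL2:
        pairs.append(("eta_e5", 2, p.omega_e5))
    for name, col, w in pairs:
        if w > 0:
            out[name] = 1.0 - float(np.std(ebes[:, col], ddof=1)) / w
        else:
            out[name] = float("nan")
    return out


def likelihood_ratio_test(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """Chi-square LRT between nested fits on the same data.

    delta = OFV(null) - OFV(alternative), df = extra estimated parameters.
    A negative delta beyond numerical tolerance flags an optimization
    failure (the richer model can never truly fit worse).
    """

    delta = fit_null.ofv - fit_alt.ofv
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("models are not nested in the expected direction")
    ok = delta >= -1e-4
    p = float(stats.chi2.sf(max(delta, 0.0), df))
    return LRTResult(delta_ofv=float(delta), df=df, p=p, ok=ok)


def individual_predictions(
    fit_result: FitResult, patients: Sequence[PatientRecord]
) -> np.ndarray:
    """Predicted SLD at every post-baseline observation, at the EBE modes.

    Patient order must match the fitted cohort (checked via ids).
    """

    usable = [p for p in patients if p.post_baseline]
    if tuple(p.id for p in usable) != fit_result.patient_ids:
        raise ValueError("patients do not match the fitted cohort")
    engine = TrajectoryEngine(usable)
    pop = fit_result.params
    r_mu, e10_mu, e5_mu = _cohort_mus(pop, usable)
    ebes = fit_result.ebes
    r_i = r_mu + ebes[:, 0]
    e10_i = e10_mu + ebes[:, 1]
    if fit_result.variant is ModelVariant.MODEL1:
        e10_i = e10_mu + ebes[:, 1]
        e5_i = e10_i
    else:
        e5_i = e5_mu + ebes[:, 2]
    return engine.predict(r_i, e10_i, e5_i)
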