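"""FOCE/Laplace estimator: joint density, marginal objective (with its
closed-form linear-mixed-model oracle), fitting, shrinkage and the LRT."""

import math

import numpy as np
import pytest

from tgikit._engine import TrajectoryEngine
from tgikit.estimate import (
    FitResult,
    eta_shrinkage,
    fit,
    individual_predictions,
    initial_estimates,
    joint_neg2ll,
    likelihood_ratio_test,
    marginal_neg2ll,
)
from tgikit.generate import TrialDesign, generate_cohort
from tgikit.model import (
    DosingHistory,
    ModelVariant,
    Observation,
    PatientRecord,
    PopulationParams,
    individual_from_population,
    solve_trajectory,
)

M1, M2 = ModelVariant.MODEL1, ModelVariant.MODEL2
LOG_2PI = math.log(2 * math.pi)


def make_placebo_cohort(n=25, seed=42, omega_r=0.0035, sigma=1.1):
    """Placebo-only patients: trajectories linear in the growth random
    effect, so the marginal likelihood has an exact closed form."""
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        y0 = 14.4 * math.exp(0.5 * rng.standard_normal())
        times = np.arange(0.0, 56.0 * rng.integers(2, 8), 56.0)
        eta_r = omega_r * rng.standard_normal()
        obs = [Observation(0.0, y0)] + [
            Observation(t, y0 + (0.046 + eta_r) * t + sigma * rng.standard_normal())
            for t in times[1:]
        ]
        patients.append(
            PatientRecord(f"p{i}", y0, DosingHistory.constant(0, times[-1] + 1), obs)
        )
    return patients


def linear_mixed_model_neg2ll(pop, patients):
    """Closed-form -2 log marginal likelihood for placebo-only data:
    y ~ N(y0 + r*t, sigma^2 I + omega_r^2 t t')."""
    total = 0.0
    for p in patients:
        t = np.array([o.time for o in p.post_baseline])
        y = np.array([o.sld for o in p.post_baseline])
        m = p.baseline_sld + pop.r * (p.baseline_sld / pop.y0_ref) ** pop.theta1 * t
        V = pop.sigma**2 * np.eye(len(t)) + pop.omega_r**2 * np.outer(t, t)
        r = y - m
        _, logdet = np.linalg.slogdet(V)
        total += len(t) * LOG_2PI + logdet + r @ np.linalg.solve(V, r)
    return total


@pytest.fixture(scope="module")
def placebo_cohort():
    return make_placebo_cohort()


@pytest.fixture(scope="module")
def placebo_pop():
    return PopulationParams(r=0.046, e10=0.0, e5=0.0, omega_r=0.0035, sigma=1.1)


class TestJointNeg2ll:
    def test_zero_residual_case(self, truth):
        # one observation exactly on the typical trajectory, no random
        # effect variance: joint -2ll is the bare Gaussian normalization
        pop = truth.with_(omega_r=0.0, omega_e10=0.0, omega_e5=0.0)
        ind = individual_from_population(pop, 14.4)
        y56 = solve_trajectory(ind, M2, DosingHistory.constant(10, 100), 14.4, [56.0])[0]
        patient = PatientRecord(
            "a", 14.4, DosingHistory.constant(10, 100),
            [Observation(0.0, 14.4), Observation(56.0, y56)],
        )
        g = joint_neg2ll(pop, patient, M2, (0.0, 0.0, 0.0))
        assert g == pytest.approx(math.log(2 * math.pi * pop.sigma**2), abs=1e-10)

    def test_eta_prior_terms_added_per_active_effect(self, truth):
        patient = PatientRecord(
            "a", 14.4, DosingHistory.constant(0, 100),
            [Observation(0.0, 14.4), Observation(56.0, 14.4 + 0.046 * 56)],
        )
        g0 = joint_neg2ll(truth.with_(omega_e10=0.0, omega_e5=0.0), patient, M2)
        g1 = joint_neg2ll(truth.with_(omega_e5=0.0), patient, M2)
        assert g1 - g0 == pytest.approx(
            math.log(2 * math.pi * truth.omega_e10**2), abs=1e-10
        )

    def test_sigma_zero_rejected(self, truth, placebo_cohort):
        with pytest.raises(ValueError, match="sigma"):
            joint_neg2ll(truth.with_(sigma=0.0), placebo_cohort[0], M2)


class TestMarginalObjective:
    def test_equals_linear_mixed_model_closed_form(
        self, placebo_cohort, placebo_pop
    ):
        """FOCE is exact when the model is linear in eta."""
        ofv = marginal_neg2ll(placebo_pop, placebo_cohort, M2)
        oracle = linear_mixed_model_neg2ll(placebo_pop, placebo_cohort)
        assert abs(ofv - oracle) / abs(oracle) < 1e-6

    def test_zero_omega_collapses_to_fixed_effects(
        self, placebo_cohort, placebo_pop
    ):
        pop = placebo_pop.with_(omega_r=0.0)
        ofv = marginal_neg2ll(pop, placebo_cohort, M2)
        direct = sum(joint_neg2ll(pop, p, M2) for p in placebo_cohort)
        assert ofv == pytest.approx(direct, abs=1e-9)

    def test_additive_over_patients(self, truth, small_cohort):
        pats = small_cohort.analysis_patients()[:4]
        twice = [
            PatientRecord(
                p.id + sfx, p.baseline_sld, p.dosing, p.observations,
                p.covariates, p.arm,
            )
            for sfx in ("_a", "_b")
            for p in pats
        ]
        one = marginal_neg2ll(truth, pats, M2)
        two = marginal_neg2ll(truth, twice, M2)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_deterministic(self, truth, small_cohort):
        pats = small_cohort.analysis_patients()
        a = marginal_neg2ll(truth, pats, M2)
        b = marginal_neg2ll(truth, pats, M2)
        assert a == b

    def test_engine_predictions_match_reference_solver(self, small_cohort):
        """Vectorized affine predictor vs the scalar trajectory solver."""
        pats = small_cohort.analysis_patients()
        eng = TrajectoryEngine(pats)
        rng = np.random.default_rng(0)
        r = 0.046 + 0.01 * rng.standard_normal(eng.n_pat)
        e10 = 0.0039 + 0.001 * rng.standard_normal(eng.n_pat)
        e5 = 0.0023 + 0.001 * rng.standard_normal(eng.n_pat)
        pred = eng.predict(r, e10, e5)
        k = 0
        for i, p in enumerate(pats):
            ind = individual_from_population(
                PopulationParams(r=r[i], e10=e10[i], e5=e5[i], sigma=1.0),
                p.baseline_sld,
            )
            times = [o.time for o in p.post_baseline]
            ref = solve_trajectory(
                ind, M2, p.dosing.extended(times[-1]), p.baseline_sld, times
            )
            for v in ref:
                assert pred[k] == pytest.approx(v, abs=1e-10)
                k += 1
        assert k == eng.n_obs


class TestFit:
    def test_noiseless_recovery_with_fixed_variances(self, truth):
        """With variability switched off in the generator, fixed effects are
        recovered essentially exactly."""
        quiet = truth.with_(
            omega_r=0.0, omega_e10=0.0, omega_e5=0.0, sigma=0.02
        )
        design = TrialDesign(
            n_total=40, n_active=27, progression_stopping=False,
            missing_baseline_prob=0.0, reduction_susceptible_prob=0.5,
        )
        cohort = generate_cohort(design, quiet, seed=9)
        result = fit(
            cohort.analysis_patients(),
            fixed={"omega_r": 0.0, "omega_e10": 0.0, "omega_e5": 0.0},
            compute_se=False,
        )
        assert result.params.r == pytest.approx(truth.r, rel=5e-3)
        assert result.params.e10 == pytest.approx(truth.e10, rel=2e-2)
        assert result.params.e5 == pytest.approx(truth.e5, rel=5e-2)
        assert result.params.theta1 == pytest.approx(truth.theta1, abs=0.05)
        assert result.params.theta2 == pytest.approx(truth.theta2, abs=0.1)
        assert result.params.sigma == pytest.approx(0.02, rel=0.3)

    def test_nested_model_never_beats_superset(self, model1_fit, model2_fit):
        assert model1_fit.ofv >= model2_fit.ofv - 1e-4

    def test_standard_errors_scale_with_information(self, truth):
        """Quadrupling the cohort roughly halves the standard errors."""
        design = TrialDesign(n_total=40, n_active=27, missing_baseline_prob=0.0)
        cohort = generate_cohort(design, truth, seed=11)
        pats = cohort.analysis_patients()
        big = [
            PatientRecord(
                f"{p.id}_{k}", p.baseline_sld, p.dosing, p.observations,
                p.covariates, p.arm,
            )
            for k in range(4)
            for p in pats
        ]
        f_small = fit(pats, compute_se=True)
        f_big = fit(big, init=f_small.params, compute_se=True)
        for name in ("r", "e10"):
            ratio = f_small.se(name) / f_big.se(name)
            assert ratio == pytest.approx(2.0, rel=0.3)

    def test_no_post_baseline_patients_rejected(self):
        p = PatientRecord(
            "only_baseline", 14.4, DosingHistory.constant(0, 10),
            [Observation(0.0, 14.4)],
        )
        with pytest.raises(ValueError):
            fit([p])

    def test_dropped_patient_count_recorded(self, small_cohort):
        pats = list(small_cohort.analysis_patients())
        pats.append(
            PatientRecord(
                "nofollowup", 14.4, DosingHistory.constant(0, 10),
                [Observation(0.0, 14.4)],
            )
        )
        result = fit(pats, compute_se=False, maxiter=5)
        assert result.n_dropped == 1
        assert result.n_patients == len(pats) - 1

    def test_initial_estimates_plausible(self, analysis_patients):
        init = initial_estimates(analysis_patients)
        assert 0.01 < init.r < 0.15
        assert 0.0005 < init.e10 < 0.02
        assert init.sigma > 0


class TestShrinkage:
    def _stub(self, ebes, omega_e5=1.0):
        params = PopulationParams(
            r=0.046, e10=0.0039, e5=0.0023,
            omega_r=1.0, omega_e10=1.0, omega_e5=omega_e5, sigma=1.0,
        )
        return FitResult(
            variant=M2, terms=(), params=params, ofv=0.0, n_params=0, ebes=ebes,
        )

    def test_definition(self):
        rng = np.random.default_rng(0)
        n = 4001
        ebes = np.zeros((n, 3))
        ebes[:, 0] = rng.standard_normal(n) * 0.79
        shr = eta_shrinkage(self._stub(ebes))
        assert shr["eta_r"] == pytest.approx(0.21, abs=0.02)

    def test_all_zero_ebes_means_total_shrinkage(self):
        shr = eta_shrinkage(self._stub(np.zeros((10, 3))))
        assert shr["eta_e10"] == pytest.approx(1.0)

    def test_zero_omega_undefined(self):
        shr = eta_shrinkage(self._stub(np.zeros((10, 3)), omega_e5=0.0))
        assert math.isnan(shr["eta_e5"])


class TestLikelihoodRatioTest:
    def _fit_stub(self, ofv, n_params):
        params = PopulationParams(r=0.046, e10=0.0039, e5=0.0023, sigma=1.0)
        return FitResult(
            variant=M2, terms=(), params=params, ofv=ofv, n_params=n_params
        )

    def test_chi_square_tail(self):
        res = likelihood_ratio_test(self._fit_stub(110.0, 5), self._fit_stub(100.0, 7))
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-5.0), rel=1e-9)

    def test_zero_delta_gives_p_one(self):
        res = likelihood_ratio_test(self._fit_stub(100.0, 5), self._fit_stub(100.0, 6))
        assert res.p == 1.0

    def test_negative_delta_flags_failure(self):
        res = likelihood_ratio_test(self._fit_stub(99.0, 5), self._fit_stub(100.0, 6))
        assert not res.ok

    def test_non_nested_direction_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(self._fit_stub(100.0, 7), self._fit_stub(90.0, 5))


class TestIndividualPredictions:
    def test_matches_cohort(self, model2_fit, analysis_patients):
        pred = individual_predictions(model2_fit, analysis_patients)
        n_obs = sum(len(p.post_baseline) for p in analysis_patients)
        assert pred.shape == (n_obs,)
        assert np.all(np.isfinite(pred))

    def test_mismatched_cohort_rejected(self, model2_fit, small_cohort):
        with pytest.raises(ValueError, match="match"):
            individual_predictions(model2_fit, small_cohort.analysis_patients())
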