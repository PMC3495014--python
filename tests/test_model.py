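"""Core model: dose-effect map, covariate structure, exact trajectories,
percent change and the RECIST progression rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tgikit.model import (
    DOSE_LEVELS,
    CovariateEffect,
    DosingHistory,
    IndividualParams,
    ModelVariant,
    Observation,
    PatientRecord,
    PopulationParams,
    effect_for_dose,
    individual_from_population,
    percent_change,
    recist_progression,
    reference_estimates,
    solve_trajectory,
)

M1, M2 = ModelVariant.MODEL1, ModelVariant.MODEL2


def ode_trajectory(indiv, variant, dosing, y0, times):
    """Independent oracle: adaptive integration restarted at dose switches."""
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    y = float(y0)
    done = 0
    for seg in dosing.intervals:
        eff = effect_for_dose(variant, indiv, seg.dose)
        t_eval = [t for t in times[done:] if t <= seg.end]
        if t_eval:
            sol = solve_ivp(
                lambda t, yy: [indiv.r - eff * yy[0]],
                (seg.start, seg.end),
                [y],
                t_eval=t_eval,
                method="DOP853",
                rtol=1e-12,
                atol=1e-13,
            )
            out[done : done + len(t_eval)] = sol.y[0]
            done += len(t_eval)
        y = solve_ivp(
            lambda t, yy: [indiv.r - eff * yy[0]],
            (seg.start, seg.end),
            [y],
            method="DOP853",
            rtol=1e-12,
            atol=1e-13,
        ).y[0][-1]
        if done == len(times):
            break
    return out


class TestDoseEffectMap:
    @pytest.mark.parametrize(
        "variant,dose,expected",
        [
            (M2, 10.0, 0.0039),
            (M2, 5.0, 0.0023),
            (M2, 0.0, 0.0),
            (M1, 10.0, 0.0039),
            (M1, 5.0, 0.0039),  # model 1 ties the two doses
            (M1, 0.0, 0.0),
        ],
    )
    def test_lookup(self, variant, dose, expected):
        indiv = IndividualParams(r=0.046, e10=0.0039, e5=0.0023)
        assert effect_for_dose(variant, indiv, dose) == pytest.approx(expected)

    def test_unknown_dose_rejected(self):
        indiv = IndividualParams(r=0.046, e10=0.0039, e5=0.0023)
        with pytest.raises(ValueError, match="dose"):
            effect_for_dose(M2, indiv, 7.5)


class TestIndividualFromPopulation:
    def test_reference_patient_gets_population_values(self, truth):
        ind = individual_from_population(truth, 14.4)
        assert ind.r == pytest.approx(0.0460)
        assert ind.e10 == pytest.approx(0.0039)
        assert ind.e5 == pytest.approx(0.0023)

    def test_baseline_power_laws(self, truth):
        # doubling baseline SLD scales r by 2^theta1 and effects by 2^theta2
        ind = individual_from_population(truth, 28.8)
        assert ind.r == pytest.approx(0.046 * 2**0.4, rel=1e-12)
        assert ind.e10 == pytest.approx(0.0039 * 2**-0.7, rel=1e-12)
        assert ind.e5 == pytest.approx(0.0023 * 2**-0.7, rel=1e-12)
        # theta2 is shared by both drug effects
        assert ind.e5 / ind.e10 == pytest.approx(0.0023 / 0.0039, rel=1e-12)

    def test_additive_random_effects_at_reference(self, truth):
        eta = (0.01, -0.002, 0.0005)
        ind = individual_from_population(truth, truth.y0_ref, eta=eta)
        assert ind.r == pytest.approx(truth.r + eta[0])
        assert ind.e10 == pytest.approx(truth.e10 + eta[1])
        assert ind.e5 == pytest.approx(truth.e5 + eta[2])

    def test_binary_covariate_multiplier(self):
        pop = PopulationParams(
            r=0.04,
            e10=0.004,
            e5=0.002,
            sigma=1.0,
            extra=(CovariateEffect("prior_sunitinib", "growth", "binary", theta=1.5),),
        )
        with_flag = individual_from_population(pop, 14.4, {"prior_sunitinib": 1})
        without = individual_from_population(pop, 14.4, {"prior_sunitinib": 0})
        assert with_flag.r == pytest.approx(1.5 * without.r)
        assert with_flag.e10 == pytest.approx(without.e10)

    def test_nonpositive_baseline_rejected(self, truth):
        with pytest.raises(ValueError):
            individual_from_population(truth, 0.0)

    def test_missing_covariate_rejected(self):
        pop = PopulationParams(
            r=0.04, e10=0.004, e5=0.002, sigma=1.0,
            extra=(CovariateEffect("hemoglobin", "growth", "continuous", 12.5, 0.3),),
        )
        with pytest.raises(ValueError, match="hemoglobin"):
            individual_from_population(pop, 14.4, {})


class TestTrajectory:
    def test_typical_patient_spot_values(self, truth):
        """Closed-form one-year SLD for the typical patient under constant
        dosing: shrinks at 10 mg, grows at 5 mg, grows linearly on placebo."""
        ind = individual_from_population(truth, 14.4)
        for dose, expected in ((10.0, 12.42), (5.0, 17.58), (0.0, 31.19)):
            y = solve_trajectory(
                ind, M2, DosingHistory.constant(dose, 366.0), 14.4, [365.0]
            )[0]
            assert y == pytest.approx(expected, abs=5e-3)

    def test_placebo_growth_is_linear(self, truth):
        ind = individual_from_population(truth, 14.4)
        t = np.array([0.0, 100.0, 365.0])
        y = solve_trajectory(ind, M2, DosingHistory.constant(0, 366.0), 14.4, t)
        assert np.allclose(y, 14.4 + 0.046 * t, rtol=1e-12)

    def test_continuity_across_dose_switch(self, truth):
        ind = individual_from_population(truth, 14.4)
        dosing = DosingHistory.from_changes([(0, 10), (100, 0)], 200)
        eps = 1e-9
        left, right = solve_trajectory(
            ind, M2, dosing, 14.4, [100.0 - eps, 100.0 + eps]
        )
        assert abs(left - right) < 1e-8

    def test_linear_branch_continuity_in_effect(self, truth):
        # the |E| < 1e-12 linear branch must join the exponential branch
        dosing = DosingHistory.constant(10, 400)
        y_lin = solve_trajectory(
            IndividualParams(r=0.046, e10=1e-13, e5=0.0), M2, dosing, 14.4, [365.0]
        )[0]
        y_exp = solve_trajectory(
            IndividualParams(r=0.046, e10=1e-10, e5=0.0), M2, dosing, 14.4, [365.0]
        )[0]
        assert y_lin == pytest.approx(y_exp, abs=1e-6)

    def test_negative_effect_grows_exponentially(self):
        # signed random effects can make E < 0; the solution stays valid
        ind = IndividualParams(r=0.0, e10=-0.005, e5=0.0)
        y = solve_trajectory(
            ind, M2, DosingHistory.constant(10, 201), 10.0, [200.0]
        )[0]
        assert y == pytest.approx(10.0 * math.exp(0.005 * 200), rel=1e-10)

    def test_monotone_approach_to_asymptote(self, truth):
        ind = individual_from_population(truth, 14.4)
        t = np.linspace(0, 700, 200)
        y = solve_trajectory(ind, M2, DosingHistory.constant(10, 701), 14.4, t)
        asym = ind.r / ind.e10
        assert np.all(np.diff(y) < 0)  # shrinking toward r/E from above
        assert np.all(y > asym)

    @pytest.mark.parametrize(
        "times,err",
        [([-1.0, 5.0], "sorted"), ([5.0, 1.0], "sorted"), ([500.0], "coverage")],
    )
    def test_invalid_times_rejected(self, truth, times, err):
        ind = individual_from_population(truth, 14.4)
        with pytest.raises(ValueError, match=err):
            solve_trajectory(ind, M2, DosingHistory.constant(10, 400), 14.4, times)

    @given(
        seed=st.integers(0, 10_000),
        n_switch=st.integers(0, 4),
        y0=st.floats(2.0, 40.0),
    )
    @settings(max_examples=20)
    def test_matches_adaptive_ode_integration(self, seed, n_switch, y0):
        """Analytic piecewise solution vs adaptive integration, randomized
        regimens and signed individual effects, to 1e-8 cm."""
        rng = np.random.default_rng(seed)
        days = np.sort(rng.uniform(10, 390, size=n_switch))
        changes = [(0.0, float(rng.choice(DOSE_LEVELS)))] + [
            (float(d), float(rng.choice(DOSE_LEVELS))) for d in days
        ]
        dosing = DosingHistory.from_changes(changes, 400.0)
        ind = IndividualParams(
            r=rng.normal(0.046, 0.02),
            e10=rng.normal(0.0039, 0.002),
            e5=rng.normal(0.0023, 0.002),
        )
        times = np.sort(rng.uniform(0, 400, size=25))
        ana = solve_trajectory(ind, M2, dosing, y0, times)
        num = ode_trajectory(ind, M2, dosing, y0, times)
        assert np.max(np.abs(ana - num)) < 1e-8


class TestPercentChange:
    @pytest.mark.parametrize(
        "sld,base,expected",
        [(12.42, 14.4, -13.75), (14.4, 14.4, 0.0), (28.8, 14.4, 100.0)],
    )
    def test_examples(self, sld, base, expected):
        assert percent_change(sld, base) == pytest.approx(expected, abs=0.02)

    @given(
        sld=st.floats(0.1, 100), base=st.floats(0.1, 100), c=st.floats(0.01, 50)
    )
    def test_scale_invariance(self, sld, base, c):
        assert percent_change(c * sld, c * base) == pytest.approx(
            percent_change(sld, base), rel=1e-9, abs=1e-9
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(10.0, 0.0)


class TestRecistProgression:
    def test_nadir_rule(self):
        # nadir is the running minimum including baseline
        obs = [(0, 10.0), (56, 9.0), (112, 10.8)]
        assert recist_progression(obs) == 112  # 10.8 >= 1.2 * 9.0

    def test_exact_twenty_percent_counts(self):
        assert recist_progression([(0, 10.0), (56, 12.0)]) == 56

    def test_no_progression(self):
        assert recist_progression([(0, 10.0), (56, 10.5), (112, 11.0)]) is None

    def test_new_lesion_event_can_come_first(self):
        obs = [(0, 10.0), (56, 9.0), (112, 10.8)]
        assert recist_progression(obs, new_lesion_times=[60.0]) == 60.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            recist_progression([])


class TestDosingHistory:
    def test_validation(self):
        with pytest.raises(ValueError, match="day 0"):
            DosingHistory([(5.0, 10.0, 10.0)])
        with pytest.raises(ValueError, match="contiguous"):
            DosingHistory([(0.0, 5.0, 10.0), (6.0, 10.0, 5.0)])
        with pytest.raises(ValueError, match="dose"):
            DosingHistory([(0.0, 5.0, 7.0)])

    def test_from_changes_collapses_repeats(self):
        d = DosingHistory.from_changes([(0, 10), (50, 10), (100, 5)], 200)
        assert len(d.intervals) == 2
        assert d.dose_at(99.9) == 10
        assert d.dose_at(100.0) == 5

    def test_segments_cover_interval(self):
        d = DosingHistory.from_changes([(0, 10), (100, 0)], 200)
        segs = d.segments(150.0)
        assert segs == [(100.0, 10.0), (50.0, 0.0)]
        assert sum(dur for dur, _ in segs) == pytest.approx(150.0)


class TestPatientRecord:
    def test_observation_ordering_enforced(self):
        with pytest.raises(ValueError, match="sorted"):
            PatientRecord(
                "x",
                10.0,
                DosingHistory.constant(0, 100),
                [Observation(56.0, 11.0), Observation(0.0, 10.0)],
            )

    def test_positive_baseline_enforced(self):
        with pytest.raises(ValueError):
            PatientRecord("x", -1.0, DosingHistory.constant(0, 100), [])
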