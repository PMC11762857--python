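"""Microsimulation engine tests: cycle mechanics, determinism, the
scalar/vectorised path identity and binomial sanity checks."""

import numpy as np
import pandas as pd
import pytest

import ascvdsim as a
from ascvdsim.engine import run_individual, run_strategy
from ascvdsim.errors import DomainError, StateError
from ascvdsim.population import profile_from_row
from ascvdsim.strategies import StrategyDefinition

from conftest import constant_hazard_params, uniform_cohort

NO_TREAT = StrategyDefinition("no-treatment", None)


class TestRunCycle:
    def test_null_dynamics(self, profile):
        params = constant_hazard_params(p10=0.0, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        rng = np.random.default_rng(0)
        out, rec = a.run_cycle(profile, NO_TREAT, params, rng)
        assert rec.event is None
        assert out.age == profile.age + 1
        assert out.alive
        assert rec.cost == 0.0

    def test_forced_fatal_event(self, profile):
        params = constant_hazard_params(p10=1.0, fatality_chd=1.0, fatality_stroke=1.0,
                                        q_background=0.0)
        rng = np.random.default_rng(0)
        out, rec = a.run_cycle(profile, NO_TREAT, params, rng)
        assert not out.alive
        assert rec.event.endswith("fatal")
        assert rec.utility == 0.0
        # fatal-event cycle accrues hospitalisation only
        assert rec.cost in (params.costs.hospitalization_ami, params.costs.hospitalization_stroke)

    def test_dead_profile_rejected(self, profile):
        profile.health_state = "dead"
        params = constant_hazard_params(p10=0.0, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        with pytest.raises(StateError):
            a.run_cycle(profile, NO_TREAT, params, np.random.default_rng(0))

    def test_constant_hazard_event_rate(self):
        # ~binomial check: one cycle for a large uniform cohort
        p10 = 0.2
        params = constant_hazard_params(p10=p10, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        p1 = a.deale_annual_probability(p10)
        n = 200_000
        res = run_strategy(uniform_cohort(n), NO_TREAT, params, seed=17, max_cycles=1)
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(res.cvd_events_per_person - p1) < 3 * se


class TestRunIndividual:
    def test_age_cap_gives_single_cycle(self):
        params = constant_hazard_params(p10=0.0, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        prof = profile_from_row(next(uniform_cohort(1, age=89).itertuples(index=False)))
        res = run_individual(prof, NO_TREAT, params, seed=1, keep_records=True)
        assert len(res.records) == 1
        assert res.life_years == 1.0

    def test_immortal_until_cap(self):
        params = constant_hazard_params(p10=0.0, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        prof = profile_from_row(next(uniform_cohort(1, age=60).itertuples(index=False)))
        res = run_individual(prof, NO_TREAT, params, seed=1)
        assert res.life_years == 89 - 60 + 1
        assert res.chd_events == 0 and res.stroke_events == 0

    def test_deterministic_given_seed(self, default_params, small_cohort):
        prof = profile_from_row(next(small_cohort.itertuples(index=False)))
        strat = a.preset_strategies()[2]
        r1 = run_individual(prof, strat, default_params, seed=33, keep_records=True)
        r2 = run_individual(prof, strat, default_params, seed=33, keep_records=True)
        assert r1 == r2

    def test_scalar_and_vectorised_paths_identical(self, default_params, small_cohort):
        """An n=1 cohort through the vectorised engine reproduces run_individual."""
        strat = a.preset_strategies()[3]
        for i in range(12):
            row = small_cohort.iloc[[i]].reset_index(drop=True)
            vec = run_strategy(row, strat, default_params, seed=500 + i, keep_individual=True)
            ind = vec.individual.iloc[0]
            scalar = run_individual(profile_from_row(next(row.itertuples(index=False))),
                                    strat, default_params, seed=500 + i)
            assert ind.discounted_cost == pytest.approx(scalar.discounted_cost, abs=1e-9)
            assert ind.discounted_qaly == pytest.approx(scalar.discounted_qaly, abs=1e-12)
            assert ind.life_years == scalar.life_years
            assert ind.chd_events == scalar.chd_events
            assert ind.stroke_events == scalar.stroke_events
            assert ind.final_treatment_state == scalar.final_treatment_state
            assert bool(ind.statin_induced_diabetes) == scalar.statin_induced_diabetes


class TestRunStrategy:
    def test_empty_cohort_rejected(self, default_params):
        with pytest.raises(DomainError):
            run_strategy(uniform_cohort(0), NO_TREAT, default_params, seed=1)

    def test_no_treatment_has_zero_eligibility_and_no_statin_cost(self):
        params = constant_hazard_params(p10=0.0, fatality_chd=0.0, fatality_stroke=0.0,
                                        q_background=0.0)
        res = run_strategy(uniform_cohort(100), NO_TREAT, params, seed=1)
        assert res.eligible_fraction == 0.0
        assert res.mean_cost == 0.0

    def test_identical_thresholds_identical_results_under_crn(self, default_params, small_cohort):
        s1 = StrategyDefinition("a", 0.10)
        s2 = StrategyDefinition("b", 0.10)
        r1 = run_strategy(small_cohort, s1, default_params, seed=9)
        r2 = run_strategy(small_cohort, s2, default_params, seed=9)
        assert r1.mean_cost == r2.mean_cost
        assert r1.mean_qaly == r2.mean_qaly
        assert r1.cvd_events_per_person == r2.cvd_events_per_person

    def test_neutral_odds_ratios_make_arms_indistinguishable(self, small_cohort):
        from dataclasses import replace
        params = a.default_parameter_set()
        neutral_ev = replace(params.events, or_chd=1.0, or_stroke=1.0, or_diabetes=1.0)
        params = replace(params, events=neutral_ev)
        treated = run_strategy(small_cohort, StrategyDefinition("t", 0.075), params, seed=4)
        untreated = run_strategy(small_cohort, NO_TREAT, params, seed=4)
        # under CRN and OR=1 the event histories coincide exactly
        assert treated.cvd_events_per_person == untreated.cvd_events_per_person
        assert treated.mean_life_years == untreated.mean_life_years

    def test_post_event_mortality_multiplier_shortens_life(self):
        base = dict(p10=0.3, fatality_chd=0.0, fatality_stroke=0.0, q_background=0.02)
        lo = constant_hazard_params(**base, post_event_multiplier=1.0)
        hi = constant_hazard_params(**base, post_event_multiplier=3.0)
        cohort = uniform_cohort(20_000)
        r_lo = run_strategy(cohort, NO_TREAT, lo, seed=6)
        r_hi = run_strategy(cohort, NO_TREAT, hi, seed=6)
        assert r_hi.mean_life_years < r_lo.mean_life_years

    def test_statin_induced_diabetes_does_not_change_event_histories(self, small_cohort):
        """The diabetes side effect must touch only costs and utilities."""
        from dataclasses import replace
        params = a.default_parameter_set()
        strat = StrategyDefinition("t", 0.075)
        base = run_strategy(small_cohort, strat, params, seed=21)
        # crank the statin diabetes OR: event counts and survival must not move
        worse = replace(params, events=replace(params.events, or_diabetes=5.0))
        res = run_strategy(small_cohort, strat, worse, seed=21)
        assert res.cvd_events_per_person == base.cvd_events_per_person
        assert res.mean_life_years == base.mean_life_years
        assert res.statin_diabetes_per_person >= base.statin_diabetes_per_person

    def test_threshold_direction_on_small_cohort(self, default_params):
        cohort = a.generate_cohort(4000, a.default_population_config(), seed=77)
        results = [run_strategy(cohort, s, default_params, seed=55)
                   for s in a.preset_strategies()]
        elig = [r.eligible_fraction for r in results]
        events = [r.cvd_events_per_person for r in results]
        assert elig[0] == 0.0
        assert elig[1] <= elig[2] <= elig[3]
        assert events[0] >= events[1] >= events[2] >= events[3]
        diab = [r.statin_diabetes_per_person for r in results]
        assert diab[0] == 0.0
        assert diab[1] <= diab[2] <= diab[3]
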