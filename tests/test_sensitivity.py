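"""PSA distributions, one-way DSA and validation-procedure tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ascvdsim as a
from ascvdsim.errors import ConfigurationError, DomainError
from ascvdsim.sensitivity import (DistributionSpec, apply_draw, default_dsa_ranges,
                                  default_psa_specs, one_way_dsa, run_psa,
                                  sample_parameters)
from ascvdsim.strategies import StrategyDefinition

from conftest import constant_hazard_params, uniform_cohort


class TestDistributionSpec:
    def test_fixed_passthrough(self):
        spec = DistributionSpec("fixed", 0.03)
        rng = np.random.default_rng(1)
        assert np.all(spec.sample(rng, size=100) == 0.03)

    @pytest.mark.parametrize("family, value, se", [
        ("beta", 0.439, 0.018),
        ("beta", 0.107, 0.019),
        ("gamma", 1_149.75, 100.0),
        ("lognormal", 0.70, 0.072),
        ("lognormal", 0.81, 0.069),
    ])
    def test_moment_recovery(self, family, value, se):
        rng = np.random.default_rng(42)
        x = DistributionSpec(family, value, se).sample(rng, size=100_000)
        se_mean = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - value) < 3 * se_mean
        assert abs(x.std(ddof=1) - se) / se < 0.05

    def test_missing_se_falls_back_to_fixed_with_warning(self):
        spec = DistributionSpec("gamma", 100.0, None)
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="fixed"):
            x = spec.sample(rng, size=10)
        assert np.all(x == 100.0)

    def test_dsa_bounds(self):
        # printed SE -> value +/- 1.96 SE; none -> +/- 20%
        lo, hi = DistributionSpec("lognormal", 0.70, 0.072).dsa_bounds()
        assert lo == pytest.approx(0.70 - 1.96 * 0.072)
        assert hi == pytest.approx(0.70 + 1.96 * 0.072)
        lo, hi = DistributionSpec("gamma", 1_000.0, None).dsa_bounds()
        assert (lo, hi) == (800.0, 1_200.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            DistributionSpec("triangular", 1.0)


class TestSampleParameters:
    def test_deterministic_given_seed(self):
        specs = default_psa_specs()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = sample_parameters(specs, seed=5)
            d2 = sample_parameters(specs, seed=5)
        assert d1 == d2

    def test_apply_draw_round_trip(self, default_params):
        out = apply_draw(default_params, {"events.or_chd": 0.5, "costs.statin_annual": 999.0})
        assert out.events.or_chd == 0.5
        assert out.costs.statin_annual == 999.0
        # original untouched (frozen dataclasses)
        assert default_params.events.or_chd == 0.70

    def test_unknown_path_rejected(self, default_params):
        with pytest.raises(ConfigurationError, match="no.such"):
            apply_draw(default_params, {"no.such": 1.0})


class TestRunPsa:
    def setup_small(self):
        params = constant_hazard_params(p10=0.15, fatality_chd=0.2, fatality_stroke=0.2,
                                        q_background=0.01)
        cohort = uniform_cohort(300)
        strategies = [StrategyDefinition("none", None),
                      StrategyDefinition("treat", 0.10)]
        return cohort, strategies, params

    def test_all_fixed_specs_reproduce_base_case(self):
        cohort, strategies, params = self.setup_small()
        specs = {"events.or_chd": DistributionSpec("fixed", 0.70)}
        psa = run_psa(cohort, strategies, specs, params, n_draws=2, seed=3)
        base = [a.run_strategy(cohort, s, params, seed=psa.sim_seed) for s in strategies]
        for j in range(2):
            assert psa.costs[0, j] == psa.costs[1, j]
            assert psa.costs[0, j] == pytest.approx(base[j].mean_cost)
            assert psa.qalys[0, j] == pytest.approx(base[j].mean_qaly)

    def test_deterministic_given_master_seed(self):
        cohort, strategies, params = self.setup_small()
        specs = {"events.or_chd": DistributionSpec("lognormal", 0.70, 0.072)}
        p1 = run_psa(cohort, strategies, specs, params, n_draws=3, seed=11)
        p2 = run_psa(cohort, strategies, specs, params, n_draws=3, seed=11)
        np.testing.assert_array_equal(p1.costs, p2.costs)
        np.testing.assert_array_equal(p1.qalys, p2.qalys)

    def test_probability_optimal_degenerate(self):
        cohort, strategies, params = self.setup_small()
        specs = {"costs.diabetes_annual": DistributionSpec("fixed", 0.0)}  # inert here
        psa = run_psa(cohort, strategies, specs, params, n_draws=2, seed=1)
        probs = psa.probability_optimal(50_000.0)
        assert set(probs.values()) == {0.0, 1.0}

    def test_draw_count_contract(self):
        cohort, strategies, params = self.setup_small()
        specs = {"events.or_chd": DistributionSpec("lognormal", 0.70, 0.072)}
        psa = run_psa(cohort, strategies, specs, params, n_draws=4, seed=2)
        assert psa.n_draws == 4
        assert len(psa.draws) == 4
        with pytest.raises(DomainError):
            run_psa(cohort, strategies, specs, params, n_draws=0, seed=2)


class TestOneWayDsa:
    def setup_run(self):
        params = constant_hazard_params(p10=0.15, fatality_chd=0.2, fatality_stroke=0.2,
                                        q_background=0.01)
        cohort = uniform_cohort(500)
        strategies = [StrategyDefinition("none", None), StrategyDefinition("treat", 0.10)]
        return cohort, strategies, params

    def test_inert_parameter_zero_width(self):
        cohort, strategies, params = self.setup_run()
        rows = one_way_dsa(cohort, strategies, params,
                           {"costs.diabetes_annual": (0.0, 500.0)}, seed=9, target="treat")
        assert rows[0].width == 0.0

    def test_statin_price_monotone_icer(self):
        cohort, strategies, params = self.setup_run()
        rows = one_way_dsa(cohort, strategies, params,
                           {"costs.statin_annual": (900.0, 1_400.0)}, seed=9, target="treat")
        # statin cost enters only the numerator: ICER strictly increasing
        assert rows[0].icer_low < rows[0].icer_high

    def test_weaker_chd_effect_raises_icer(self):
        cohort, strategies, params = self.setup_run()
        rows = one_way_dsa(cohort, strategies, params,
                           {"events.or_chd": (0.56, 0.95)}, seed=9, target="treat")
        assert rows[0].icer_low < rows[0].icer_high

    def test_tornado_ordering_by_range(self):
        cohort, strategies, params = self.setup_run()
        rows = one_way_dsa(cohort, strategies, params,
                           {"costs.statin_annual": (900.0, 1_400.0),
                            "costs.diabetes_annual": (0.0, 100.0)},
                           seed=9, target="treat")
        assert rows[0].parameter == "costs.statin_annual"
        assert rows[0].width >= rows[-1].width

    def test_bad_range_rejected(self):
        cohort, strategies, params = self.setup_run()
        with pytest.raises(ConfigurationError):
            one_way_dsa(cohort, strategies, params, {"events.or_chd": (0.9, 0.5)}, seed=1)


class TestInternalValidation:
    def test_r_squared_near_one_for_large_cohort(self, default_params):
        cohort = a.generate_cohort(40_000, a.default_population_config(), seed=31)
        r2, table = a.internal_validation(cohort, default_params, seed=31, n_reps=20)
        assert len(table) >= 3
        assert 0.9 < r2 <= 1.0

    def test_closed_form_regression(self):
        # R² computed independently via the normal equations
        from scipy import stats
        x = np.array([0.01, 0.02, 0.03])
        y = np.array([0.012, 0.019, 0.031])
        fit = stats.linregress(x, y)
        ss_res = np.sum((y - (fit.intercept + fit.slope * x)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.rvalue**2 == pytest.approx(1 - ss_res / ss_tot)

    def test_too_few_groups_rejected(self, default_params):
        cohort = uniform_cohort(50, age=60)
        with pytest.raises(DomainError):
            a.internal_validation(cohort, default_params, seed=1)


class TestExternalValidation:
    def test_empty_reference_warns(self):
        sim = pd.DataFrame({"metric": ["life_expectancy"], "value": [74.5]})
        with pytest.warns(UserWarning, match="skipped"):
            report = a.external_validation(sim, None)
        assert report.empty

    def test_self_comparison_zero_deltas(self):
        sim = pd.DataFrame({"metric": ["le", "inc_M_60"], "value": [74.5, 0.012]})
        ref = sim.copy()
        report = a.external_validation(sim, ref)
        assert np.allclose(report["delta"], 0.0)

    def test_doubled_hazard_lowers_life_expectancy(self):
        lo = constant_hazard_params(p10=0.1, fatality_chd=0.3, fatality_stroke=0.3,
                                    q_background=0.01)
        hi = constant_hazard_params(p10=0.1, fatality_chd=0.3, fatality_stroke=0.3,
                                    q_background=0.02)
        cohort = uniform_cohort(5_000)
        strat = StrategyDefinition("none", None)
        r_lo = a.run_strategy(cohort, strat, lo, seed=2)
        r_hi = a.run_strategy(cohort, strat, hi, seed=2)
        assert r_hi.mean_life_years < r_lo.mean_life_years
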