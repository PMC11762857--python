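"""Cost/utility accrual, discounting, ICER ladder and CEAC tests.

The frontier algorithm is checked against an independent oracle: a strategy
is cost-effective for *some* willingness-to-pay iff it maximises net monetary
benefit at some λ ≥ 0, so sweeping the candidate λ set (all pairwise slopes)
enumerates the frontier without any dominance logic.
"""

import numpy as np
import pytest

import ascvdsim as a
from ascvdsim.economics import (DOMINATED, EXT_DOMINATED, ON_FRONTIER, FrontierEntry,
                                accrue_cycle_cost, accrue_cycle_utility, ceac, discount,
                                icer_ladder)
from ascvdsim.errors import ConfigurationError, DomainError
from ascvdsim.risk import CHD, STROKE


def nmb_sweep_frontier(points):
    """Independent frontier oracle: union of NMB maximisers over WTP >= 0.

    NMB is linear in the WTP, so argmax regions are intervals whose endpoints
    are pairwise crossing points; evaluating at the midpoints between
    consecutive candidates (plus 0 and beyond the largest) finds every
    strategy that is uniquely optimal somewhere.
    """
    names = [p[0] for p in points]
    costs = np.array([p[1] for p in points])
    qalys = np.array([p[2] for p in points])
    lams = {0.0}
    for i in range(len(points)):
        for j in range(len(points)):
            dq = qalys[i] - qalys[j]
            if dq > 0:
                lam = (costs[i] - costs[j]) / dq
                if lam >= 0:
                    lams.add(lam)
    grid = sorted(lams)
    eval_at = [0.0] + [(x + y) / 2 for x, y in zip(grid, grid[1:])] + [grid[-1] + 1.0]
    frontier = set()
    for lam in eval_at:
        nmb = lam * qalys - costs
        winners = np.flatnonzero(np.isclose(nmb, nmb.max(), rtol=0, atol=1e-9))
        # among NMB ties prefer the cheaper strategy (weak dominance)
        cheapest = winners[np.argmin(costs[winners])]
        frontier.add(names[cheapest])
    return frontier


class TestCostAccrual:
    def test_statin_only_cycle(self, default_params):
        c = accrue_cycle_cost(default_params.costs, on_statin=True, event=None, died=False,
                              post_event=None, years_since_event=None, diabetic=False)
        assert c == 1_149.75

    def test_nonfatal_ami_on_statin(self, default_params):
        c = accrue_cycle_cost(default_params.costs, on_statin=True, event=CHD, died=False,
                              post_event=None, years_since_event=None, diabetic=False)
        assert c == pytest.approx(22_611 + 1_149.75)

    def test_untreated_event_free_costs_nothing(self, default_params):
        c = accrue_cycle_cost(default_params.costs, on_statin=False, event=None, died=False,
                              post_event=None, years_since_event=None, diabetic=False)
        assert c == 0.0

    def test_fatal_event_cycle_hospitalisation_only(self, default_params):
        c = accrue_cycle_cost(default_params.costs, on_statin=True, event=STROKE, died=True,
                              post_event=None, years_since_event=None, diabetic=True)
        assert c == 13_983.0

    def test_post_event_year_costs(self, default_params):
        first = accrue_cycle_cost(default_params.costs, on_statin=False, event=None,
                                  died=False, post_event=CHD, years_since_event=1,
                                  diabetic=False)
        later = accrue_cycle_cost(default_params.costs, on_statin=False, event=None,
                                  died=False, post_event=CHD, years_since_event=4,
                                  diabetic=False)
        assert first == 5_255.85
        assert later == 585.87


class TestUtilityAccrual:
    def test_stroke_event_cycle_floors_at_zero(self, default_params):
        # age weight ~0.9 minus the 0.92 acute stroke decrement
        u = accrue_cycle_utility(default_params.utilities, male=True, age=62, event=STROKE,
                                 died=False, post_event=None, years_since_event=None,
                                 diabetic=False)
        assert u == 0.0

    def test_post_ami_longterm_decrement(self, default_params):
        w = default_params.utilities.age_weights.lookup(True, 62)
        u = accrue_cycle_utility(default_params.utilities, male=True, age=62, event=None,
                                 died=False, post_event=CHD, years_since_event=2,
                                 diabetic=False)
        assert u == pytest.approx(w - 0.107)

    def test_event_free_uses_age_weight(self, default_params):
        w = default_params.utilities.age_weights.lookup(False, 45)
        u = accrue_cycle_utility(default_params.utilities, male=False, age=45, event=None,
                                 died=False, post_event=None, years_since_event=None,
                                 diabetic=False)
        assert u == w

    def test_death_cycle_contributes_zero(self, default_params):
        u = accrue_cycle_utility(default_params.utilities, male=True, age=50, event=CHD,
                                 died=True, post_event=None, years_since_event=None,
                                 diabetic=False)
        assert u == 0.0


class TestDiscount:
    def test_base_year_undiscounted(self):
        assert discount(100.0, 0, 0.03) == 100.0

    def test_one_year(self):
        assert discount(103.0, 1, 0.03) == pytest.approx(100.0)

    def test_zero_rate_identity(self):
        assert discount(57.3, 12, 0.0) == 57.3

    def test_negative_cycle_rejected(self):
        with pytest.raises(DomainError):
            discount(1.0, -1, 0.03)

    def test_totals_nonincreasing_in_rate(self):
        values = np.ones(30)
        totals = [sum(discount(v, t, r) for t, v in enumerate(values))
                  for r in (0.0, 0.015, 0.03, 0.05)]
        assert all(x >= y for x, y in zip(totals, totals[1:]))


class TestIcerLadder:
    def test_single_strategy(self):
        f = icer_ladder([("only", 100.0, 5.0)])
        assert [e.status for e in f.entries] == [ON_FRONTIER]
        assert f.entries[0].icer is None

    def test_hand_computed_ladder(self):
        f = icer_ladder([("A", 0.0, 10.0), ("B", 100.0, 11.0), ("C", 150.0, 11.05)])
        assert all(e.status == ON_FRONTIER for e in f.entries)
        assert f.entries[1].icer == pytest.approx(100.0)
        assert f.entries[2].icer == pytest.approx(1000.0)

    def test_extended_dominance_removal(self):
        f = icer_ladder([("A", 0.0, 10.0), ("B", 100.0, 10.2), ("C", 120.0, 10.5)])
        by_name = {e.name: e for e in f.entries}
        assert by_name["B"].status == EXT_DOMINATED
        assert by_name["C"].icer == pytest.approx(240.0)

    def test_strict_dominance(self):
        f = icer_ladder([("A", 0.0, 10.0), ("B", 50.0, 9.0)])
        by_name = {e.name: e for e in f.entries}
        assert by_name["B"].status == DOMINATED

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            icer_ladder([("A", 0.0, 1.0), ("A", 1.0, 2.0)])

    def test_matches_nmb_sweep_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(1000):
            k = rng.integers(2, 7)
            pts = [(f"s{i}", float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
                   for i in range(k)]
            f = icer_ladder(pts)
            mine = {e.name for e in f.frontier}
            oracle = nmb_sweep_frontier(pts)
            assert mine == oracle, (trial, pts)

    def test_frontier_icers_nondecreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pts = [(f"s{i}", float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
                   for i in range(5)]
            icers = [e.icer for e in icer_ladder(pts).frontier if e.icer is not None]
            assert all(x <= y + 1e-9 for x, y in zip(icers, icers[1:]))

    def test_published_rounded_aggregates_qualitative_frontier(self):
        """From the published rounded (cost, QALY) table: ascending cost must give
        nondecreasing QALYs; no-treatment and the 10% arm sit on the frontier; the
        7.5% arm (same rounded QALY at higher cost) drops off."""
        pts = [("no-treatment", 49_360.91, 12.17), ("threshold-15", 62_236.63, 12.46),
               ("guideline-10", 65_128.64, 12.47), ("threshold-7.5", 66_866.81, 12.47)]
        ordered = sorted(pts, key=lambda p: p[1])
        assert all(x[2] <= y[2] for x, y in zip(ordered, ordered[1:]))
        f = icer_ladder(pts)
        by_name = {e.name: e for e in f.entries}
        assert by_name["no-treatment"].status == ON_FRONTIER
        assert by_name["guideline-10"].status == ON_FRONTIER
        assert by_name["threshold-7.5"].status == DOMINATED


class TestCeac:
    def test_single_strategy_probability_one(self):
        curves = ceac([[10.0]], [[1.0]], ["only"], [0.0, 50_000.0])
        assert (curves["probability"] == 1.0).all()

    def test_step_function_at_breakeven(self):
        # two strategies, no uncertainty: ICER = 100/0.01 = 10,000
        costs = np.tile([0.0, 100.0], (50, 1))
        qalys = np.tile([1.0, 1.01], (50, 1))
        curves = ceac(costs, qalys, ["cheap", "rich"], [5_000.0, 20_000.0])
        below = curves[(curves.wtp == 5_000.0) & (curves.strategy == "cheap")]
        above = curves[(curves.wtp == 20_000.0) & (curves.strategy == "rich")]
        assert below["probability"].item() == 1.0
        assert above["probability"].item() == 1.0

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        costs = rng.uniform(0, 100, size=(40, 3))
        qalys = rng.uniform(0, 10, size=(40, 3))
        curves = ceac(costs, qalys, ["a", "b", "c"], np.linspace(0, 50, 7))
        sums = curves.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(DomainError):
            ceac(np.empty((0, 2)), np.empty((0, 2)), ["a", "b"], [1.0])
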