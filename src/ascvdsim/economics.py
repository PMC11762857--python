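"""Costs, QALYs, discounting and the cost-effectiveness frontier.

Cost accrual follows the healthcare-payer perspective: statin drug costs,
event hospitalisation, first-year post-event care, lifelong annual outpatient
visits, and (optional) annual diabetes management.  Utilities are age-specific
weights minus additive event decrements (acute in the event cycle, long-term
thereafter), floored at zero.  Strategies are ranked on the cost-QALY plane
by the standard ICER ladder with strict and extended dominance, and
probabilistic results are summarised as cost-effectiveness acceptability
curves (CEACs) via net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .risk import CHD, STROKE
from .tables import SexAgeBandTable

__all__ = [
    "CostParameters",
    "UtilityParameters",
    "FrontierEntry",
    "CEFrontier",
    "WTP_1GDP",
    "WTP_3GDP",
    "accrue_cycle_cost",
    "accrue_cycle_utility",
    "discount",
    "discount_factor",
    "icer_ladder",
    "ceac",
    "frontier_report",
]

#: willingness-to-pay anchors: 1x and 3x 2022 Chinese GDP per capita (CN¥/QALY)
WTP_1GDP = 85_700.0
WTP_3GDP = 257_100.0


@dataclass(frozen=True)
class CostParameters:
    """Direct medical costs, 2022 CN¥ unless tagged otherwise."""

    statin_annual: float = 1_149.75
    hospitalization_ami: float = 22_611.0
    hospitalization_stroke: float = 13_983.0
    first_year_ami: float = 5_255.85
    first_year_stroke: float = 2_652.0
    office_visit_ami: float = 585.87
    office_visit_stroke: float = 565.0
    diabetes_annual: float = 0.0
    currency_year: str = "2022 CN¥"

    def __post_init__(self):
        for name in ("statin_annual", "hospitalization_ami", "hospitalization_stroke",
                     "first_year_ami", "first_year_stroke", "office_visit_ami",
                     "office_visit_stroke", "diabetes_annual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost {name} must be >= 0")

    def hospitalization(self, event: str) -> float:
        return self.hospitalization_ami if event == CHD else self.hospitalization_stroke

    def first_year(self, event: str) -> float:
        return self.first_year_ami if event == CHD else self.first_year_stroke

    def office_visit(self, event: str) -> float:
        return self.office_visit_ami if event == CHD else self.office_visit_stroke


@dataclass(frozen=True)
class UtilityParameters:
    """Age-specific utility weights and event disutilities (additive decrements)."""

    age_weights: SexAgeBandTable = None
    acute_chd: float = 0.439
    acute_stroke: float = 0.92
    longterm_ami: float = 0.107
    longterm_stroke: float = 0.266
    diabetes_disutility: float = 0.0
    discount_rate: float = 0.03

    def __post_init__(self):
        for name in ("acute_chd", "acute_stroke", "longterm_ami", "longterm_stroke", "diabetes_disutility"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"disutility {name} must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ConfigurationError("discount rate must be >= 0")

    def acute(self, event: str) -> float:
        return self.acute_chd if event == CHD else self.acute_stroke

    def longterm(self, event: str) -> float:
        return self.longterm_ami if event == CHD else self.longterm_stroke


def accrue_cycle_cost(costs: CostParameters, *, on_statin: bool, event: str | None,
                      died: bool, post_event: str | None, years_since_event: int | None,
                      diabetic: bool) -> float:
    """Undiscounted cost of one annual cycle.

    The event cycle adds hospitalisation; a cycle ending in death accrues
    hospitalisation only (nothing for a background death); survivors accrue
    statin cost while on statin, first-year post-event cost in the first
    post-event year, outpatient-visit cost in later post-event years, and the
    annual diabetes cost while diabetic.
    """
    total = 0.0
    if event is not None:
        total += costs.hospitalization(event)
    if died:
        return total
    if on_statin:
        total += costs.statin_annual
    if post_event is not None and years_since_event is not None and years_since_event >= 1:
        if years_since_event == 1:
            total += costs.first_year(post_event)
        else:
            total += costs.office_visit(post_event)
    if diabetic:
        total += costs.diabetes_annual
    return total


def accrue_cycle_utility(utils: UtilityParameters, *, male: bool, age: float,
                         event: str | None, died: bool, post_event: str | None,
                         years_since_event: int | None, diabetic: bool) -> float:
    """Undiscounted utility of one annual cycle: age weight minus decrements, floored at 0.

    A cycle ending in death contributes no utility.
    """
    if died:
        return 0.0
    u = utils.age_weights.lookup(male, age)
    if event is not None:
        u -= utils.acute(event)
    if post_event is not None and years_since_event is not None and years_since_event >= 1:
        u -= utils.longterm(post_event)
    if diabetic:
        u -= utils.diabetes_disutility
    return max(u, 0.0)


def discount_factor(cycle_index, rate: float):
    c = np.asarray(cycle_index)
    if np.any(c < 0):
        raise DomainError("cycle index must be >= 0")
    if rate < 0:
        raise DomainError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(cycle_index, dtype=float))


def discount(value, cycle_index, rate: float):
    """Discount a cycle value to present value; cycle 0 is undiscounted."""
    out = np.asarray(value, dtype=float) * discount_factor(cycle_index, rate)
    return float(out) if np.isscalar(value) and np.isscalar(cycle_index) else out


# ---------------------------------------------------------------------------
# frontier / ICER machinery
# ---------------------------------------------------------------------------

DOMINATED = "dominated"
EXT_DOMINATED = "extended-dominated"
ON_FRONTIER = "on-frontier"


@dataclass(frozen=True)
class FrontierEntry:
    name: str
    cost: float
    qaly: float
    status: str
    icer: float | None = None  # vs previous frontier step; None for cheapest


@dataclass(frozen=True)
class CEFrontier:
    entries: tuple  # all strategies, original classification, sorted by cost
    wtp_1gdp: float = WTP_1GDP
    wtp_3gdp: float = WTP_3GDP

    @property
    def frontier(self) -> tuple:
        return tuple(e for e in self.entries if e.status == ON_FRONTIER)

    def icer_of(self, name: str) -> float | None:
        for e in self.frontier:
            if e.name == name:
                return e.icer
        return None

    def optimal_at(self, wtp: float) -> str:
        """Frontier strategy with the highest net monetary benefit at ``wtp``."""
        nmb = [wtp * e.qaly - e.cost for e in self.frontier]
        return self.frontier[int(np.argmax(nmb))].name


def _as_points(results):
    pts = []
    for r in results:
        if hasattr(r, "mean_cost"):
            pts.append((r.name, float(r.mean_cost), float(r.mean_qaly)))
        else:
            name, cost, qaly = r
            pts.append((str(name), float(cost), float(qaly)))
    return pts


def icer_ladder(results) -> CEFrontier:
    """Classify strategies as dominated / extended-dominated / on-frontier.

    Sort by ascending cost; drop strictly dominated strategies (another
    strategy is no more costly and no less effective, strictly better on one
    axis); then iteratively drop extended-dominated strategies until the
    sequential ICERs along the ladder are nondecreasing.
    """
    pts = _as_points(results)
    if not pts:
        raise DomainError("icer_ladder needs at least one strategy")
    names = [p[0] for p in pts]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate strategy names")
    order = sorted(range(len(pts)), key=lambda i: (pts[i][1], pts[i][2]))
    status = {name: ON_FRONTIER for name in names}
    # strict dominance (pairwise, weak with one strict)
    for i in range(len(pts)):
        ni, ci, qi = pts[i]
        for j in range(len(pts)):
            if i == j:
                continue
            nj, cj, qj = pts[j]
            if (cj <= ci and qj >= qi) and (cj < ci or qj > qi):
                status[ni] = DOMINATED
                break
    # extended dominance on the survivors
    surviving = [i for i in order if status[pts[i][0]] == ON_FRONTIER]
    changed = True
    while changed and len(surviving) >= 3:
        changed = False
        for k in range(1, len(surviving) - 1):
            i0, i1, i2 = surviving[k - 1], surviving[k], surviving[k + 1]
            icer_a = _pair_icer(pts[i0], pts[i1])
            icer_b = _pair_icer(pts[i1], pts[i2])
            if icer_a > icer_b:
                status[pts[i1][0]] = EXT_DOMINATED
                surviving.pop(k)
                changed = True
                break
    entries = []
    prev = None
    for i in order:
        name, cost, qaly = pts[i]
        icer = None
        if status[name] == ON_FRONTIER:
            if prev is not None:
                icer = _pair_icer(prev, pts[i])
            prev = pts[i]
        entries.append(FrontierEntry(name, cost, qaly, status[name], icer))
    return CEFrontier(entries=tuple(entries))


def _pair_icer(cheap, rich) -> float:
    dq = rich[2] - cheap[2]
    dc = rich[1] - cheap[1]
    if dq <= 0:
        return np.inf
    return dc / dq


def ceac(costs, qalys, names, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    ``costs`` / ``qalys`` are (n_draws, n_strategies) arrays; at each WTP the
    probability a strategy maximises net monetary benefit (ties split
    equally).  Returns a tidy DataFrame (wtp, strategy, probability); the
    probabilities sum to 1 at every WTP.
    """
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(qalys, dtype=float))
    if costs.shape != qalys.shape or costs.shape[1] != len(names):
        raise DomainError("costs/qalys must be (n_draws, n_strategies) matching names")
    if costs.shape[0] == 0:
        raise DomainError("CEAC needs at least one PSA draw")
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise DomainError("CEAC needs at least one WTP point")
    rows = []
    n_draws = costs.shape[0]
    for lam in wtp_grid:
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        for name, p in zip(names, probs):
            rows.append({"wtp": float(lam), "strategy": name, "probability": float(p)})
    return pd.DataFrame(rows)


def frontier_report(strategy_results, frontier: CEFrontier) -> pd.DataFrame:
    """Strategy-level summary mirroring the base-case results table."""
    by_name = {e.name: e for e in frontier.entries}
    rows = []
    for r in strategy_results:
        e = by_name[r.name]
        rows.append(
            {
                "strategy": r.name,
                "eligible_pct": 100.0 * r.eligible_fraction,
                "statin_diabetes_per_person": r.statin_diabetes_per_person,
                "cvd_events_per_person": r.cvd_events_per_person,
                "mean_discounted_qalys": r.mean_qaly,
                "life_expectancy": r.mean_life_expectancy,
                "mean_discounted_cost": r.mean_cost,
                "status": e.status,
                "icer": e.icer if e.icer is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("mean_discounted_cost").reset_index(drop=True)
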