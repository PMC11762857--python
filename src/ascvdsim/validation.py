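"""Parameter-recovery experiments used for verification.

These helpers run stripped-down simulations with known ground truth so the
engine's probability machinery can be checked against closed forms: a
two-arm person-cycle simulation recovering a configured odds ratio, and a
deterministic cohort-Markov recursion for constant-hazard populations (the
independent oracle the microsimulation means are compared against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .risk import EventParameters, apply_odds_ratio
from .strategies import treated_event_probabilities

__all__ = ["TwoArmResult", "recover_odds_ratio", "cohort_markov_oracle", "MarkovOracleResult"]


@dataclass(frozen=True)
class TwoArmResult:
    odds_ratio: float
    log_or_se: float
    events_treated: int
    events_untreated: int
    n_per_arm: int

    @property
    def ci3(self) -> tuple[float, float]:
        """+/- 3 SE interval for the log-OR, back-transformed."""
        lo = np.exp(np.log(self.odds_ratio) - 3 * self.log_or_se)
        hi = np.exp(np.log(self.odds_ratio) + 3 * self.log_or_se)
        return float(lo), float(hi)


def recover_odds_ratio(p_baseline: float, endpoint: str, n_per_arm: int, seed: int,
                       params: EventParameters | None = None) -> TwoArmResult:
    """Empirical odds ratio from a two-arm constant-probability simulation.

    Both arms share a fixed baseline annual event probability; the treated
    arm applies the model's default treatment effect for ``endpoint``
    ("chd", "stroke" or "diabetes") through the same odds-scale adjustment
    the engine uses.  Person-cycles are independent Bernoulli draws.
    """
    if not (0.0 < p_baseline < 1.0):
        raise DomainError("baseline probability must lie strictly inside (0, 1)")
    if params is None:
        params = EventParameters()
    if endpoint == "chd":
        p_t, _, _ = treated_event_probabilities(p_baseline, 0.0, 0.0, True, params)
    elif endpoint == "stroke":
        _, p_t, _ = treated_event_probabilities(0.0, p_baseline, 0.0, True, params)
    elif endpoint == "diabetes":
        _, _, p_t = treated_event_probabilities(0.0, 0.0, p_baseline, True, params)
    else:
        raise DomainError(f"unknown endpoint {endpoint!r}")
    rng = np.random.default_rng(seed)
    a = int((rng.random(n_per_arm) < p_t).sum())  # treated events
    b = int((rng.random(n_per_arm) < p_baseline).sum())  # untreated events
    if min(a, b, n_per_arm - a, n_per_arm - b) == 0:
        raise DomainError("a cell of the 2x2 table is empty; increase n_per_arm")
    or_hat = (a / (n_per_arm - a)) / (b / (n_per_arm - b))
    se = np.sqrt(1 / a + 1 / (n_per_arm - a) + 1 / b + 1 / (n_per_arm - b))
    return TwoArmResult(odds_ratio=float(or_hat), log_or_se=float(se),
                        events_treated=a, events_untreated=b, n_per_arm=n_per_arm)


@dataclass(frozen=True)
class MarkovOracleResult:
    life_expectancy_years: float  # expected survived cycles
    discounted_qalys: float
    discounted_cost: float
    survival: np.ndarray  # P(alive at end of cycle t)


def cohort_markov_oracle(*, n_cycles: int, p_event: float, chd_share: float,
                         fatality_chd: float, fatality_stroke: float, q_background: float,
                         post_event_multiplier: float, age_weight: float, acute_chd: float,
                         acute_stroke: float, longterm_chd: float, longterm_stroke: float,
                         hosp_chd: float, hosp_stroke: float, first_year_chd: float,
                         first_year_stroke: float, office_chd: float, office_stroke: float,
                         statin_cost: float = 0.0, discount_rate: float = 0.03) -> MarkovOracleResult:
    """Deterministic cohort recursion for identical constant-hazard individuals.

    Mirrors the engine's within-cycle accounting (event, then case fatality,
    then background death; death cycles accrue hospitalisation only; acute
    decrement in the event cycle, long-term decrement and post-event costs
    from the first post-event year) as an expectation over the state
    distribution, with no Monte-Carlo noise.  States: event-free, post-CHD
    (first year / later), post-stroke (first year / later), dead.
    """
    EF, C1, C2, S1, S2 = range(5)
    dist = np.zeros(5)
    dist[EF] = 1.0
    disc = 1.0 / (1.0 + discount_rate)
    qd = min(1.0, q_background * post_event_multiplier)
    le = qaly = cost = 0.0
    survival = np.zeros(n_cycles)
    p_chd = p_event * chd_share
    p_stroke = p_event * (1.0 - chd_share)
    for t in range(n_cycles):
        w = disc**t
        new = np.zeros(5)
        # event-free flows
        ef = dist[EF]
        chd_fatal = ef * p_chd * fatality_chd
        chd_nonfatal = ef * p_chd * (1 - fatality_chd)
        stroke_fatal = ef * p_stroke * fatality_stroke
        stroke_nonfatal = ef * p_stroke * (1 - fatality_stroke)
        no_event = ef * (1 - p_event)
        # background death applies to non-fatal-event and no-event alike (normal q:
        # the individual is event-free at cycle start)
        chd_surv = chd_nonfatal * (1 - q_background)
        stroke_surv = stroke_nonfatal * (1 - q_background)
        ef_surv = no_event * (1 - q_background)
        # post-event states: no recurrence, doubled background mortality
        c1_surv = dist[C1] * (1 - qd)
        c2_surv = dist[C2] * (1 - qd)
        s1_surv = dist[S1] * (1 - qd)
        s2_surv = dist[S2] * (1 - qd)
        # costs: event cycles accrue hospitalisation regardless of survival;
        # survivors accrue statin cost; post-event survivors their year costs
        cost_t = (
            (chd_fatal + chd_nonfatal) * hosp_chd
            + (stroke_fatal + stroke_nonfatal) * hosp_stroke
            + (chd_surv + stroke_surv + ef_surv) * statin_cost
            + c1_surv * first_year_chd + s1_surv * first_year_stroke
            + c2_surv * office_chd + s2_surv * office_stroke
            + (c1_surv + c2_surv + s1_surv + s2_surv) * statin_cost
        )
        # utilities: survivors only; acute decrement in the event cycle,
        # long-term decrement in every post-event year; floored at 0
        u_event_chd = max(age_weight - acute_chd, 0.0)
        u_event_stroke = max(age_weight - acute_stroke, 0.0)
        u_post_chd = max(age_weight - longterm_chd, 0.0)
        u_post_stroke = max(age_weight - longterm_stroke, 0.0)
        util_t = (
            chd_surv * u_event_chd + stroke_surv * u_event_stroke + ef_surv * age_weight
            + (c1_surv + c2_surv) * u_post_chd + (s1_surv + s2_surv) * u_post_stroke
        )
        alive = ef_surv + chd_surv + stroke_surv + c1_surv + c2_surv + s1_surv + s2_surv
        le += alive
        qaly += w * util_t
        cost += w * cost_t
        survival[t] = alive
        new[EF] = ef_surv
        new[C1] = chd_surv
        new[C2] = c1_surv + c2_surv
        new[S1] = stroke_surv
        new[S2] = s1_surv + s2_surv
        dist = new
    return MarkovOracleResult(life_expectancy_years=le, discounted_qalys=qaly,
                              discounted_cost=cost, survival=survival)
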