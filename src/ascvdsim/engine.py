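"""Annual-cycle individual-level microsimulation.

Each simulated year executes a fixed within-cycle order:

1. screening / statin initiation, plus the end-of-first-year discontinuation
   draw (bookkept at the end of the cycle);
2. annual ASCVD probability from the risk engine (event-free individuals),
   split into CHD/stroke components with the statin odds ratios applied while
   on treatment;
3. ASCVD event draw; on an event, type assignment and a case-fatality draw;
4. diabetes-onset draw for non-diabetic survivors (statin-adjusted);
5. background all-cause mortality draw (doubled for post-event survivors);
6. cost and utility accrual, discounted by the cycle index;
7. risk-factor projection and the age increment.

Two implementations share this contract: a scalar per-individual path
(:func:`run_cycle` / :func:`run_individual`) that mirrors the printed model
diagram literally, and a vectorised cohort path (:func:`run_strategy`) used
for production runs.  Both consume exactly six uniform draws per cycle in a
fixed order (discontinuation, event, type, fatality, diabetes, background
death), so an n=1 cohort reproduces the scalar path bit-for-bit and common
random numbers across strategies come free: strategies run from the same
master seed see identical per-cycle draw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .economics import CostParameters, UtilityParameters, accrue_cycle_cost, accrue_cycle_utility
from .errors import DomainError, StateError
from .population import (MAX_MODEL_AGE, AgeTrendModel, IndividualProfile,
                         project_cohort_arrays, project_risk_factors)
from .risk import (CHD, STROKE, EventParameters, RiskCoefficients, apply_odds_ratio,
                   deale_annual_probability, ten_year_risk_arrays)
from .strategies import DIRECT_INITIATION_RULES, StrategyDefinition, eligibility_mask

__all__ = ["ParameterSet", "CycleRecord", "LifetimeResult", "StrategyResult",
           "run_cycle", "run_individual", "run_strategy"]


@dataclass(frozen=True)
class ParameterSet:
    """Everything the simulation needs besides the cohort and strategy."""

    coefficients: RiskCoefficients
    events: EventParameters
    costs: CostParameters
    utilities: UtilityParameters
    trends: AgeTrendModel
    discount_rate: float = 0.03

    def __post_init__(self):
        if self.discount_rate < 0:
            raise DomainError("discount rate must be >= 0")


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    age: float
    event: str | None  # None / "CHD fatal" / "CHD non-fatal" / "stroke fatal" /
    #                    "stroke non-fatal" / "background death" / with "+diabetes onset" suffix
    treatment_state: str
    cost: float  # undiscounted
    utility: float  # undiscounted


@dataclass(frozen=True)
class LifetimeResult:
    id: int
    discounted_cost: float
    discounted_qaly: float
    life_years: float
    chd_events: int
    stroke_events: int
    statin_induced_diabetes: bool
    age_at_exit: float  # age at death, or censoring at the model cap
    ever_initiated: bool
    final_treatment_state: str
    records: tuple = ()


@dataclass(frozen=True)
class StrategyResult:
    """Cohort means under one strategy (plus SDs for Monte-Carlo error bars)."""

    name: str
    n: int
    mean_cost: float
    mean_qaly: float
    mean_life_years: float
    mean_life_expectancy: float  # mean age at death / censoring
    cvd_events_per_person: float
    chd_events_per_person: float
    stroke_events_per_person: float
    statin_diabetes_per_person: float
    eligible_fraction: float
    sd_cost: float
    sd_qaly: float
    sd_life_years: float
    seed: int | None = None
    individual: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# scalar path
# ---------------------------------------------------------------------------


def _annual_probabilities(profile: IndividualProfile, params: ParameterSet):
    """Adjusted annual (p_chd, p_stroke, p_diab) for one alive profile."""
    ev = params.events
    on = profile.treatment_state == "on-statin"
    if profile.health_state == "event-free":
        fields = {
            "age": profile.age, "sbp": profile.sbp, "tc": profile.tc, "hdl": profile.hdl,
            "ldl": profile.ldl, "wc": profile.wc, "smoker": float(profile.smoker),
            "diabetes": float(profile.diabetes_rf), "antihtn": float(profile.antihtn),
        }
        p10 = float(ten_year_risk_arrays(fields, profile.is_male, params.coefficients))
        p1 = deale_annual_probability(p10)
        p_chd = p1 * ev.chd_share
        p_stroke = p1 * ev.stroke_share
    else:
        p_chd = p_stroke = 0.0
    p_diab = 0.0
    if not profile.diabetes:
        p_diab = float(ev.diabetes_incidence.lookup(profile.is_male, profile.age))
    if on:
        p_chd = apply_odds_ratio(p_chd, ev.or_chd)
        p_stroke = apply_odds_ratio(p_stroke, ev.or_stroke)
        p_diab = apply_odds_ratio(p_diab, ev.or_diabetes)
    return p_chd, p_stroke, p_diab


def run_cycle(profile: IndividualProfile, strategy: StrategyDefinition,
              params: ParameterSet, rng: np.random.Generator,
              cycle_index: int = 0) -> tuple[IndividualProfile, CycleRecord]:
    """Advance one alive profile through one annual cycle.

    Consumes exactly six uniforms from ``rng`` in the fixed order
    (discontinuation, event, type, fatality, diabetes, background death).
    Returns the updated profile and the cycle's undiscounted accounting.
    """
    if not profile.alive:
        raise StateError("cannot run a cycle for a dead profile")
    ev = params.events
    p = profile
    age_at_start = p.age
    u_disc = rng.random()
    u_event = rng.random()
    u_type = rng.random()
    u_fatal = rng.random()
    u_diab = rng.random()
    u_death = rng.random()

    # post-event year counter advances at cycle start
    if p.years_since_event is not None:
        p = replace(p, years_since_event=p.years_since_event + 1)

    # 1. screening / initiation
    if p.treatment_state == "never" and p.health_state == "event-free" and strategy.treats:
        fields = {"ldl": p.ldl, "diabetes_rf": p.diabetes_rf}
        rule_fire = any(bool(DIRECT_INITIATION_RULES[r](fields)) for r in strategy.rules)
        from .risk import ten_year_ascvd_risk  # local import avoids cycle at module load
        eligible = rule_fire or (
            strategy.threshold is not None
            and ten_year_ascvd_risk(p, params.coefficients) >= strategy.threshold
        )
        if eligible:
            p = replace(p, treatment_state="on-statin", treated_years=0)
    on_statin = p.treatment_state == "on-statin"

    # 2-3. ASCVD event
    p_chd, p_stroke, p_diab = _annual_probabilities(p, params)
    p_event = p_chd + p_stroke
    event = None
    fatal = False
    if p.health_state == "event-free" and u_event < p_event:
        event = CHD if u_type < (p_chd / p_event) else STROKE
        table = ev.case_fatality_chd if event == CHD else ev.case_fatality_stroke
        fatal = u_fatal < table.lookup(p.is_male, p.age)

    # 4. diabetes onset (skipped on an ASCVD death)
    new_diabetes = False
    if not fatal and not p.diabetes and u_diab < p_diab:
        new_diabetes = True

    # 5. background mortality (doubled for individuals already post-event)
    bg_dead = False
    if not fatal:
        q = float(ev.background_mortality.lookup(p.is_male, p.age))
        if p.health_state in ("post-CHD", "post-stroke"):
            q = min(1.0, q * ev.post_event_mortality_multiplier)
        bg_dead = u_death < q
    died = fatal or bg_dead

    # 6. cost / utility accrual
    post_event = {"post-CHD": CHD, "post-stroke": STROKE}.get(p.health_state)
    diabetic_now = p.diabetes or new_diabetes
    cost = accrue_cycle_cost(
        params.costs, on_statin=on_statin, event=event, died=died, post_event=post_event,
        years_since_event=p.years_since_event, diabetic=diabetic_now,
    )
    utility = accrue_cycle_utility(
        params.utilities, male=p.is_male, age=p.age, event=event, died=died,
        post_event=post_event, years_since_event=p.years_since_event, diabetic=diabetic_now,
    )

    # 7. state updates, adherence bookkeeping, projection
    updates: dict = {}
    if new_diabetes:
        # incident diabetes drives costs/utilities only; the risk-equation
        # covariate reflects baseline diabetes status (see docs/methods.md)
        updates["diabetes"] = True
        if on_statin:
            updates["statin_induced_diabetes"] = True
    if died:
        updates["health_state"] = "dead"
        p = replace(p, **updates)
    else:
        if event is not None:
            updates["health_state"] = "post-CHD" if event == CHD else "post-stroke"
            updates["years_since_event"] = 0
        p = replace(p, **updates)
        if on_statin:
            p = replace(p, treated_years=p.treated_years + 1)
            if p.treated_years == 1 and u_disc < strategy.discontinuation:
                p = replace(p, treatment_state="discontinued")
        p = project_risk_factors(p, params.trends, rng=None if params.trends.residual_sd == 0 else rng)

    label = None
    if event is not None:
        label = f"{event} {'fatal' if fatal else 'non-fatal'}"
    elif bg_dead:
        label = "background death"
    if new_diabetes:
        label = (label + "+diabetes onset") if label else "diabetes onset"
    record = CycleRecord(cycle=cycle_index, age=age_at_start, event=label,
                         treatment_state=p.treatment_state if p.alive else profile.treatment_state,
                         cost=cost, utility=utility)
    return p, record


def run_individual(profile: IndividualProfile, strategy: StrategyDefinition,
                   params: ParameterSet, seed: int, keep_records: bool = False) -> LifetimeResult:
    """Simulate one individual from baseline to death or the age cap."""
    rng = np.random.default_rng(seed)
    p = profile
    disc = 1.0 / (1.0 + params.discount_rate)
    cost = qaly = 0.0
    life_years = 0.0
    chd = stroke = 0
    records = []
    t = 0
    while p.alive and p.age <= MAX_MODEL_AGE:
        p, rec = run_cycle(p, strategy, params, rng, cycle_index=t)
        w = disc ** t
        cost += w * rec.cost
        qaly += w * rec.utility
        if p.alive:
            life_years += 1.0
        if rec.event:
            if rec.event.startswith(CHD):
                chd += 1
            elif rec.event.startswith(STROKE):
                stroke += 1
        if keep_records:
            records.append(rec)
        t += 1
    return LifetimeResult(
        id=profile.id, discounted_cost=cost, discounted_qaly=qaly, life_years=life_years,
        chd_events=chd, stroke_events=stroke, statin_induced_diabetes=p.statin_induced_diabetes,
        age_at_exit=float(p.age if not p.alive else MAX_MODEL_AGE + 1),
        ever_initiated=p.treatment_state != "never",
        final_treatment_state=p.treatment_state, records=tuple(records),
    )


# ---------------------------------------------------------------------------
# vectorised path
# ---------------------------------------------------------------------------

_EF, _PCHD, _PSTROKE, _DEAD = 0, 1, 2, 3
_NEVER, _ON, _DISC = 0, 1, 3
_TREAT_LABEL = {_NEVER: "never", _ON: "on-statin", _DISC: "discontinued"}


def run_strategy(cohort: pd.DataFrame, strategy: StrategyDefinition, params: ParameterSet,
                 seed: int, *, max_cycles: int | None = None, allow_recurrence: bool = False,
                 keep_individual: bool = False) -> StrategyResult:
    """Run the full cohort under one strategy (vectorised).

    Common random numbers: strategies run with the same ``seed`` consume
    identical per-cycle uniform draw arrays, so incremental comparisons are
    paired at the individual level.
    """
    n = len(cohort)
    if n == 0:
        raise DomainError("cohort must be nonempty")
    ev = params.events
    rng = np.random.default_rng(seed)

    age = cohort["age"].to_numpy(dtype=float).copy()
    male = (cohort["sex"].to_numpy() == "M")
    fields = {f: cohort[f].to_numpy(dtype=float).copy() for f in ("sbp", "tc", "hdl", "ldl", "wc")}
    smoker = cohort["smoker"].to_numpy(dtype=bool)
    antihtn = cohort["antihtn"].to_numpy(dtype=bool)
    diabetic = cohort["diabetes"].to_numpy(dtype=bool).copy()
    diabetes_rf = diabetic.copy()
    statin_diab = np.zeros(n, dtype=bool)

    state = np.full(n, _EF, dtype=np.int8)
    treat = np.full(n, _NEVER, dtype=np.int8)
    treated_years = np.zeros(n, dtype=np.int16)
    ys_event = np.full(n, -1, dtype=np.int32)  # years since first event; -1 = none
    post_type_chd = np.zeros(n, dtype=bool)

    disc = 1.0 / (1.0 + params.discount_rate)
    cost_tot = np.zeros(n)
    qaly_tot = np.zeros(n)
    life_years = np.zeros(n)
    chd_count = np.zeros(n, dtype=np.int32)
    stroke_count = np.zeros(n, dtype=np.int32)
    age_at_exit = np.full(n, np.nan)

    horizon = int(MAX_MODEL_AGE - age.min() + 1)
    if max_cycles is not None:
        horizon = min(horizon, max_cycles)

    for t in range(horizon):
        active = (state != _DEAD) & (age <= MAX_MODEL_AGE)
        if not active.any():
            break
        u_disc = rng.random(n)
        u_event = rng.random(n)
        u_type = rng.random(n)
        u_fatal = rng.random(n)
        u_diab = rng.random(n)
        u_death = rng.random(n)

        post = active & ((state == _PCHD) | (state == _PSTROKE))
        ys_event[post] += 1

        # 1. screening / initiation
        ef = active & (state == _EF)
        risk_fields = {
            "age": age, "sbp": fields["sbp"], "tc": fields["tc"], "hdl": fields["hdl"],
            "ldl": fields["ldl"], "wc": fields["wc"], "smoker": smoker.astype(float),
            "diabetes": diabetes_rf.astype(float), "antihtn": antihtn.astype(float),
        }
        risk10 = np.zeros(n)
        risk_pool = (ef | (post if allow_recurrence else np.zeros(n, dtype=bool)))
        if risk_pool.any():
            sub = {k: v[risk_pool] for k, v in risk_fields.items()}
            risk10[risk_pool] = ten_year_risk_arrays(sub, male[risk_pool], params.coefficients)
        if strategy.treats:
            rule_fields = {"ldl": fields["ldl"], "diabetes_rf": diabetes_rf}
            elig = ef & (treat == _NEVER) & eligibility_mask(risk10, rule_fields, strategy)
            treat[elig] = _ON
            treated_years[elig] = 0
        on = active & (treat == _ON)

        # 2. annual probabilities
        p1 = deale_annual_probability(risk10)
        p_chd = p1 * ev.chd_share
        p_stroke = p1 * ev.stroke_share
        p_chd = np.where(on, apply_odds_ratio(p_chd, ev.or_chd), p_chd)
        p_stroke = np.where(on, apply_odds_ratio(p_stroke, ev.or_stroke), p_stroke)
        p_event = p_chd + p_stroke

        # 3. event draw, type split, case fatality
        event_pool = ef | (post if allow_recurrence else np.zeros(n, dtype=bool))
        event = event_pool & (u_event < p_event)
        with np.errstate(invalid="ignore", divide="ignore"):
            chd_frac = np.divide(p_chd, p_event, out=np.zeros(n), where=p_event > 0)
        is_chd = event & (u_type < chd_frac)
        is_stroke = event & ~is_chd
        cf = np.zeros(n)
        if event.any():
            if is_chd.any():
                cf[is_chd] = ev.case_fatality_chd.lookup(male[is_chd], age[is_chd])
            if is_stroke.any():
                cf[is_stroke] = ev.case_fatality_stroke.lookup(male[is_stroke], age[is_stroke])
        fatal = event & (u_fatal < cf)

        # 4. diabetes onset
        p_diab = np.zeros(n)
        nd_pool = active & ~diabetic & ~fatal
        if nd_pool.any():
            p_diab[nd_pool] = ev.diabetes_incidence.lookup(male[nd_pool], age[nd_pool])
        p_diab = np.where(on, apply_odds_ratio(p_diab, ev.or_diabetes), p_diab)
        new_diab = nd_pool & (u_diab < p_diab)
        new_statin_diab = new_diab & on

        # 5. background mortality
        q = np.zeros(n)
        bg_pool = active & ~fatal
        if bg_pool.any():
            q[bg_pool] = ev.background_mortality.lookup(male[bg_pool], age[bg_pool])
        q = np.where(post, np.minimum(1.0, q * ev.post_event_mortality_multiplier), q)
        bg_dead = bg_pool & (u_death < q)
        died = fatal | bg_dead
        living = active & ~died

        # 6. cost / utility accrual
        diabetic_now = diabetic | new_diab
        cost = np.zeros(n)
        cost[is_chd] += params.costs.hospitalization_ami
        cost[is_stroke] += params.costs.hospitalization_stroke
        cost[living & on] += params.costs.statin_annual
        first_year = living & post & (ys_event == 1)
        later_year = living & post & (ys_event >= 2)
        cost[first_year & post_type_chd] += params.costs.first_year_ami
        cost[first_year & ~post_type_chd] += params.costs.first_year_stroke
        cost[later_year & post_type_chd] += params.costs.office_visit_ami
        cost[later_year & ~post_type_chd] += params.costs.office_visit_stroke
        cost[living & diabetic_now] += params.costs.diabetes_annual
        cost[died & ~event] = 0.0  # background death without an event accrues nothing
        cost[died & event] = np.where(
            is_chd[died & event], params.costs.hospitalization_ami, params.costs.hospitalization_stroke
        )  # a death cycle with an event accrues hospitalisation only

        utility = np.zeros(n)
        if living.any():
            utility[living] = params.utilities.age_weights.lookup(male[living], age[living])
        utility[living & is_chd] -= params.utilities.acute_chd
        utility[living & is_stroke] -= params.utilities.acute_stroke
        lt = living & post & (ys_event >= 1)
        utility[lt & post_type_chd] -= params.utilities.longterm_ami
        utility[lt & ~post_type_chd] -= params.utilities.longterm_stroke
        utility[living & diabetic_now] -= params.utilities.diabetes_disutility
        np.maximum(utility, 0.0, out=utility)

        w = disc ** t
        cost_tot += w * cost
        qaly_tot += w * utility
        life_years += living

        chd_count += is_chd
        stroke_count += is_stroke

        # 7. state updates, adherence, projection
        age_at_exit[died] = age[died]
        state[died] = _DEAD
        surv_event = event & living
        new_chd = surv_event & is_chd
        new_stroke = surv_event & is_stroke
        if allow_recurrence:
            # keep the larger long-term decrement: stroke outranks AMI
            post_type_chd = np.where(new_stroke, False, np.where(new_chd & ~(state == _PSTROKE), True, post_type_chd))
        else:
            post_type_chd = np.where(new_chd, True, post_type_chd)
        state[new_chd] = _PCHD
        state[new_stroke] = _PSTROKE
        ys_event[surv_event] = 0

        diabetic |= new_diab
        statin_diab |= new_statin_diab
        # diabetes_rf (risk-equation covariate) deliberately stays at baseline

        adv = living & (treat == _ON)
        treated_years[adv] += 1
        stop = living & (treat == _ON) & (treated_years == 1) & (u_disc < strategy.discontinuation)
        treat[stop] = _DISC

        if living.any():
            sub = {f: fields[f][living] for f in fields}
            project_cohort_arrays(sub, male[living], params.trends,
                                  rng=rng if params.trends.residual_sd > 0 else None)
            for f in fields:
                fields[f][living] = sub[f]
            age[living] += 1

    censored = state != _DEAD
    age_at_exit[censored] = MAX_MODEL_AGE + 1

    baseline_age = cohort["age"].to_numpy(dtype=float)
    ever = treat != _NEVER
    events_pp = float((chd_count + stroke_count).mean())
    individual = None
    if keep_individual:
        individual = pd.DataFrame({
            "id": cohort["id"].to_numpy(),
            "discounted_cost": cost_tot,
            "discounted_qaly": qaly_tot,
            "life_years": life_years,
            "chd_events": chd_count,
            "stroke_events": stroke_count,
            "statin_induced_diabetes": statin_diab,
            "age_at_exit": age_at_exit,
            "ever_initiated": ever,
            "final_treatment_state": [_TREAT_LABEL[int(v)] for v in treat],
            "dead": state == _DEAD,
        })
    return StrategyResult(
        name=strategy.name, n=n,
        mean_cost=float(cost_tot.mean()), mean_qaly=float(qaly_tot.mean()),
        mean_life_years=float(life_years.mean()),
        mean_life_expectancy=float((baseline_age + life_years).mean()),
        cvd_events_per_person=float(events_pp),
        chd_events_per_person=float(chd_count.mean()),
        stroke_events_per_person=float(stroke_count.mean()),
        statin_diabetes_per_person=float(statin_diab.mean()),
        eligible_fraction=float(ever.mean()),
        sd_cost=float(cost_tot.std(ddof=1)) if n > 1 else 0.0,
        sd_qaly=float(qaly_tot.std(ddof=1)) if n > 1 else 0.0,
        sd_life_years=float(life_years.std(ddof=1)) if n > 1 else 0.0,
        seed=seed, individual=individual,
    )
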