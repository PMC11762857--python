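"""Statin initiation strategies, adherence and treatment effects.

A strategy is a 10-year-risk initiation threshold (or none, for the
no-treatment arm), optionally augmented by named direct-initiation
predicates, with a first-year discontinuation probability.  Moderate
intensity only: eligibility triggers moderate-intensity statins whose
effects enter the annual event probabilities as odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, StateError
from .risk import EventParameters, RiskCoefficients, apply_odds_ratio, ten_year_ascvd_risk

__all__ = [
    "StrategyDefinition",
    "DIRECT_INITIATION_RULES",
    "preset_strategies",
    "is_eligible",
    "update_treatment_state",
    "treated_event_probabilities",
]

#: Named direct-initiation predicates (vectorisable: take dict of arrays).
#: These model guideline direct-initiation criteria beyond the pure risk
#: threshold; all default off.
DIRECT_INITIATION_RULES = {
    # very high LDL-C initiates regardless of computed risk
    "ldl_very_high": lambda f: np.asarray(f["ldl"]) >= 4.9,
    # diabetic and LDL-C above target
    "diabetes_ldl_elevated": lambda f: np.asarray(f["diabetes_rf"], dtype=bool) & (np.asarray(f["ldl"]) >= 2.6),
    # unconditional initiation (used for adherence experiments)
    "always": lambda f: np.ones(np.asarray(f["ldl"]).shape, dtype=bool),
}


@dataclass(frozen=True)
class StrategyDefinition:
    """An initiation rule with its adherence model."""

    name: str
    threshold: float | None  # 10-year risk initiation threshold; None = never treat
    discontinuation: float = 0.40  # probability of stopping at end of first treated year
    rules: tuple = ()  # names into DIRECT_INITIATION_RULES
    intensity: str = "moderate"

    def __post_init__(self):
        if self.threshold is not None and not (0.0 < self.threshold <= 1.0):
            raise ConfigurationError(f"threshold must lie in (0, 1] or be None, got {self.threshold}")
        if not (0.0 <= self.discontinuation <= 1.0):
            raise ConfigurationError("discontinuation probability must lie in [0, 1]")
        for r in self.rules:
            if r not in DIRECT_INITIATION_RULES:
                raise ConfigurationError(f"unknown direct-initiation rule {r!r}")

    @property
    def treats(self) -> bool:
        return self.threshold is not None or bool(self.rules)


def preset_strategies(discontinuation: float = 0.40) -> list[StrategyDefinition]:
    """The four arms evaluated in the base case.

    No treatment, a 15% threshold, the 10% guideline threshold, and 7.5%.
    """
    return [
        StrategyDefinition("no-treatment", None, discontinuation),
        StrategyDefinition("threshold-15", 0.15, discontinuation),
        StrategyDefinition("guideline-10", 0.10, discontinuation),
        StrategyDefinition("threshold-7.5", 0.075, discontinuation),
    ]


def is_eligible(profile, strategy: StrategyDefinition, coef: RiskCoefficients) -> bool:
    """Whether an alive, event-free, never-treated individual initiates now.

    True iff the 10-year risk reaches the threshold (inclusive ``>=``) or any
    direct-initiation predicate fires; always False for the no-treatment arm.
    """
    if not profile.alive:
        raise StateError("eligibility is undefined for a dead profile")
    if not strategy.treats:
        return False
    fields = {"ldl": profile.ldl, "diabetes_rf": profile.diabetes_rf}
    for rule in strategy.rules:
        if bool(DIRECT_INITIATION_RULES[rule](fields)):
            return True
    if strategy.threshold is None:
        return False
    return ten_year_ascvd_risk(profile, coef) >= strategy.threshold


def eligibility_mask(risk10, fields: dict, strategy: StrategyDefinition):
    """Vectorised eligibility over precomputed risks and profile fields."""
    risk10 = np.asarray(risk10, dtype=float)
    out = np.zeros(risk10.shape, dtype=bool)
    if not strategy.treats:
        return out
    if strategy.threshold is not None:
        out |= risk10 >= strategy.threshold
    for rule in strategy.rules:
        out |= DIRECT_INITIATION_RULES[rule](fields)
    return out


def update_treatment_state(profile, strategy: StrategyDefinition, u: float,
                           eligible: bool | None = None, coef: RiskCoefficients | None = None):
    """One annual update of the treatment state machine.

    never -> on-statin when eligible this cycle; at the end of the first
    treated year the individual discontinues with the strategy's
    discontinuation probability (``u < p``) and otherwise adheres for life;
    discontinued is absorbing.
    """
    if not profile.alive:
        raise StateError("cannot update treatment state of a dead profile")
    p = profile
    if p.treatment_state == "never":
        if eligible is None:
            if coef is None:
                raise ConfigurationError("eligibility must be given or a coefficient set supplied")
            eligible = is_eligible(p, strategy, coef)
        if eligible:
            return replace(p, treatment_state="on-statin", treated_years=0)
        return p
    if p.treatment_state == "on-statin" and p.treated_years == 1:
        if u < strategy.discontinuation:
            return replace(p, treatment_state="discontinued")
    return p


def treated_event_probabilities(p_chd: float, p_stroke: float, p_diab: float,
                                on_statin: bool, params: EventParameters):
    """Apply the statin odds ratios to annual CHD / stroke / diabetes probabilities.

    Identity when not on statin.  Discontinued individuals carry no treatment
    effect, so callers pass ``on_statin=False`` for them.
    """
    if not on_statin:
        return p_chd, p_stroke, p_diab
    return (
        apply_odds_ratio(p_chd, params.or_chd),
        apply_odds_ratio(p_stroke, params.or_stroke),
        apply_odds_ratio(p_diab, params.or_diabetes),
    )
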