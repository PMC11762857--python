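"""Annual ASCVD event probabilities.

The hazard source is a Cox-form 10-year composite ASCVD risk equation
(China-PAR style)::

    risk10 = 1 - S0 ** exp(LP - mean_LP)

where ``LP`` is a per-sex linear predictor over named covariates, ``S0`` the
per-sex baseline 10-year survival and ``mean_LP`` the population-mean linear
predictor.  The 10-year risk is converted to an annual probability with the
DEALE constant-hazard identity, split into CHD vs stroke by fixed shares
(29.46% / 70.54%), and treatment effects are applied on the odds scale.

Coefficient sets are pluggable via a JSON schema (named covariates, per-sex
blocks with ``coefficients``, ``s0_10yr`` and ``mean_lp``); the packaged
default is a *synthetic* China-PAR-style calibration, see
:func:`ascvdsim.defaults.default_risk_coefficients`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConfigurationError, DomainError, StateError
from .tables import SexAgeBandTable

if TYPE_CHECKING:  # pragma: no cover
    from .population import IndividualProfile

__all__ = [
    "CHD",
    "STROKE",
    "SexCoefficientBlock",
    "RiskCoefficients",
    "EventParameters",
    "ten_year_ascvd_risk",
    "ten_year_risk_arrays",
    "deale_annual_probability",
    "annual_rate_from_ten_year",
    "apply_odds_ratio",
    "split_event_type",
    "case_fatality",
    "covariate_arrays",
]

CHD = "CHD"
STROKE = "stroke"

#: How each named covariate is computed from profile fields.  Antihypertensive
#: treatment status switches SBP between the treated/untreated coefficients,
#: mirroring the published risk equation's treated-SBP interaction.
_COVARIATE_BUILDERS = {
    "age": lambda f: f["age"],
    "sbp": lambda f: f["sbp"],
    "sbp_untreated": lambda f: f["sbp"] * (1.0 - f["antihtn"]),
    "sbp_treated": lambda f: f["sbp"] * f["antihtn"],
    "tc": lambda f: f["tc"],
    "hdl": lambda f: f["hdl"],
    "ldl": lambda f: f["ldl"],
    "wc": lambda f: f["wc"],
    "smoker": lambda f: f["smoker"],
    "diabetes": lambda f: f["diabetes"],
    "antihtn": lambda f: f["antihtn"],
}


def covariate_arrays(fields: dict, names) -> dict:
    """Build the named covariates the coefficient file declares.

    ``fields`` maps profile field names to scalars or arrays; unknown
    covariate names raise :class:`ConfigurationError` naming the offender.
    """
    farr = {k: np.asarray(v, dtype=float) for k, v in fields.items()}
    out = {}
    for name in names:
        try:
            builder = _COVARIATE_BUILDERS[name]
        except KeyError:
            raise ConfigurationError(
                f"covariate {name!r} in coefficient file cannot be computed from an individual profile"
            ) from None
        out[name] = np.asarray(builder(farr), dtype=float)
    return out


@dataclass(frozen=True)
class SexCoefficientBlock:
    coefficients: dict
    s0_10yr: float
    mean_lp: float

    def __post_init__(self):
        # s0 = 0 (certain event within 10 years) is a valid degenerate case
        if not (0.0 <= self.s0_10yr <= 1.0):
            raise ConfigurationError(f"baseline 10-year survival must be in [0, 1], got {self.s0_10yr}")
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"coefficient {k!r} is not finite")

    def linear_predictor(self, covariates: dict):
        lp = 0.0
        for name, beta in self.coefficients.items():
            lp = lp + beta * covariates[name]
        return lp


@dataclass(frozen=True)
class RiskCoefficients:
    """Per-sex Cox-form risk coefficient set."""

    male: SexCoefficientBlock
    female: SexCoefficientBlock
    name: str = "unnamed"
    version: str = "0"

    @property
    def covariate_names(self):
        return tuple(self.male.coefficients)

    @classmethod
    def from_mapping(cls, payload: dict) -> "RiskCoefficients":
        try:
            blocks = {
                sex: SexCoefficientBlock(
                    coefficients=dict(payload[sex]["coefficients"]),
                    s0_10yr=float(payload[sex]["s0_10yr"]),
                    mean_lp=float(payload[sex]["mean_lp"]),
                )
                for sex in ("male", "female")
            }
        except KeyError as exc:
            raise ConfigurationError(f"coefficient file missing required field: {exc}") from None
        # validate covariate names eagerly so load fails, not the first cycle
        covariate_arrays({k: 1.0 for k in ("age", "sbp", "tc", "hdl", "ldl", "wc", "smoker", "diabetes", "antihtn")},
                         set(blocks["male"].coefficients) | set(blocks["female"].coefficients))
        return cls(
            male=blocks["male"],
            female=blocks["female"],
            name=str(payload.get("name", "unnamed")),
            version=str(payload.get("version", "0")),
        )

    @classmethod
    def from_json(cls, path) -> "RiskCoefficients":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))

    def to_mapping(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "male": {"coefficients": dict(self.male.coefficients), "s0_10yr": self.male.s0_10yr,
                     "mean_lp": self.male.mean_lp},
            "female": {"coefficients": dict(self.female.coefficients), "s0_10yr": self.female.s0_10yr,
                       "mean_lp": self.female.mean_lp},
        }


@dataclass(frozen=True)
class EventParameters:
    """Event-splitting, fatality, mortality and treatment-effect parameters.

    ``chd_share`` and ``1 - chd_share`` are the fixed shares by which a
    composite ASCVD event is classified CHD vs stroke; case fatality is an
    event-type x sex x age-band lookup; post-event survivors face
    ``post_event_mortality_multiplier`` times the background all-cause
    mortality; statin odds ratios act on annual CHD / stroke / diabetes
    probabilities.
    """

    chd_share: float = 0.2946
    case_fatality_chd: SexAgeBandTable = None
    case_fatality_stroke: SexAgeBandTable = None
    background_mortality: SexAgeBandTable = None
    diabetes_incidence: SexAgeBandTable = None
    post_event_mortality_multiplier: float = 2.0
    or_chd: float = 0.70
    or_stroke: float = 0.81
    or_diabetes: float = 1.21

    def __post_init__(self):
        if not (0.0 <= self.chd_share <= 1.0):
            raise ConfigurationError("chd_share must lie in [0, 1]")
        for name in ("or_chd", "or_stroke", "or_diabetes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.post_event_mortality_multiplier < 0:
            raise ConfigurationError("post-event mortality multiplier must be >= 0")

    @property
    def stroke_share(self) -> float:
        return 1.0 - self.chd_share


def _profile_fields(profile: "IndividualProfile") -> dict:
    return {
        "age": float(profile.age),
        "sbp": float(profile.sbp),
        "tc": float(profile.tc),
        "hdl": float(profile.hdl),
        "ldl": float(profile.ldl),
        "wc": float(profile.wc),
        "smoker": float(profile.smoker),
        "diabetes": float(profile.diabetes_rf),
        "antihtn": float(profile.antihtn),
    }


def ten_year_risk_arrays(fields: dict, male_mask, coef: RiskCoefficients):
    """Vectorised 10-year composite ASCVD risk for arrays of profile fields."""
    m = np.asarray(male_mask, dtype=bool)
    cov = covariate_arrays(fields, coef.covariate_names)
    n = np.broadcast(*cov.values()).shape if cov else ()
    lp_m = coef.male.linear_predictor(cov)
    lp_f = coef.female.linear_predictor(cov)
    rel_m = np.exp(np.asarray(lp_m, dtype=float) - coef.male.mean_lp)
    rel_f = np.exp(np.asarray(lp_f, dtype=float) - coef.female.mean_lp)
    risk = np.where(m, 1.0 - coef.male.s0_10yr ** rel_m, 1.0 - coef.female.s0_10yr ** rel_f)
    return np.clip(risk, 0.0, 1.0)


def ten_year_ascvd_risk(profile: "IndividualProfile", coef: RiskCoefficients) -> float:
    """10-year composite ASCVD risk for one event-free individual.

    Primary-prevention equation: the profile must be alive and event-free.
    """
    if profile.health_state == "dead":
        raise StateError("cannot compute ASCVD risk for a dead profile")
    if profile.health_state != "event-free":
        raise StateError("the 10-year risk equation applies to event-free (primary prevention) profiles")
    risk = ten_year_risk_arrays(_profile_fields(profile), profile.is_male, coef)
    return float(risk)


def deale_annual_probability(p10):
    """Convert a 10-year probability to a 1-year probability, constant hazard.

    ``p1 = 1 - (1 - p10)**(1/10)``; algebraically identical to converting to
    a rate ``-ln(1-p10)/10`` and back.
    """
    p = np.asarray(p10, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("10-year probability must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** 0.1
    return float(out) if np.isscalar(p10) else out


def annual_rate_from_ten_year(p10) -> float:
    """Constant hazard rate implied by a 10-year probability (utility helper)."""
    p = np.asarray(p10, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise DomainError("10-year probability must lie in [0, 1) for a finite rate")
    out = -np.log(1.0 - p) / 10.0
    return float(out) if np.isscalar(p10) else out


def apply_odds_ratio(p, or_value):
    """Adjust a probability by an odds ratio: ``p' = OR*odds / (1 + OR*odds)``.

    ``p = 1`` is a fixed point (infinite odds stay infinite).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("probability must lie in [0, 1]")
    if np.any(np.asarray(or_value) <= 0):
        raise DomainError("odds ratio must be positive")
    with np.errstate(divide="ignore"):
        odds = np.where(arr < 1.0, arr / (1.0 - arr), np.inf) * or_value
    out = np.full(np.shape(odds), 1.0)
    finite = np.isfinite(odds)
    np.divide(odds, 1.0 + odds, out=out, where=finite)
    return float(out) if (np.isscalar(p) and np.isscalar(or_value)) else out


def split_event_type(u, chd_share: float = 0.2946):
    """Classify a composite ASCVD event as CHD or stroke from a uniform draw.

    Deterministic given ``u``: CHD iff ``u < chd_share``.
    """
    if not (0.0 <= chd_share <= 1.0):
        raise DomainError("chd_share must lie in [0, 1]")
    u_arr = np.asarray(u, dtype=float)
    if np.isscalar(u):
        return CHD if u < chd_share else STROKE
    return np.where(u_arr < chd_share, CHD, STROKE)


def case_fatality(event: str, sex: str, age: float, params: EventParameters) -> float:
    """Probability an incident event of ``event`` type is fatal, by sex and age band."""
    if event == CHD:
        table = params.case_fatality_chd
    elif event == STROKE:
        table = params.case_fatality_stroke
    else:
        raise DomainError(f"unknown event type {event!r}")
    male = sex in ("male", "M")
    if not male and sex not in ("female", "F"):
        raise DomainError(f"unknown sex {sex!r}")
    return float(table.lookup(male, float(age)))
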