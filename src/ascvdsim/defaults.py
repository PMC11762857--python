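"""Packaged default parameters.

Everything here is overridable; the defaults pin down one coherent,
documented baseline:

* Table-driven clinical/economic parameters (case fatality by age band,
  costs, disutilities, odds ratios, the 29.46/70.54 CHD/stroke event split,
  3% discounting, the 40% first-year discontinuation) use the published point
  values.
* Quantities that in applied use come from restricted survey microdata or
  national reference tables — the risk-equation coefficients, background
  all-cause mortality, age-specific EQ-5D utility weights, annual diabetes
  incidence, and the baseline cohort marginals — ship as clearly labelled
  *synthetic* stand-ins with literature-plausible values for middle-aged and
  elderly Chinese adults.  See docs/methods.md for the rationale behind each
  value.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .economics import CostParameters, UtilityParameters
from .engine import ParameterSet
from .population import AgeTrendModel, ContinuousSpec, PopulationConfig, SexMarginals
from .risk import EventParameters, RiskCoefficients
from .tables import AgeBandTable, SexAgeBandTable

__all__ = [
    "default_risk_coefficients",
    "default_event_parameters",
    "default_cost_parameters",
    "default_utility_parameters",
    "default_age_trends",
    "default_population_config",
    "default_parameter_set",
    "toy_risk_coefficients",
]

# case fatality by event type, sex and age band (men, women per band);
# the published table stops at 75-84, ages 85-89 reuse the top band
_CF_BANDS = [(34, 44), (45, 54), (55, 64), (65, 74), (75, 84)]
_CF_CHD_M = [0.12, 0.21, 0.29, 0.33, 0.48]
_CF_CHD_F = [0.18, 0.23, 0.27, 0.43, 0.51]
_CF_STROKE_M = [0.25, 0.18, 0.12, 0.20, 0.45]
_CF_STROKE_F = [0.18, 0.14, 0.15, 0.20, 0.45]


def default_risk_coefficients() -> RiskCoefficients:
    """Synthetic China-PAR-style coefficient set (packaged JSON).

    The published equation's coefficients are not reproduced here; this file
    is a synthetic calibration with the same Cox functional form, covariates
    and plausible effect magnitudes, suitable for exercising and testing the
    pipeline.  Swap in a transcription of the published coefficients via
    :meth:`RiskCoefficients.from_json` for applied use.
    """
    payload = json.loads(
        resources.files("ascvdsim.data").joinpath("china_par_style_synthetic.json").read_text()
    )
    return RiskCoefficients.from_mapping(payload)


def toy_risk_coefficients(p10: float = 0.1) -> RiskCoefficients:
    """All-zero coefficient set giving every profile the same 10-year risk.

    With all coefficients zero the relative hazard is exactly 1 and the
    10-year risk is ``1 - S0`` for everyone — the documented toy set used in
    unit tests and constant-hazard oracles.
    """
    from .risk import SexCoefficientBlock

    zero = {k: 0.0 for k in ("age", "sbp_untreated", "sbp_treated", "tc", "hdl", "wc", "smoker", "diabetes")}
    block = SexCoefficientBlock(coefficients=zero, s0_10yr=1.0 - p10, mean_lp=0.0)
    return RiskCoefficients(male=block, female=block, name="toy-constant-risk", version="1")


def _gompertz_mortality(a: float, b: float) -> AgeBandTable:
    ages = np.arange(40, 90)
    q = np.clip(a * np.exp(b * ages), 0.0, 1.0)
    return AgeBandTable(ages.astype(float), ages.astype(float), q)


def default_background_mortality() -> SexAgeBandTable:
    """Synthetic Gompertz life table approximating Chinese adult all-cause mortality.

    Calibrated to plausible anchor rates (men: ~0.002 at 40, ~0.06 at 80;
    women: ~0.001 at 40, ~0.04 at 80); a stand-in for a national life table,
    replaceable via the table-CSV interface.
    """
    # male: q40=0.002, q80=0.06  => b = ln(30)/40; female: q40=0.001, q80=0.04
    b_m = np.log(30.0) / 40.0
    a_m = 0.002 / np.exp(b_m * 40.0)
    b_f = np.log(40.0) / 40.0
    a_f = 0.001 / np.exp(b_f * 40.0)
    return SexAgeBandTable(male=_gompertz_mortality(a_m, b_m), female=_gompertz_mortality(a_f, b_f))


def default_diabetes_incidence() -> SexAgeBandTable:
    """Synthetic annual type-2 diabetes incidence by age (per year, both sexes).

    Rises from ~0.4%/yr at 40 to ~1.2%/yr at 70+, a plausible shape for the
    target population; stands in for the supplementary incidence table.
    """
    bands = [(40, 49), (50, 59), (60, 69), (70, 89)]
    values = [0.004, 0.007, 0.010, 0.012]
    return SexAgeBandTable.from_bands(bands, values, values)


def default_age_utility_weights() -> SexAgeBandTable:
    """Synthetic age-specific EQ-5D utility weights (Chinese population norms shape)."""
    bands = [(40, 49), (50, 59), (60, 69), (70, 79), (80, 89)]
    male = [0.96, 0.94, 0.92, 0.87, 0.82]
    female = [0.95, 0.93, 0.90, 0.85, 0.80]
    return SexAgeBandTable.from_bands(bands, male, female)


def default_event_parameters() -> EventParameters:
    return EventParameters(
        chd_share=0.2946,
        case_fatality_chd=SexAgeBandTable.from_bands(_CF_BANDS, _CF_CHD_M, _CF_CHD_F, extend_upper=True),
        case_fatality_stroke=SexAgeBandTable.from_bands(_CF_BANDS, _CF_STROKE_M, _CF_STROKE_F, extend_upper=True),
        background_mortality=default_background_mortality(),
        diabetes_incidence=default_diabetes_incidence(),
        post_event_mortality_multiplier=2.0,
        or_chd=0.70,
        or_stroke=0.81,
        or_diabetes=1.21,
    )


def default_cost_parameters() -> CostParameters:
    return CostParameters()


def default_utility_parameters() -> UtilityParameters:
    return UtilityParameters(age_weights=default_age_utility_weights())


def default_age_trends() -> AgeTrendModel:
    """Synthetic cross-sectional age slopes for the five drifting factors.

    Units per year of age: SBP +0.5 mmHg, TC +0.010 mmol/L, HDL-C -0.002
    mmol/L, LDL-C +0.005 mmol/L, WC +0.10 cm, with slightly steeper SBP in
    women — plausible magnitudes for middle-aged/elderly Chinese adults.
    """
    male = {"sbp": 0.50, "tc": 0.010, "hdl": -0.002, "ldl": 0.005, "wc": 0.10}
    female = {"sbp": 0.60, "tc": 0.012, "hdl": -0.002, "ldl": 0.006, "wc": 0.10}
    return AgeTrendModel(male_slopes=male, female_slopes=female, residual_sd=0.0)


def default_population_config(min_age: int = 45) -> PopulationConfig:
    """Synthetic baseline-cohort marginals (middle-aged/elderly Chinese adults).

    The generator starts at 45 by default (the analysed survey excluded
    younger respondents) but accepts 40, the model's lower age bound.
    """
    male = SexMarginals(
        age=ContinuousSpec(59.0, 9.5, float(min_age), 89.0),
        sbp=ContinuousSpec(132.0, 18.0, 80.0, 230.0),
        tc=ContinuousSpec(4.70, 0.90, 2.0, 10.0),
        hdl=ContinuousSpec(1.25, 0.30, 0.4, 3.0),
        ldl=ContinuousSpec(2.70, 0.80, 0.5, 7.0),
        wc=ContinuousSpec(86.0, 10.0, 55.0, 130.0),
        smoking_prevalence=0.46,
        diabetes_prevalence=0.10,
        antihtn_prevalence=0.15,
    )
    female = SexMarginals(
        age=ContinuousSpec(59.0, 9.5, float(min_age), 89.0),
        sbp=ContinuousSpec(130.0, 20.0, 80.0, 230.0),
        tc=ContinuousSpec(5.00, 1.00, 2.0, 10.0),
        hdl=ContinuousSpec(1.35, 0.32, 0.4, 3.0),
        ldl=ContinuousSpec(2.90, 0.85, 0.5, 7.0),
        wc=ContinuousSpec(84.0, 10.5, 55.0, 130.0),
        smoking_prevalence=0.05,
        diabetes_prevalence=0.12,
        antihtn_prevalence=0.18,
    )
    return PopulationConfig(male=male, female=female, male_fraction=0.47)


def default_parameter_set(discount_rate: float = 0.03) -> ParameterSet:
    return ParameterSet(
        coefficients=default_risk_coefficients(),
        events=default_event_parameters(),
        costs=default_cost_parameters(),
        utilities=default_utility_parameters(),
        trends=default_age_trends(),
        discount_rate=discount_rate,
    )
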