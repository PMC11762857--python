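import numpy as np
import pandas as pd
import pytest

import ascvdsim as a
from ascvdsim.economics import CostParameters, UtilityParameters
from ascvdsim.engine import ParameterSet
from ascvdsim.population import AgeTrendModel, IndividualProfile
from ascvdsim.risk import EventParameters
from ascvdsim.tables import SexAgeBandTable

ZERO_SLOPES = {f: 0.0 for f in ("sbp", "tc", "hdl", "ldl", "wc")}


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return a.default_parameter_set()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return a.generate_cohort(200, a.default_population_config(), seed=123)


@pytest.fixture
def profile() -> IndividualProfile:
    return IndividualProfile(
        id=0, age=55, sex="M", sbp=130.0, tc=4.8, hdl=1.2, ldl=2.8, wc=88.0,
        smoker=True, diabetes=False, antihtn=False,
    )


def constant_hazard_params(*, p10: float, fatality_chd: float, fatality_stroke: float,
                           q_background: float, age_weight: float = 0.9,
                           diabetes_incidence: float = 0.0,
                           discount_rate: float = 0.03,
                           post_event_multiplier: float = 2.0) -> ParameterSet:
    """A degenerate parameter set: every profile has the same hazards, no drift."""
    ev = EventParameters(
        case_fatality_chd=SexAgeBandTable.constant(fatality_chd),
        case_fatality_stroke=SexAgeBandTable.constant(fatality_stroke),
        background_mortality=SexAgeBandTable.constant(q_background),
        diabetes_incidence=SexAgeBandTable.constant(diabetes_incidence),
        post_event_mortality_multiplier=post_event_multiplier,
    )
    return ParameterSet(
        coefficients=a.toy_risk_coefficients(p10),
        events=ev,
        costs=CostParameters(),
        utilities=UtilityParameters(age_weights=SexAgeBandTable.constant(age_weight)),
        trends=AgeTrendModel(male_slopes=dict(ZERO_SLOPES), female_slopes=dict(ZERO_SLOPES)),
        discount_rate=discount_rate,
    )


def uniform_cohort(n: int, age: int = 60, sex: str = "M") -> pd.DataFrame:
    """n identical event-free individuals (for constant-hazard oracles)."""
    return pd.DataFrame({
        "id": np.arange(n), "age": age, "sex": sex, "sbp": 120.0, "tc": 4.5,
        "hdl": 1.2, "ldl": 2.5, "wc": 85.0, "smoker": False, "diabetes": False,
        "antihtn": False,
    })
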