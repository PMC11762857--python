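"""Synthetic baseline cohorts and age trends of risk factors.

The generator stands in for restricted survey microdata of middle-aged and
elderly Chinese adults: per-sex marginal distributions for age, SBP, TC,
HDL-C, LDL-C and waist circumference (truncated Gaussians, optionally with a
Gaussian correlation structure), plus smoking / diabetes / antihypertensive
prevalences.  Risk factors drift linearly with age (slope per year from
cross-sectional regression); the drift is deterministic by default.

Cohorts are plain :class:`pandas.DataFrame` objects with canonical columns
``id, age, sex, sbp, tc, hdl, ldl, wc, smoker, diabetes, antihtn`` (sex
encoded ``"M"``/``"F"``); :class:`IndividualProfile` is the scalar view used
by the per-individual simulation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError

__all__ = [
    "MIN_MODEL_AGE",
    "MAX_MODEL_AGE",
    "ContinuousSpec",
    "SexMarginals",
    "PopulationConfig",
    "AgeTrendModel",
    "IndividualProfile",
    "TREND_FACTORS",
    "DEFAULT_FACTOR_FLOORS",
    "generate_cohort",
    "project_risk_factors",
    "project_cohort_arrays",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_profiles",
    "profile_from_row",
]

MIN_MODEL_AGE = 40
MAX_MODEL_AGE = 89

#: risk factors subject to linear age trends (exactly these five)
TREND_FACTORS = ("hdl", "ldl", "tc", "sbp", "wc")

#: clinically plausible floors that keep the risk equation finite under
#: decades of linear drift
DEFAULT_FACTOR_FLOORS = {"hdl": 0.3, "ldl": 0.3, "tc": 1.0, "sbp": 70.0, "wc": 40.0}

COHORT_COLUMNS = ["id", "age", "sex", "sbp", "tc", "hdl", "ldl", "wc", "smoker", "diabetes", "antihtn"]


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated-Gaussian marginal: mean, SD and hard bounds."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ConfigurationError(f"distribution mean must be finite and positive, got {self.mean}")
        if self.sd < 0 or not np.isfinite(self.sd):
            raise ConfigurationError(f"distribution sd must be finite and >= 0, got {self.sd}")
        if self.lower >= self.upper:
            raise ConfigurationError("distribution lower bound must be below upper bound")


#: order in which continuous factors enter the correlation matrix
CONTINUOUS_FACTORS = ("age", "sbp", "tc", "hdl", "ldl", "wc")


@dataclass(frozen=True)
class SexMarginals:
    age: ContinuousSpec
    sbp: ContinuousSpec
    tc: ContinuousSpec
    hdl: ContinuousSpec
    ldl: ContinuousSpec
    wc: ContinuousSpec
    smoking_prevalence: float
    diabetes_prevalence: float
    antihtn_prevalence: float

    def __post_init__(self):
        for name in ("smoking_prevalence", "diabetes_prevalence", "antihtn_prevalence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PopulationConfig:
    """Marginals + correlation structure defining the baseline cohort."""

    male: SexMarginals
    female: SexMarginals
    male_fraction: float = 0.47
    correlation: np.ndarray | None = None  # over CONTINUOUS_FACTORS; None = independence

    def __post_init__(self):
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(CONTINUOUS_FACTORS)
            if c.shape != (k, k):
                raise ConfigurationError(f"correlation matrix must be {k}x{k} over {CONTINUOUS_FACTORS}")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigurationError("correlation matrix must be symmetric")
            eigvals = np.linalg.eigvalsh(c)
            if eigvals.min() < -1e-10:
                raise ConfigurationError("correlation matrix must be positive semi-definite")
            object.__setattr__(self, "correlation", c)


@dataclass(frozen=True)
class AgeTrendModel:
    """Per-sex linear age trends for the five drifting risk factors.

    ``slopes[sex][factor]`` is in factor units per year of age; an optional
    residual SD adds Gaussian noise around the drift (default 0: purely
    deterministic trajectories).  Factor floors guard against impossible
    values after decades of drift.
    """

    male_slopes: dict
    female_slopes: dict
    residual_sd: float = 0.0
    floors: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_FLOORS))

    def __post_init__(self):
        for name, slopes in (("male", self.male_slopes), ("female", self.female_slopes)):
            if set(slopes) != set(TREND_FACTORS):
                raise ConfigurationError(
                    f"{name} age-trend slopes must cover exactly {sorted(TREND_FACTORS)}, got {sorted(slopes)}"
                )
            for f, s in slopes.items():
                if not np.isfinite(s):
                    raise ConfigurationError(f"{name} slope for {f!r} is not finite")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")

    def slopes_for(self, male: bool) -> dict:
        return self.male_slopes if male else self.female_slopes


@dataclass
class IndividualProfile:
    """One simulated person: risk factors plus disease / treatment state."""

    id: int
    age: float
    sex: str  # "M" / "F"
    sbp: float
    tc: float
    hdl: float
    ldl: float
    wc: float
    smoker: bool
    diabetes: bool
    antihtn: bool
    statin_induced_diabetes: bool = False
    health_state: str = "event-free"  # event-free / post-CHD / post-stroke / dead
    treatment_state: str = "never"  # never / on-statin / discontinued
    years_since_event: int | None = None
    treated_years: int = 0
    diabetes_rf: bool | None = None  # diabetes as seen by the risk equation

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ConfigurationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        # MAX_MODEL_AGE + 1 is permitted transiently: it marks exit at the age cap
        if self.health_state != "dead" and not (MIN_MODEL_AGE <= self.age <= MAX_MODEL_AGE + 1):
            raise ConfigurationError(
                f"age must lie in [{MIN_MODEL_AGE}, {MAX_MODEL_AGE}] while alive, got {self.age}"
            )
        for f in ("sbp", "tc", "hdl", "ldl", "wc"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be positive")
        if self.statin_induced_diabetes and not self.diabetes:
            raise ConfigurationError("statin-induced-diabetes flag implies the diabetes flag")
        if self.diabetes_rf is None:
            # statin-attributable diabetes never enters the risk equation
            self.diabetes_rf = bool(self.diabetes and not self.statin_induced_diabetes)

    @property
    def is_male(self) -> bool:
        return self.sex == "M"

    @property
    def alive(self) -> bool:
        return self.health_state != "dead"


def _sample_sex_block(n: int, marg: SexMarginals, corr, rng: np.random.Generator) -> dict:
    k = len(CONTINUOUS_FACTORS)
    if corr is None:
        z = rng.standard_normal((n, k))
    else:
        # Gaussian copula via Cholesky of the (regularised) correlation
        try:
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(f"correlation matrix is not usable: {exc}") from exc
        z = rng.standard_normal((n, k)) @ chol.T
    out = {}
    for j, name in enumerate(CONTINUOUS_FACTORS):
        spec: ContinuousSpec = getattr(marg, name)
        out[name] = np.clip(spec.mean + spec.sd * z[:, j], spec.lower, spec.upper)
    out["smoker"] = rng.random(n) < marg.smoking_prevalence
    out["diabetes"] = rng.random(n) < marg.diabetes_prevalence
    out["antihtn"] = rng.random(n) < marg.antihtn_prevalence
    return out


def generate_cohort(n: int, config: PopulationConfig, seed: int) -> pd.DataFrame:
    """Generate ``n`` baseline individuals, all event-free and never-treated.

    A pure function of ``(n, config, seed)``: identical arguments give a
    bit-identical cohort.
    """
    if n < 0:
        raise ConfigurationError(f"cohort size must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    male = rng.random(n) < config.male_fraction
    n_m = int(male.sum())
    n_f = n - n_m
    block_m = _sample_sex_block(n_m, config.male, config.correlation, rng)
    block_f = _sample_sex_block(n_f, config.female, config.correlation, rng)
    cols = {}
    for name in list(CONTINUOUS_FACTORS) + ["smoker", "diabetes", "antihtn"]:
        arr = np.empty(n, dtype=float if name in CONTINUOUS_FACTORS else bool)
        arr[male] = block_m[name]
        arr[~male] = block_f[name]
        cols[name] = arr
    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age": np.floor(cols["age"]).astype(np.int64) if n else np.array([], dtype=np.int64),
            "sex": np.where(male, "M", "F"),
            "sbp": cols["sbp"],
            "tc": cols["tc"],
            "hdl": cols["hdl"],
            "ldl": cols["ldl"],
            "wc": cols["wc"],
            "smoker": cols["smoker"].astype(bool) if n else np.array([], dtype=bool),
            "diabetes": cols["diabetes"].astype(bool) if n else np.array([], dtype=bool),
            "antihtn": cols["antihtn"].astype(bool) if n else np.array([], dtype=bool),
        }
    )
    return df


def project_risk_factors(profile: IndividualProfile, trends: AgeTrendModel,
                         rng: np.random.Generator | None = None) -> IndividualProfile:
    """Advance a living profile by one year of age-driven risk-factor drift.

    Each of the five drifting factors is incremented by its sex-specific
    slope (plus optional Gaussian residual), floored, and age is incremented
    by one year.
    """
    if not profile.alive:
        raise StateError("cannot project risk factors of a dead profile")
    slopes = trends.slopes_for(profile.is_male)
    updates = {}
    for f in TREND_FACTORS:
        value = getattr(profile, f) + slopes[f]
        if trends.residual_sd > 0:
            if rng is None:
                raise ConfigurationError("residual_sd > 0 requires an rng")
            value += trends.residual_sd * rng.standard_normal()
        updates[f] = max(value, trends.floors.get(f, 0.0))
    updates["age"] = profile.age + 1
    return replace(profile, **updates)


def project_cohort_arrays(fields: dict, male_mask, trends: AgeTrendModel,
                          rng: np.random.Generator | None = None) -> None:
    """In-place vectorised counterpart of :func:`project_risk_factors`.

    ``fields`` maps factor name -> float array; only the five trend factors
    are touched (age is managed by the caller).
    """
    m = np.asarray(male_mask, dtype=bool)
    for f in TREND_FACTORS:
        arr = fields[f]
        drift = np.where(m, trends.male_slopes[f], trends.female_slopes[f])
        arr += drift
        if trends.residual_sd > 0:
            if rng is None:
                raise ConfigurationError("residual_sd > 0 requires an rng")
            arr += trends.residual_sd * rng.standard_normal(arr.shape)
        np.maximum(arr, trends.floors.get(f, 0.0), out=arr)


def cohort_to_profiles(df: pd.DataFrame) -> list[IndividualProfile]:
    return [profile_from_row(row) for row in df.itertuples(index=False)]


def profile_from_row(row) -> IndividualProfile:
    return IndividualProfile(
        id=int(row.id), age=float(row.age), sex=str(row.sex), sbp=float(row.sbp),
        tc=float(row.tc), hdl=float(row.hdl), ldl=float(row.ldl), wc=float(row.wc),
        smoker=bool(row.smoker), diabetes=bool(row.diabetes), antihtn=bool(row.antihtn),
    )


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    out = cohort[COHORT_COLUMNS].copy()
    for c in ("smoker", "diabetes", "antihtn"):
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"cohort CSV missing columns: {sorted(missing)}")
    df = df[COHORT_COLUMNS].copy()
    for c in ("smoker", "diabetes", "antihtn"):
        df[c] = df[c].astype(bool)
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise ConfigurationError(f"cohort CSV has invalid sex codes: {df.loc[bad_sex, 'sex'].unique()}")
    return df
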