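"""Deterministic and probabilistic sensitivity analysis, plus model validation.

One-way DSA re-runs the frontier with a single parameter at its low/high
bound (common random numbers, all else at base) and reports the target ICER
range; the PSA draws full parameter vectors from the assigned distributions
(beta / gamma by method of moments, lognormal for odds ratios via the delta
method) and re-runs all strategies per draw, feeding the CEAC.

Validation mirrors the published procedures: internal validity as the R² of
simulated vs analytically expected 1-year event frequencies across age-sex
groups; external validity as a side-by-side report against a user-supplied
reference table (no pass/fail).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEFrontier, icer_ladder
from .engine import ParameterSet, StrategyResult, run_strategy
from .errors import ConfigurationError, DomainError
from .risk import CHD, STROKE, deale_annual_probability, ten_year_risk_arrays

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "DSARow",
    "default_psa_specs",
    "default_dsa_ranges",
    "sample_parameters",
    "apply_draw",
    "run_psa",
    "one_way_dsa",
    "internal_validation",
    "external_validation",
]

_FAMILIES = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA distribution: family, point value, standard error, DSA bounds."""

    family: str
    value: float
    se: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.se is not None and self.se < 0:
            raise ConfigurationError("standard error must be >= 0")
        if self.family == "beta" and not (0.0 < self.value < 1.0) and self.se:
            raise ConfigurationError("beta family needs a point value strictly inside (0, 1)")

    def effective_family(self) -> str:
        """Families that need an SE degrade to fixed when none is given."""
        if self.family != "fixed" and (self.se is None or self.se == 0.0):
            return "fixed"
        return self.family

    def sample(self, rng: np.random.Generator, size=None):
        fam = self.effective_family()
        if fam != self.family:
            warnings.warn(
                f"distribution {self.family!r} for value {self.value} has no standard error; "
                "sampling as fixed", stacklevel=2,
            )
        m, s = self.value, self.se
        if fam == "fixed":
            return np.full(size, m) if size is not None else m
        if fam == "beta":
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:
                raise ConfigurationError(f"beta moments (value={m}, se={s}) are infeasible")
            return rng.beta(m * nu, (1.0 - m) * nu, size=size)
        if fam == "gamma":
            shape = (m / s) ** 2
            scale = s**2 / m
            return rng.gamma(shape, scale, size=size)
        # lognormal: ln-scale sigma from the printed SE via the delta method,
        # mu chosen so the arithmetic mean equals the point value
        sigma = s / m
        mu = np.log(m) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, size=size)

    def dsa_bounds(self) -> tuple[float, float]:
        """One-way range: explicit bounds, else value +/- 1.96 SE, else +/-20%."""
        if self.low is not None and self.high is not None:
            return self.low, self.high
        if self.se:
            lo, hi = self.value - 1.96 * self.se, self.value + 1.96 * self.se
            if self.family == "beta":
                lo, hi = max(lo, 1e-9), min(hi, 1.0 - 1e-9)
            else:
                lo = max(lo, 1e-9)
            return lo, hi
        return 0.8 * self.value, 1.2 * self.value


def default_psa_specs() -> dict:
    """The published parameter-distribution table as dotted-path specs.

    Costs carry a Gamma family and the diabetes odds ratio a Beta family with
    no printed standard errors; per the sampling contract these fall back to
    fixed (with a warning) unless an SE or explicit bounds are supplied.
    """
    return {
        "utilities.acute_chd": DistributionSpec("beta", 0.439, 0.018),
        "utilities.acute_stroke": DistributionSpec("beta", 0.92, 0.04),
        "utilities.longterm_ami": DistributionSpec("beta", 0.107, 0.019),
        "utilities.longterm_stroke": DistributionSpec("beta", 0.266, 0.02),
        "events.or_chd": DistributionSpec("lognormal", 0.70, 0.072),
        "events.or_stroke": DistributionSpec("lognormal", 0.81, 0.069),
        "events.or_diabetes": DistributionSpec("beta", 1.21, None),
        "costs.statin_annual": DistributionSpec("gamma", 1_149.75, None),
        "costs.hospitalization_ami": DistributionSpec("gamma", 22_611.0, None),
        "costs.hospitalization_stroke": DistributionSpec("gamma", 13_983.0, None),
        "costs.first_year_ami": DistributionSpec("gamma", 5_255.85, None),
        "costs.first_year_stroke": DistributionSpec("gamma", 2_652.0, None),
        "costs.office_visit_ami": DistributionSpec("gamma", 585.87, None),
        "costs.office_visit_stroke": DistributionSpec("gamma", 565.0, None),
    }


def default_dsa_ranges() -> dict:
    """One-way ranges for the parameters the univariate analysis focuses on."""
    specs = default_psa_specs()
    focus = ["events.or_chd", "events.or_stroke", "events.or_diabetes",
             "costs.statin_annual"]
    return {name: specs[name].dsa_bounds() for name in focus}


def sample_parameters(specs: dict, seed: int) -> dict:
    """Draw one parameter vector; deterministic given (specs, seed)."""
    rng = np.random.default_rng(seed)
    return {name: float(spec.sample(rng)) for name, spec in sorted(specs.items())}


def _set_dotted(params: ParameterSet, path: str, value: float) -> ParameterSet:
    try:
        group_name, attr = path.split(".", 1)
        group = getattr(params, group_name)
        if not hasattr(group, attr):
            raise AttributeError(attr)
    except (ValueError, AttributeError):
        raise ConfigurationError(f"unknown parameter path {path!r}") from None
    return replace(params, **{group_name: replace(group, **{attr: value})})


def apply_draw(params: ParameterSet, draw: dict) -> ParameterSet:
    out = params
    for path, value in draw.items():
        out = _set_dotted(out, path, value)
    return out


@dataclass(frozen=True)
class PSAResult:
    names: tuple
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    draws: pd.DataFrame  # per-draw sampled parameters
    seed: int
    sim_seed: int = 0  # the shared simulation seed (common random numbers)

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def probability_optimal(self, wtp: float) -> dict:
        nmb = wtp * self.qalys - self.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        return dict(zip(self.names, weights.mean(axis=0)))


def run_psa(cohort: pd.DataFrame, strategies, specs: dict, params: ParameterSet,
            n_draws: int = 1000, seed: int = 0, **run_kwargs) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples one parameter vector, holds it fixed across strategies
    and individuals, and re-runs every strategy with common random numbers
    (simulation seed shared within and across draws, so only parameter
    uncertainty varies across draws).
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    ss = np.random.SeedSequence(seed)
    param_seeds = ss.spawn(n_draws)
    sim_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    names = tuple(s.name for s in strategies)
    costs = np.empty((n_draws, len(strategies)))
    qalys = np.empty((n_draws, len(strategies)))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixed-fallback warning, once is enough
        for d in range(n_draws):
            draw_seed = int(param_seeds[d].generate_state(1)[0] % (2**31))
            draw = sample_parameters(specs, draw_seed)
            p_d = apply_draw(params, draw)
            for j, strat in enumerate(strategies):
                res = run_strategy(cohort, strat, p_d, seed=sim_seed, **run_kwargs)
                costs[d, j] = res.mean_cost
                qalys[d, j] = res.mean_qaly
            rows.append(draw)
    return PSAResult(names=names, costs=costs, qalys=qalys,
                     draws=pd.DataFrame(rows), seed=seed, sim_seed=sim_seed)


@dataclass(frozen=True)
class DSARow:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _target_icer(results, target: str | None, comparator: str | None) -> float:
    if target is not None and comparator is not None:
        by_name = {r.name: r for r in results}
        t, c = by_name[target], by_name[comparator]
        dq = t.mean_qaly - c.mean_qaly
        if dq <= 0:
            return np.inf
        return (t.mean_cost - c.mean_cost) / dq
    frontier = icer_ladder(results)
    if target is None:
        # last frontier step's ICER (the most effective non-dominated strategy)
        steps = [e for e in frontier.frontier if e.icer is not None]
        if not steps:
            return np.nan
        return steps[-1].icer
    icer = frontier.icer_of(target)
    return np.nan if icer is None else icer


def one_way_dsa(cohort: pd.DataFrame, strategies, params: ParameterSet,
                ranges: dict, seed: int, target: str | None = None,
                comparator: str | None = None, **run_kwargs) -> list[DSARow]:
    """One-way deterministic sensitivity analysis (tornado input).

    ``ranges`` maps dotted parameter paths to (low, high).  For each
    parameter the model is re-run with that parameter at each bound (same
    simulation seed: common random numbers; all else at base) and the target
    ICER recorded — the pairwise ICER of ``target`` vs ``comparator`` when
    both are named (robust to the target leaving the frontier mid-sweep),
    otherwise the target's frontier ICER.  Rows come back sorted by
    descending ICER range — tornado order.
    """
    rows = []
    for name, (low, high) in ranges.items():
        if not low < high:
            raise ConfigurationError(f"DSA range for {name!r} must have low < high")
        icers = []
        for bound in (low, high):
            p_b = _set_dotted(params, name, bound)
            results = [run_strategy(cohort, s, p_b, seed=seed, **run_kwargs) for s in strategies]
            icers.append(_target_icer(results, target, comparator))
        rows.append(DSARow(parameter=name, low=low, high=high,
                           icer_low=icers[0], icer_high=icers[1]))
    rows.sort(key=lambda r: (-(r.width if np.isfinite(r.width) else np.inf)))
    return rows


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _age_sex_groups(cohort: pd.DataFrame, width: int = 10):
    lo = (cohort["age"] // width * width).astype(int)
    return cohort.assign(_band=lo, _sex=cohort["sex"])


def internal_validation(cohort: pd.DataFrame, params: ParameterSet, seed: int,
                        strategy=None, n_reps: int = 10) -> tuple[float, pd.DataFrame]:
    """Internal validity: R² of simulated vs expected first-cycle event frequencies.

    Per sex x 10-year age band, the analytic mean 1-year CHD and stroke
    probabilities at baseline are compared with the mean simulated
    first-cycle event frequencies in the untreated arm (averaged over
    ``n_reps`` independent replications to keep small groups from dominating
    the regression with binomial noise); returns the least-squares R² of
    simulated on expected and the underlying group table.
    """
    from .strategies import StrategyDefinition

    if strategy is None:
        strategy = StrategyDefinition("no-treatment", None)
    fields = {
        "age": cohort["age"].to_numpy(dtype=float),
        "sbp": cohort["sbp"].to_numpy(dtype=float),
        "tc": cohort["tc"].to_numpy(dtype=float),
        "hdl": cohort["hdl"].to_numpy(dtype=float),
        "ldl": cohort["ldl"].to_numpy(dtype=float),
        "wc": cohort["wc"].to_numpy(dtype=float),
        "smoker": cohort["smoker"].to_numpy(dtype=float),
        "diabetes": cohort["diabetes"].to_numpy(dtype=float),
        "antihtn": cohort["antihtn"].to_numpy(dtype=float),
    }
    male = cohort["sex"].to_numpy() == "M"
    p1 = deale_annual_probability(ten_year_risk_arrays(fields, male, params.coefficients))
    expected = pd.DataFrame({
        "sex": cohort["sex"], "band": (cohort["age"] // 10 * 10).astype(int),
        "p_chd": p1 * params.events.chd_share, "p_stroke": p1 * params.events.stroke_share,
    })
    # simulate the untreated first cycle n_reps times, average the frequencies
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(n_reps)]
    chd = np.zeros(len(cohort))
    stroke = np.zeros(len(cohort))
    for rs in rep_seeds:
        res = run_strategy(cohort, strategy, params, seed=rs, max_cycles=1, keep_individual=True)
        chd += res.individual["chd_events"].to_numpy()
        stroke += res.individual["stroke_events"].to_numpy()
    observed = pd.DataFrame({
        "sex": cohort["sex"], "band": expected["band"],
        "chd": chd / n_reps, "stroke": stroke / n_reps,
    })
    rows = []
    for (sex, band), grp in expected.groupby(["sex", "band"]):
        obs = observed[(observed["sex"] == sex) & (observed["band"] == band)]
        rows.append({"sex": sex, "band": band, "n": len(grp),
                     "expected_chd": grp["p_chd"].mean(), "simulated_chd": obs["chd"].mean(),
                     "expected_stroke": grp["p_stroke"].mean(), "simulated_stroke": obs["stroke"].mean()})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise DomainError("internal validation needs at least 3 age-sex groups")
    x = np.concatenate([table["expected_chd"], table["expected_stroke"]])
    y = np.concatenate([table["simulated_chd"], table["simulated_stroke"]])
    if np.allclose(x, x[0]):
        raise DomainError("expected probabilities are degenerate; R² undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), table


def external_validation(summaries: pd.DataFrame, reference: pd.DataFrame | None) -> pd.DataFrame:
    """External validity report: simulated vs reference values, no pass/fail.

    ``summaries`` and ``reference`` share a ``metric`` key column (e.g.
    ``life_expectancy`` or ``incidence_M_60``); the report tabulates both
    values and their difference.  An absent or empty reference yields an
    empty report with a warning.
    """
    if reference is None or reference.empty:
        warnings.warn("no external reference table supplied; report skipped", stacklevel=2)
        return pd.DataFrame(columns=["metric", "simulated", "reference", "delta"])
    merged = summaries.merge(reference, on="metric", suffixes=("_sim", "_ref"))
    return pd.DataFrame({
        "metric": merged["metric"],
        "simulated": merged["value_sim"],
        "reference": merged["value_ref"],
        "delta": merged["value_sim"] - merged["value_ref"],
    })
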