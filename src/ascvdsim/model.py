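"""Top-level model / results objects.

:class:`StatinPolicyModel` bundles a baseline cohort, a parameter set and a
list of initiation strategies; :meth:`run` executes the microsimulation for
every strategy under common random numbers and returns a
:class:`StatinPolicyResults` carrying the strategy-level estimates, their
Monte-Carlo uncertainty, the ICER frontier and a ``summary()`` table.
Sensitivity analyses hang off the same pair.

Example
-------
>>> from ascvdsim import StatinPolicyModel
>>> model = StatinPolicyModel.from_synthetic(n=2000, seed=7)
>>> results = model.run(seed=7)
>>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import default_parameter_set, default_population_config
from .economics import WTP_1GDP, WTP_3GDP, CEFrontier, ceac, frontier_report, icer_ladder
from .engine import ParameterSet, StrategyResult, run_strategy
from .errors import ConfigurationError
from .population import generate_cohort, read_cohort_csv
from .sensitivity import (default_dsa_ranges, default_psa_specs, one_way_dsa, run_psa)
from .strategies import StrategyDefinition, preset_strategies

__all__ = ["StatinPolicyModel", "StatinPolicyResults"]


class StatinPolicyModel:
    """Cost-effectiveness microsimulation of statin initiation thresholds."""

    def __init__(self, cohort: pd.DataFrame, params: ParameterSet | None = None,
                 strategies: list[StrategyDefinition] | None = None,
                 allow_recurrence: bool = False):
        if len(cohort) == 0:
            raise ConfigurationError("cohort must be nonempty")
        self.cohort = cohort.reset_index(drop=True)
        self.params = params if params is not None else default_parameter_set()
        self.strategies = list(strategies) if strategies is not None else preset_strategies()
        self.allow_recurrence = allow_recurrence

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_synthetic(cls, n: int = 10_000, seed: int = 0, population=None,
                       **kwargs) -> "StatinPolicyModel":
        """Build from a generated synthetic baseline cohort."""
        pop = population if population is not None else default_population_config()
        return cls(generate_cohort(n, pop, seed=seed), **kwargs)

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "StatinPolicyModel":
        return cls(cohort, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StatinPolicyModel":
        return cls(read_cohort_csv(path), **kwargs)

    # -- estimation ---------------------------------------------------------

    def run(self, seed: int, keep_individual: bool = False) -> "StatinPolicyResults":
        """Simulate every strategy (common random numbers) and rank by ICER."""
        results = [
            run_strategy(self.cohort, s, self.params, seed=seed,
                         allow_recurrence=self.allow_recurrence,
                         keep_individual=keep_individual)
            for s in self.strategies
        ]
        frontier = icer_ladder(results)
        return StatinPolicyResults(model=self, strategy_results=tuple(results),
                                   frontier=frontier, seed=seed)

    #: statsmodels-style alias
    fit = run

    # -- sensitivity --------------------------------------------------------

    def run_psa(self, n_draws: int = 1000, seed: int = 0, specs=None):
        specs = specs if specs is not None else default_psa_specs()
        return run_psa(self.cohort, self.strategies, specs, self.params,
                       n_draws=n_draws, seed=seed,
                       allow_recurrence=self.allow_recurrence)

    def run_dsa(self, seed: int, ranges=None, target: str | None = None,
                comparator: str | None = None):
        ranges = ranges if ranges is not None else default_dsa_ranges()
        return one_way_dsa(self.cohort, self.strategies, self.params, ranges,
                           seed=seed, target=target, comparator=comparator,
                           allow_recurrence=self.allow_recurrence)


@dataclass(frozen=True)
class StatinPolicyResults:
    """Strategy-level estimates, their uncertainty and the CE frontier."""

    model: StatinPolicyModel
    strategy_results: tuple
    frontier: CEFrontier
    seed: int

    @property
    def strategy_table(self) -> pd.DataFrame:
        return frontier_report(self.strategy_results, self.frontier)

    def result_for(self, name: str) -> StrategyResult:
        for r in self.strategy_results:
            if r.name == name:
                return r
        raise KeyError(name)

    def se_table(self) -> pd.DataFrame:
        """Monte-Carlo standard errors of the per-strategy means."""
        rows = []
        for r in self.strategy_results:
            rows.append({
                "strategy": r.name,
                "se_cost": r.sd_cost / np.sqrt(r.n),
                "se_qaly": r.sd_qaly / np.sqrt(r.n),
                "se_life_years": r.sd_life_years / np.sqrt(r.n),
            })
        return pd.DataFrame(rows)

    def ceac_from_psa(self, psa_result, wtp_grid=None) -> pd.DataFrame:
        if wtp_grid is None:
            wtp_grid = np.linspace(0, 3 * WTP_1GDP, 31)
        return ceac(psa_result.costs, psa_result.qalys, psa_result.names, wtp_grid)

    def summary(self) -> str:
        """Formatted strategy table with dominance status and frontier ICERs."""
        tbl = self.strategy_table
        lines = [
            "Statin initiation-threshold cost-effectiveness microsimulation",
            f"cohort n = {len(self.model.cohort):,}   seed = {self.seed}   "
            f"discount rate = {self.model.params.discount_rate:.1%}",
            "",
            f"{'strategy':<16}{'eligible%':>10}{'CVD/pp':>9}{'SID/pp':>9}"
            f"{'QALYs':>10}{'LE':>8}{'cost':>12}  {'status':<20}{'ICER':>12}",
        ]
        for _, row in tbl.iterrows():
            icer = "" if np.isnan(row["icer"]) else f"{row['icer']:,.0f}"
            lines.append(
                f"{row['strategy']:<16}{row['eligible_pct']:>9.1f}%"
                f"{row['cvd_events_per_person']:>9.3f}{row['statin_diabetes_per_person']:>9.4f}"
                f"{row['mean_discounted_qalys']:>10.3f}{row['life_expectancy']:>8.2f}"
                f"{row['mean_discounted_cost']:>12,.0f}  {row['status']:<20}{icer:>12}"
            )
        lines.append("")
        lines.append(f"optimal at 1x GDP/capita ({WTP_1GDP:,.0f}): {self.frontier.optimal_at(WTP_1GDP)}")
        lines.append(f"optimal at 3x GDP/capita ({WTP_3GDP:,.0f}): {self.frontier.optimal_at(WTP_3GDP)}")
        return "\n".join(lines)
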