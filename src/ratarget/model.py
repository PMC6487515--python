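"""Model/Results facade tying the pipeline together.

:class:`CostEffectivenessModel` is built from longitudinal visit records
plus the strategies to compare; ``fit()`` estimates every model parameter
(transition matrices, per-state utilities and costs, their uncertainty
distributions, stationarity diagnostics) and returns a
:class:`CostEffectivenessResults` carrying the estimates.  Simulation
(``simulate``/``compare``) and probabilistic sensitivity analysis
(``run_psa``) hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .economics import CEComparison, icer
from .engine import (
    CohortResult,
    ModelConfig,
    cohort_expectation,
    simulate_cohort,
)
from .estimation import (
    CYCLE_DAYS,
    WINDOW_DAYS,
    TransitionModel,
    estimate_matrices,
    read_visits_csv,
    stationarity_test,
    window_transitions,
)
from .psa import FittedParameterDistributions, PSAResult, run_psa
from .states import HealthState, StrategySpec, build_strategy
from .valuation import StateValues, Tariff


class CostEffectivenessModel:
    """Treat-to-target cost-effectiveness model built from visit records.

    Parameters
    ----------
    visits : pandas.DataFrame
        Longitudinal visit records (columns ``patient_id, visit_day, das28,
        treatment_key, mo, sc, ua, pd, ad, interval_cost, sick_days``),
        typically the concatenation of one cohort per strategy.
    tariff : Tariff
        EQ-5D-3L valuation tariff.
    strategies : sequence
        The two (or more) strategies whose transition keys the data must
        cover; preset names or :class:`StrategySpec` objects.
    config : ModelConfig, optional
        Engine configuration shared by all downstream simulation.
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        tariff: Tariff,
        strategies: Sequence,
        config: ModelConfig | None = None,
        workforce_participation: float = 0.7,
        day_cost: float = 230.0,
        cycle_days: int = CYCLE_DAYS,
        window_days: int = WINDOW_DAYS,
    ) -> None:
        self.visits = visits
        self.tariff = tariff
        self.strategies = [build_strategy(s) for s in strategies]
        if not self.strategies:
            raise ValueError("need at least one strategy")
        self.config = config if config is not None else ModelConfig()
        self.workforce_participation = workforce_participation
        self.day_cost = day_cost
        self.cycle_days = cycle_days
        self.window_days = window_days

    @classmethod
    def from_csv(cls, visits_path, tariff: Tariff, strategies: Sequence,
                 **kwargs) -> "CostEffectivenessModel":
        return cls(read_visits_csv(visits_path), tariff, strategies, **kwargs)

    @property
    def required_keys(self) -> list[str]:
        keys: list[str] = []
        for s in self.strategies:
            for k in s.transition_keys:
                if k not in keys:
                    keys.append(k)
        return keys

    def fit(
        self,
        dirichlet_prior: float = 1.0,
        on_missing: str = "error",
    ) -> "CostEffectivenessResults":
        """Estimate all model parameters from the visit records.

        ``on_missing="identity"`` substitutes self-transition rows for
        treatment keys absent from the data instead of raising.
        """
        transitions = window_transitions(
            self.visits, cycle_days=self.cycle_days,
            window_days=self.window_days)
        required = self.required_keys if on_missing == "error" else None
        tm = estimate_matrices(transitions, required_keys=required)
        if on_missing == "identity":
            for key in self.required_keys:
                if key not in tm.probs:
                    tm.counts[key] = np.zeros((4, 4))
                    tm.probs[key] = np.eye(4)
        state_values = StateValues.from_visits(
            self.visits, self.tariff,
            workforce_participation=self.workforce_participation,
            day_cost=self.day_cost)
        stationarity = stationarity_test(transitions)
        fits = FittedParameterDistributions.from_data(
            self.visits, self.tariff, tm,
            dirichlet_prior=dirichlet_prior,
            workforce_participation=self.workforce_participation,
            day_cost=self.day_cost)
        return CostEffectivenessResults(
            model=self,
            transition_model=tm,
            state_values=state_values,
            stationarity=stationarity,
            parameter_fits=fits,
            n_transitions=len(transitions),
        )


@dataclass
class ComparisonReport:
    """Base-case comparison of two strategies."""

    result_i: CohortResult
    result_ii: CohortResult
    comparison: CEComparison
    strategy_i: str
    strategy_ii: str

    def summary(self) -> dict:
        return {
            "strategies": {
                self.strategy_i: self.result_i.summary(),
                self.strategy_ii: self.result_ii.summary(),
            },
            "icer": self.comparison.summary(),
        }


@dataclass
class CostEffectivenessResults:
    """Fitted parameters plus simulation/PSA entry points."""

    model: CostEffectivenessModel
    transition_model: TransitionModel
    state_values: StateValues
    stationarity: pd.DataFrame
    parameter_fits: FittedParameterDistributions
    n_transitions: int

    def _strategy(self, which) -> StrategySpec:
        if isinstance(which, int):
            return self.model.strategies[which]
        for s in self.model.strategies:
            if s.name == which:
                return s
        return build_strategy(which)

    def simulate(
        self,
        strategy=0,
        n_patients: int | None = None,
        seed: int | None = None,
        method: str = "microsimulation",
    ) -> CohortResult:
        """Run one strategy through the engine.

        ``method`` is ``"microsimulation"`` (Monte Carlo over individual
        patients) or ``"expectation"`` (deterministic occupancy propagation).
        """
        strat = self._strategy(strategy)
        cfg = self.model.config
        if n_patients is not None:
            cfg = replace(cfg, n_patients=n_patients)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if method == "microsimulation":
            return simulate_cohort(strat, self.transition_model,
                                   self.state_values, cfg)
        if method == "expectation":
            return cohort_expectation(strat, self.transition_model,
                                      self.state_values, cfg)
        raise ValueError(f"unknown method {method!r}")

    def compare(
        self,
        strategy_i=0,
        strategy_ii=1,
        n_patients: int | None = None,
        seed: int | None = None,
        method: str = "microsimulation",
    ) -> ComparisonReport:
        """Base-case comparison: simulate both strategies and compute the
        ICER of II vs I with a dominance label."""
        si, sii = self._strategy(strategy_i), self._strategy(strategy_ii)
        seed = self.model.config.seed if seed is None else seed
        res_i = self.simulate(si.name, n_patients, seed, method)
        res_ii = self.simulate(sii.name, n_patients,
                               None if seed is None else seed + 1, method)
        comp = icer(res_i.mean_cost, res_i.mean_qaly,
                    res_ii.mean_cost, res_ii.mean_qaly)
        return ComparisonReport(result_i=res_i, result_ii=res_ii,
                                comparison=comp, strategy_i=si.name,
                                strategy_ii=sii.name)

    def run_psa(
        self,
        strategy_i=0,
        strategy_ii=1,
        n_outer: int = 2000,
        n_inner: int = 200,
        seed: int | None = None,
    ) -> PSAResult:
        """Two-level probabilistic sensitivity analysis of II vs I."""
        return run_psa(
            self._strategy(strategy_i), self._strategy(strategy_ii),
            self.parameter_fits, n_outer=n_outer, n_inner=n_inner,
            seed=self.model.config.seed if seed is None else seed,
            base_cfg=self.model.config,
        )

    def summary(self) -> str:
        """Human-readable parameter summary table."""
        lines = []
        w = 72
        lines.append("Treat-to-target cost-effectiveness model".center(w))
        lines.append("=" * w)
        lines.append(f"ratarget {_version}")
        lines.append(f"Visits: {len(self.model.visits)}    "
                     f"Patients: {self.model.visits['patient_id'].nunique()}    "
                     f"Transitions: {self.n_transitions}")
        lines.append(f"Strategies: "
                     f"{', '.join(s.name for s in self.model.strategies)}")
        cfg = self.model.config
        lines.append(
            f"Horizon: {cfg.horizon_cycles} cycles x {cfg.cycle_years} y; "
            f"discounting {cfg.discount_rate_cost:.1%} cost / "
            f"{cfg.discount_rate_effect:.1%} effect"
        )
        lines.append("-" * w)
        lines.append("Per-state parameters (per 3-month cycle)")
        lines.append(f"{'state':<12}{'utility':>10}{'sick days':>12}"
                     f"{'hc cost':>12}{'state cost':>12}")
        for s in HealthState:
            lines.append(
                f"{s.name:<12}"
                f"{self.state_values.utilities[s]:>10.3f}"
                f"{self.state_values.sick_days_per_cycle[s]:>12.2f}"
                f"{self.state_values.hc_cost_per_cycle[s]:>12.2f}"
                f"{self.state_values.state_cost(s):>12.2f}"
            )
        lines.append("-" * w)
        lines.append("Transition matrices (row counts)")
        for key in self.transition_model.keys:
            counts = self.transition_model.counts[key]
            lines.append(f"  {key:<16} n={int(counts.sum()):>6}  "
                         f"rows: {[int(c) for c in counts.sum(axis=1)]}")
        flagged = int(self.stationarity["flagged"].sum())
        tested = int((~self.stationarity["flagged"]).sum())
        nonstat = int(((self.stationarity["pvalue"] < 0.05)
                       & ~self.stationarity["flagged"]).sum())
        lines.append("-" * w)
        lines.append(
            f"Stationarity: {tested} rows tested, {nonstat} with p < 0.05, "
            f"{flagged} flagged untestable"
        )
        lines.append("=" * w)
        return "\n".join(lines)
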