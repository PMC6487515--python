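"""EQ-5D-3L valuation and per-health-state utility/cost parameters.

The EQ-5D-3L questionnaire scores five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression) on three levels each,
giving 3^5 = 243 health profiles.  A *tariff* maps each profile to a utility
(1 = perfect health; values below 0, worse than death, are permitted).  Per
DAS28 health state the model needs a mean utility, a mean healthcare
consumption cost per 3-month cycle and a mean number of sick days per cycle;
the societal cost of a state is

    sick_days * workforce_participation * day_cost + healthcare_cost

with a default day-of-absence cost of EUR 230.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import N_STATES, HealthState, classify_das28

EQ5D_DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")
EQ5D_LEVELS = (1, 2, 3)
N_EQ5D_PROFILES = len(EQ5D_LEVELS) ** len(EQ5D_DIMENSIONS)  # 243

DEFAULT_DAY_COST = 230.0


class MissingParameterError(KeyError):
    """A required per-state parameter could not be computed."""


def _validate_responses(responses: Sequence[int]) -> tuple[int, ...]:
    responses = tuple(int(r) for r in responses)
    if len(responses) != len(EQ5D_DIMENSIONS):
        raise ValueError(
            f"EQ-5D response vector must have 5 entries, got {len(responses)}"
        )
    if any(r not in EQ5D_LEVELS for r in responses):
        raise ValueError(
            f"EQ-5D levels must be in {{1,2,3}}, got {responses}"
        )
    return responses


@dataclass(frozen=True)
class Tariff:
    """EQ-5D-3L valuation tariff.

    Either a full 243-profile lookup (``lookup``) or the usual additive form:
    utility = 1 - sum of per-dimension level decrements - ``constant`` (once,
    if any dimension is above level 1) - ``n3`` (once, if any dimension is at
    level 3).  The full-health profile (1,1,1,1,1) always values to 1.
    """

    level2: Mapping[str, float] | None = None
    level3: Mapping[str, float] | None = None
    constant: float = 0.0
    n3: float = 0.0
    lookup: Mapping[tuple[int, ...], float] | None = None

    def __post_init__(self) -> None:
        if self.lookup is not None:
            if len(self.lookup) != N_EQ5D_PROFILES:
                raise ValueError(
                    f"lookup tariff must cover all {N_EQ5D_PROFILES} profiles, "
                    f"got {len(self.lookup)}"
                )
            full = tuple([1] * 5)
            if abs(self.lookup[full] - 1.0) > 1e-12:
                raise ValueError("full-health profile must value to 1")
        else:
            if self.level2 is None or self.level3 is None:
                raise ValueError(
                    "additive tariff needs level2 and level3 decrements"
                )
            missing = [d for d in EQ5D_DIMENSIONS
                       if d not in self.level2 or d not in self.level3]
            if missing:
                raise ValueError(f"tariff lacks coefficients for {missing}")

    @classmethod
    def additive(
        cls,
        level2: float | Mapping[str, float],
        level3: float | Mapping[str, float],
        constant: float = 0.0,
        n3: float = 0.0,
    ) -> "Tariff":
        """Additive tariff; scalar decrements apply to every dimension."""
        if not isinstance(level2, Mapping):
            level2 = {d: float(level2) for d in EQ5D_DIMENSIONS}
        if not isinstance(level3, Mapping):
            level3 = {d: float(level3) for d in EQ5D_DIMENSIONS}
        return cls(level2=dict(level2), level3=dict(level3),
                   constant=constant, n3=n3)

    def utility(self, responses: Sequence[int]) -> float:
        """Value one EQ-5D-3L response vector."""
        responses = _validate_responses(responses)
        if self.lookup is not None:
            return float(self.lookup[responses])
        u = 1.0
        any_problem = any(r > 1 for r in responses)
        any_level3 = any(r == 3 for r in responses)
        if any_problem:
            u -= self.constant
        if any_level3:
            u -= self.n3
        for dim, r in zip(EQ5D_DIMENSIONS, responses):
            if r == 2:
                u -= self.level2[dim]
            elif r == 3:
                u -= self.level3[dim]
        return u

    def all_profiles(self) -> pd.DataFrame:
        """Enumerate all 243 profiles with their utilities."""
        rows = [
            dict(zip(EQ5D_DIMENSIONS, prof), utility=self.utility(prof))
            for prof in itertools.product(EQ5D_LEVELS, repeat=5)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        if self.lookup is not None:
            self.all_profiles().to_csv(path, index=False)
            return
        rows = [{"term": "constant", "value": self.constant},
                {"term": "n3", "value": self.n3}]
        for dim in EQ5D_DIMENSIONS:
            rows.append({"term": f"{dim}2", "value": self.level2[dim]})
            rows.append({"term": f"{dim}3", "value": self.level3[dim]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Tariff":
        """Load a tariff from CSV: either ``term,value`` additive
        coefficients or a 243-row ``mo,sc,ua,pd,ad,utility`` lookup."""
        df = pd.read_csv(path)
        if {"term", "value"} <= set(df.columns):
            coef = dict(zip(df["term"], df["value"].astype(float)))
            level2 = {d: coef[f"{d}2"] for d in EQ5D_DIMENSIONS}
            level3 = {d: coef[f"{d}3"] for d in EQ5D_DIMENSIONS}
            return cls(level2=level2, level3=level3,
                       constant=coef.get("constant", 0.0),
                       n3=coef.get("n3", 0.0))
        lookup = {
            tuple(int(row[d]) for d in EQ5D_DIMENSIONS): float(row["utility"])
            for _, row in df.iterrows()
        }
        return cls(lookup=lookup)


def eq5d_utility(responses: Sequence[int], tariff: Tariff) -> float:
    """Utility of one EQ-5D-3L response vector under a tariff."""
    return tariff.utility(responses)


def state_cost_per_cycle(
    sick_days: float,
    participation: float,
    day_cost: float,
    hc_cost: float,
) -> float:
    """Societal per-cycle cost of a health state:
    ``sick_days * participation * day_cost + hc_cost``."""
    for name, v in [("sick_days", sick_days), ("participation", participation),
                    ("day_cost", day_cost), ("hc_cost", hc_cost)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if participation > 1:
        raise ValueError(f"participation must be <= 1, got {participation}")
    return sick_days * participation * day_cost + hc_cost


def participation_from_table(
    table: pd.DataFrame,
    fraction_col: str = "participation",
    weight_col: str = "weight",
) -> float:
    """Collapse a stratified workforce-participation table (e.g. by age and
    sex) to the single scalar the model uses, as the weight-averaged
    fraction."""
    f = table[fraction_col].astype(float)
    w = table[weight_col].astype(float)
    if ((f < 0) | (f > 1)).any() or (w < 0).any() or w.sum() == 0:
        raise ValueError("invalid participation fractions or weights")
    return float((f * w).sum() / w.sum())


def _classify_column(visits: pd.DataFrame) -> pd.Series:
    return visits["das28"].map(classify_das28)


def state_utilities(
    visits: pd.DataFrame, tariff: Tariff
) -> dict[HealthState, float]:
    """Mean EQ-5D utility per DAS28 health state over visit records."""
    states = _classify_column(visits)
    utils = visits.apply(
        lambda row: tariff.utility([row[d] for d in EQ5D_DIMENSIONS]), axis=1
    )
    means: dict[HealthState, float] = {}
    for hs in HealthState:
        mask = states == hs
        if not mask.any():
            raise MissingParameterError(
                f"no visits observed in state {hs.name}; "
                "cannot estimate its utility"
            )
        means[hs] = float(utils[mask].mean())
    return means


@dataclass
class StateValues:
    """Per-health-state model parameters.

    ``utilities`` are annual utility weights (a cycle contributes
    utility x 0.25 QALY); ``sick_days_per_cycle`` and ``hc_cost_per_cycle``
    are per-3-month means.
    """

    utilities: dict[HealthState, float]
    sick_days_per_cycle: dict[HealthState, float]
    hc_cost_per_cycle: dict[HealthState, float]
    workforce_participation: float = 0.7
    day_cost: float = DEFAULT_DAY_COST

    def __post_init__(self) -> None:
        if not 0 <= self.workforce_participation <= 1:
            raise ValueError("workforce_participation must be in [0, 1]")
        for d in (self.utilities, self.sick_days_per_cycle,
                  self.hc_cost_per_cycle):
            missing = [s.name for s in HealthState if s not in d]
            if missing:
                raise MissingParameterError(
                    f"state values missing for states: {missing}"
                )
        if self.utilities[HealthState.REMISSION] < self.utilities[HealthState.HIGH]:
            warnings.warn(
                "remission utility below high-disease-activity utility; "
                "check the fitted parameters", stacklevel=2
            )

    def utility_array(self) -> np.ndarray:
        return np.array([self.utilities[s] for s in HealthState])

    def cost_array(self) -> np.ndarray:
        """Per-cycle societal state costs, ordered by HealthState."""
        return np.array([self.state_cost(s) for s in HealthState])

    def state_cost(self, state: HealthState) -> float:
        return state_cost_per_cycle(
            self.sick_days_per_cycle[state],
            self.workforce_participation,
            self.day_cost,
            self.hc_cost_per_cycle[state],
        )

    @classmethod
    def from_visits(
        cls,
        visits: pd.DataFrame,
        tariff: Tariff,
        workforce_participation: float = 0.7,
        day_cost: float = DEFAULT_DAY_COST,
    ) -> "StateValues":
        """Estimate all per-state means from visit records."""
        states = _classify_column(visits)
        utilities = state_utilities(visits, tariff)
        sick: dict[HealthState, float] = {}
        hc: dict[HealthState, float] = {}
        for hs in HealthState:
            mask = states == hs
            if not mask.any():
                raise MissingParameterError(
                    f"no visits observed in state {hs.name}"
                )
            sick[hs] = float(visits.loc[mask, "sick_days"].mean())
            hc[hs] = float(visits.loc[mask, "interval_cost"].mean())
        return cls(utilities=utilities, sick_days_per_cycle=sick,
                   hc_cost_per_cycle=hc,
                   workforce_participation=workforce_participation,
                   day_cost=day_cost)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in HealthState:
            rows.append({
                "state": s.name,
                "utility": self.utilities[s],
                "sick_days_per_cycle": self.sick_days_per_cycle[s],
                "hc_cost_per_cycle": self.hc_cost_per_cycle[s],
                "workforce_participation": self.workforce_participation,
                "day_cost": self.day_cost,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StateValues":
        df = pd.read_csv(path)
        utilities = {}
        sick = {}
        hc = {}
        for _, row in df.iterrows():
            s = HealthState[row["state"]]
            utilities[s] = float(row["utility"])
            sick[s] = float(row["sick_days_per_cycle"])
            hc[s] = float(row["hc_cost_per_cycle"])
        return cls(
            utilities=utilities, sick_days_per_cycle=sick,
            hc_cost_per_cycle=hc,
            workforce_participation=float(df["workforce_participation"].iloc[0]),
            day_cost=float(df["day_cost"].iloc[0]),
        )
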