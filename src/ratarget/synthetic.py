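"""Synthetic registry-like cohorts with known ground truth.

Emulates a treat-to-target registry of early RA patients: DMARD-naive
patients enrolled with moderate-to-high disease activity (DAS28 > 3.2),
seen roughly every 3 months, with a DAS28 score, EQ-5D-3L responses, a
healthcare-consumption cost for the interval and sick days recorded at each
visit.  The generating process is exactly the model's own structure — the
patient's state evolves by the true transition matrix of the treatment step
assigned by the strategy automaton — so estimation, valuation, engine and
PSA can all be tested against known truth.

Scenarios: every non-remission row of a truth matrix shares one per-cycle
remission-entry probability ``r`` and the remission row has stay probability
``q``, so the chain's stationary remission share is ``r / (r + 1 - q)`` in
closed form.  The step-up-like and combo-like scenarios (r = 0.25 vs 0.307,
q = 0.80) differ by ~5 percentage points in that share, mirroring the
observed contrast between the two treat-to-target protocols; NULL_EQUAL
makes both strategies identical for null testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import _advance_vec, _prepare  # reuse the automaton kernels
from .estimation import VISIT_COLUMNS, TransitionModel, WINDOW_DAYS
from .states import (
    DAS28_CUTOFFS,
    N_STATES,
    HealthState,
    StrategySpec,
    build_strategy,
)
from .valuation import EQ5D_DIMENSIONS, StateValues, Tariff

STEP_UP_LIKE = "STEP_UP_LIKE"
COMBO_LIKE = "COMBO_LIKE"
NULL_EQUAL = "NULL_EQUAL"

#: Upper support cap for synthetic DAS28 values in the HIGH state.
DAS28_MAX = 8.6

_REMISSION_STAY = 0.80
_REMISSION_ENTRY = {STEP_UP_LIKE: 0.25, COMBO_LIKE: 0.307, NULL_EQUAL: 0.25}


def example_tariff() -> Tariff:
    """A synthetic additive EQ-5D-3L tariff for tests and examples.

    The coefficients are illustrative only (the model treats the tariff as a
    configuration input; national tariffs are published separately).  Worst
    profile (3,3,3,3,3) values to -0.22, i.e. worse than death.
    """
    return Tariff.additive(
        level2={"mo": 0.04, "sc": 0.05, "ua": 0.03, "pd": 0.05, "ad": 0.04},
        level3={"mo": 0.16, "sc": 0.20, "ua": 0.11, "pd": 0.24, "ad": 0.18},
        constant=0.07,
        n3=0.26,
    )


def _scenario_matrix(r: float, q: float = _REMISSION_STAY) -> np.ndarray:
    """4x4 truth matrix: remission-entry probability r from every
    non-remission state, remission-stay probability q."""
    m = np.array([
        [q,    0.12, 0.06, 0.02],
        [r,    0.40, 0.25, 0.35 - r],
        [r,    0.25, 0.35, 0.40 - r],
        [r,    0.15, 0.30, 0.55 - r],
    ])
    if np.any(m < 0):
        raise ValueError(f"remission entry probability {r} out of range")
    assert np.allclose(m.sum(axis=1), 1.0)
    return m


@dataclass
class GroundTruth:
    """True generating parameters of a synthetic registry.

    ``matrices`` covers the transition keys of both preset strategies;
    ``eq5d_level_probs`` gives, per health state, a (5 dimensions x 3 levels)
    categorical response distribution; interval costs are Gamma, sick days
    Poisson, both state-conditional.
    """

    matrices: dict[str, np.ndarray]
    eq5d_level_probs: dict[HealthState, np.ndarray]
    cost_gamma: dict[HealthState, tuple[float, float]]  # (shape, scale)
    sick_day_mean: dict[HealthState, float]
    workforce_participation: float = 0.7
    day_cost: float = 230.0
    baseline_state_probs: tuple[float, ...] = (0.0, 0.0, 0.6, 0.4)

    def __post_init__(self) -> None:
        for key, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9) or np.any(m < 0):
                raise ValueError(f"truth matrix {key!r} is not row-stochastic")
            self.matrices[key] = m
        bp = np.asarray(self.baseline_state_probs, dtype=float)
        if abs(bp.sum() - 1.0) > 1e-9 or np.any(bp < 0):
            raise ValueError("baseline_state_probs must sum to 1")
        if np.any(bp[:2] > 0):
            raise ValueError(
                "baseline support must lie above DAS28 3.2 "
                "(moderate/high only)"
            )

    def transition_model(self) -> TransitionModel:
        return TransitionModel.from_probs(self.matrices)

    def expected_utilities(self, tariff: Tariff) -> dict[HealthState, float]:
        """Exact per-state mean utility by enumerating all 243 profiles."""
        out = {}
        profiles = tariff.all_profiles()
        for hs, probs in self.eq5d_level_probs.items():
            w = np.ones(len(profiles))
            for d_i, dim in enumerate(EQ5D_DIMENSIONS):
                levels = profiles[dim].to_numpy() - 1
                w *= probs[d_i, levels]
            out[hs] = float(np.sum(w * profiles["utility"].to_numpy()))
        return out

    def state_values(self, tariff: Tariff) -> StateValues:
        """True StateValues implied by the generating distributions."""
        return StateValues(
            utilities=self.expected_utilities(tariff),
            sick_days_per_cycle=dict(self.sick_day_mean),
            hc_cost_per_cycle={
                s: shape * scale
                for s, (shape, scale) in self.cost_gamma.items()
            },
            workforce_participation=self.workforce_participation,
            day_cost=self.day_cost,
        )

    def to_json(self, path) -> None:
        payload = {
            "matrices": {k: v.tolist() for k, v in self.matrices.items()},
            "eq5d_level_probs": {
                s.name: np.asarray(v).tolist()
                for s, v in self.eq5d_level_probs.items()
            },
            "cost_gamma": {s.name: list(v)
                           for s, v in self.cost_gamma.items()},
            "sick_day_mean": {s.name: v
                              for s, v in self.sick_day_mean.items()},
            "workforce_participation": self.workforce_participation,
            "day_cost": self.day_cost,
            "baseline_state_probs": list(self.baseline_state_probs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            matrices={k: np.asarray(v) for k, v in d["matrices"].items()},
            eq5d_level_probs={HealthState[s]: np.asarray(v)
                              for s, v in d["eq5d_level_probs"].items()},
            cost_gamma={HealthState[s]: tuple(v)
                        for s, v in d["cost_gamma"].items()},
            sick_day_mean={HealthState[s]: float(v)
                           for s, v in d["sick_day_mean"].items()},
            workforce_participation=float(d["workforce_participation"]),
            day_cost=float(d["day_cost"]),
            baseline_state_probs=tuple(d["baseline_state_probs"]),
        )


def stationary_remission_share(matrix: np.ndarray) -> float:
    """Remission share of the stationary distribution of a truth matrix."""
    m = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    return float(pi[HealthState.REMISSION])


def make_truth(scenario: str) -> GroundTruth:
    """Ground truth for one scenario (STEP_UP_LIKE, COMBO_LIKE, NULL_EQUAL).

    All treatment keys of both preset strategies share the scenario's
    transition matrix; NULL_EQUAL equals STEP_UP_LIKE, so the two strategies'
    matrices are identical under it.
    """
    scenario = scenario.upper()
    if scenario not in _REMISSION_ENTRY:
        raise ValueError(
            f"unknown scenario {scenario!r}; "
            f"expected one of {sorted(_REMISSION_ENTRY)}"
        )
    matrix = _scenario_matrix(_REMISSION_ENTRY[scenario])
    keys: list[str] = []
    for preset in ("STEP_UP", "INITIAL_COMBINATION"):
        keys.extend(build_strategy(preset).transition_keys)
    return GroundTruth(
        matrices={k: matrix.copy() for k in keys},
        eq5d_level_probs={
            HealthState.REMISSION: np.tile([0.85, 0.13, 0.02], (5, 1)),
            HealthState.LOW: np.tile([0.70, 0.25, 0.05], (5, 1)),
            HealthState.MODERATE: np.tile([0.45, 0.45, 0.10], (5, 1)),
            HealthState.HIGH: np.tile([0.25, 0.55, 0.20], (5, 1)),
        },
        cost_gamma={
            HealthState.REMISSION: (2.0, 125.0),
            HealthState.LOW: (2.0, 200.0),
            HealthState.MODERATE: (2.0, 350.0),
            HealthState.HIGH: (2.0, 550.0),
        },
        sick_day_mean={
            HealthState.REMISSION: 0.5,
            HealthState.LOW: 1.5,
            HealthState.MODERATE: 4.0,
            HealthState.HIGH: 8.0,
        },
    )


_STATE_BOUNDS = {
    HealthState.REMISSION: (0.0, DAS28_CUTOFFS[0]),
    HealthState.LOW: (DAS28_CUTOFFS[0], DAS28_CUTOFFS[1]),
    HealthState.MODERATE: (DAS28_CUTOFFS[1], DAS28_CUTOFFS[2]),
    HealthState.HIGH: (DAS28_CUTOFFS[2], DAS28_MAX),
}


def generate_cohort(
    truth: GroundTruth,
    strategy: StrategySpec | str,
    n_patients: int = 500,
    visits_per_patient: int = 20,
    schedule_jitter_days: int = 10,
    seed: int = 0,
    cycle_days: int = 91,
    dropout_rate: float = 0.0,
    patient_prefix: str = "P",
) -> pd.DataFrame:
    """Generate registry-like visit records for one strategy cohort.

    Baseline states are moderate/high (DAS28 > 3.2 inclusion); subsequent
    states evolve by the truth matrix of the treatment step assigned by the
    strategy automaton at each visit.  DAS28 values are uniform within the
    occupied state's interval; EQ-5D responses, interval costs and sick days
    are drawn from the state-conditional truth distributions.  Visit days are
    jittered uniformly by up to ``schedule_jitter_days`` around the 3-month
    schedule; optional missing-completely-at-random dropout removes
    non-baseline visits.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    strategy = build_strategy(strategy)
    if schedule_jitter_days > WINDOW_DAYS:
        warnings.warn(
            f"schedule jitter {schedule_jitter_days}d exceeds the "
            f"{WINDOW_DAYS}d estimation window; many visit pairs will fall "
            "outside it", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    tm = truth.transition_model()
    # Reuse the engine's ladder/automaton preparation with dummy values.
    dummy_vals = truth.state_values(example_tariff())
    arr = _prepare(strategy, tm, dummy_vals)

    n = n_patients
    bp = np.asarray(truth.baseline_state_probs)
    states = rng.choice(N_STATES, size=n, p=bp)
    idx = np.full(n, arr.entry_index, dtype=int)
    cnt = np.zeros(n, dtype=int)
    last_eff = np.full(n, -1, dtype=int)

    lows = np.array([_STATE_BOUNDS[HealthState(s)][0] for s in range(N_STATES)])
    highs = np.array([_STATE_BOUNDS[HealthState(s)][1] for s in range(N_STATES)])
    level_probs = np.stack(
        [truth.eq5d_level_probs[HealthState(s)] for s in range(N_STATES)]
    )  # (4, 5, 3)
    gamma_shape = np.array(
        [truth.cost_gamma[HealthState(s)][0] for s in range(N_STATES)])
    gamma_scale = np.array(
        [truth.cost_gamma[HealthState(s)][1] for s in range(N_STATES)])
    sick_mu = np.array(
        [truth.sick_day_mean[HealthState(s)] for s in range(N_STATES)])

    frames = []
    for v in range(visits_per_patient):
        if v > 0:
            idx, cnt, last_eff = _advance_vec(arr, idx, cnt, last_eff, states)
        if v == 0:
            days = np.zeros(n)
        else:
            days = v * cycle_days + rng.integers(
                -schedule_jitter_days, schedule_jitter_days + 1, size=n)
        # (low, high] so values classify back to the generating state
        das28 = lows[states] + (1.0 - rng.random(n)) * (highs[states] - lows[states])
        rec = {
            "patient_id": [f"{patient_prefix}{i:05d}" for i in range(n)],
            "visit_day": days,
            "das28": das28,
            "treatment_key": [strategy.full_ladder[i].transition_key
                              for i in idx],
        }
        u_dims = rng.random((n, 5))
        cum = np.cumsum(level_probs, axis=2)  # (4, 5, 3)
        for d_i, dim in enumerate(EQ5D_DIMENSIONS):
            c = cum[states, d_i]  # (n, 3)
            rec[dim] = 1 + (c[:, :2] <= u_dims[:, d_i:d_i + 1]).sum(axis=1)
        rec["interval_cost"] = rng.gamma(gamma_shape[states],
                                         gamma_scale[states])
        rec["sick_days"] = rng.poisson(sick_mu[states])
        frames.append(pd.DataFrame(rec))
        # State transition to the next visit under the current step.
        u = rng.random(n)
        rowcum = arr.cum_probs[idx, states]
        states = (rowcum[:, :3] <= u[:, None]).sum(axis=1)

    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["patient_id", "visit_day"]).reset_index(drop=True)
    if dropout_rate > 0:
        keep = (df["visit_day"] == 0) | (rng.random(len(df)) >= dropout_rate)
        df = df.loc[keep].reset_index(drop=True)
    return df[VISIT_COLUMNS]
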