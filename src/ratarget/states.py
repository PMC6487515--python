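"""Health states, treatment ladders and the treat-to-target automaton.

The disease course is discretised into four mutually exclusive DAS28-defined
health states (remission, low, moderate, high disease activity).  A treatment
*strategy* is an ordered escalation ladder of drug steps plus a taper ladder
ending in a medication-free step.  The treat-to-target protocol is a small
deterministic automaton over positions on that ladder:

* non-remission at a cycle start moves the patient one medication step up
  (escalation while on active treatment, re-escalation after a flare);
* remission sustained for ``sustained_remission_cycles`` consecutive cycle
  starts moves the patient one step down (taper), eventually reaching the
  medication-free step.

Internally the taper ladder (reversed) and the escalation ladder are joined
into one *full ladder*, ordered from medication-free up to the most intensive
drug, so both rules are single-index moves.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence


class ConfigError(ValueError):
    """Raised for invalid strategy or run configuration."""


class HealthState(enum.IntEnum):
    """DAS28-defined disease-activity state, ordered by severity."""

    REMISSION = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: DAS28 cut points: <=2.6 remission, <=3.2 low, <=5.1 moderate, >5.1 high.
DAS28_CUTOFFS = (2.6, 3.2, 5.1)

N_STATES = len(HealthState)


def classify_das28(score: float) -> HealthState:
    """Map a DAS28 score to its health state.

    Boundaries belong to the lower state: 2.6 is remission, 3.2 is low,
    5.1 is moderate.

    Raises
    ------
    ValueError
        If ``score`` is negative, NaN or infinite.
    """
    score = float(score)
    if not math.isfinite(score) or score < 0.0:
        raise ValueError(f"DAS28 score must be finite and >= 0, got {score!r}")
    if score <= DAS28_CUTOFFS[0]:
        return HealthState.REMISSION
    if score <= DAS28_CUTOFFS[1]:
        return HealthState.LOW
    if score <= DAS28_CUTOFFS[2]:
        return HealthState.MODERATE
    return HealthState.HIGH


class TreatmentMode(enum.Enum):
    ESCALATING = "escalating"
    TAPERING = "tapering"
    MEDICATION_FREE = "medication_free"


@dataclass(frozen=True)
class TreatmentStep:
    """One rung of a treatment ladder.

    Parameters
    ----------
    name : str
        Human-readable drug/dose label.
    drug_cost_per_cycle : float
        Medication cost in EUR per 3-month cycle (>= 0).
    transition_key : str
        Identifier linking the step to its estimated transition matrix.
    """

    name: str
    drug_cost_per_cycle: float
    transition_key: str

    def __post_init__(self) -> None:
        if self.drug_cost_per_cycle < 0:
            raise ConfigError(
                f"drug_cost_per_cycle must be >= 0 for step {self.name!r}"
            )


@dataclass(frozen=True)
class StrategySpec:
    """A treat-to-target strategy: escalation ladder, taper ladder, taper rule.

    ``taper_ladder`` is ordered in taper direction and must end in the
    medication-free step.  ``flare_from_free`` selects where a flare from the
    medication-free state re-escalates to: ``"one_step"`` (default, the lowest
    taper rung) or ``"last_effective"`` (the step on which sustained remission
    was last achieved).
    """

    name: str
    escalation_ladder: tuple[TreatmentStep, ...]
    taper_ladder: tuple[TreatmentStep, ...]
    sustained_remission_cycles: int = 2
    flare_from_free: str = "one_step"

    def __post_init__(self) -> None:
        object.__setattr__(self, "escalation_ladder", tuple(self.escalation_ladder))
        object.__setattr__(self, "taper_ladder", tuple(self.taper_ladder))
        if not self.escalation_ladder:
            raise ConfigError("escalation_ladder must be non-empty")
        if not self.taper_ladder:
            raise ConfigError("taper_ladder must be non-empty")
        if self.sustained_remission_cycles < 1:
            raise ConfigError("sustained_remission_cycles must be >= 1")
        if self.flare_from_free not in ("one_step", "last_effective"):
            raise ConfigError(
                f"flare_from_free must be 'one_step' or 'last_effective', "
                f"got {self.flare_from_free!r}"
            )
        keys = [s.transition_key for s in self.full_ladder]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ConfigError(f"duplicate transition keys in strategy: {dupes}")

    @property
    def full_ladder(self) -> tuple[TreatmentStep, ...]:
        """Ladder positions ordered medication-free .. most intensive drug."""
        return tuple(reversed(self.taper_ladder)) + self.escalation_ladder

    @property
    def entry_index(self) -> int:
        """Full-ladder index of the strategy's entry (first escalation) step."""
        return len(self.taper_ladder)

    @property
    def transition_keys(self) -> tuple[str, ...]:
        return tuple(s.transition_key for s in self.full_ladder)

    @property
    def medication_free_step(self) -> TreatmentStep:
        return self.taper_ladder[-1]

    def to_dict(self) -> dict:
        def _steps(steps: Iterable[TreatmentStep]) -> list[dict]:
            return [
                {
                    "name": s.name,
                    "drug_cost_per_cycle": s.drug_cost_per_cycle,
                    "transition_key": s.transition_key,
                }
                for s in steps
            ]

        return {
            "name": self.name,
            "escalation_ladder": _steps(self.escalation_ladder),
            "taper_ladder": _steps(self.taper_ladder),
            "sustained_remission_cycles": self.sustained_remission_cycles,
            "flare_from_free": self.flare_from_free,
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "StrategySpec":
        try:
            esc = tuple(TreatmentStep(**s) for s in cfg["escalation_ladder"])
            tap = tuple(TreatmentStep(**s) for s in cfg["taper_ladder"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed strategy config: {exc}") from exc
        return cls(
            name=cfg.get("name", "custom"),
            escalation_ladder=esc,
            taper_ladder=tap,
            sustained_remission_cycles=int(cfg.get("sustained_remission_cycles", 2)),
            flare_from_free=cfg.get("flare_from_free", "one_step"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StrategySpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Preset strategies.  Drug costs per 3-month cycle are configuration inputs
# (EUR, plausible 2016 Dutch magnitudes); override via custom configs.

STEP_UP = "STEP_UP"
INITIAL_COMBINATION = "INITIAL_COMBINATION"

_PRESETS: dict[str, dict] = {
    STEP_UP: {
        "name": "step-up",
        "escalation_ladder": [
            {"name": "MTX monotherapy", "drug_cost_per_cycle": 25.0,
             "transition_key": "mtx_mono"},
            {"name": "MTX + csDMARD combination", "drug_cost_per_cycle": 55.0,
             "transition_key": "mtx_csdmard"},
            {"name": "adalimumab", "drug_cost_per_cycle": 2900.0,
             "transition_key": "tnfi_1"},
            {"name": "second TNF inhibitor", "drug_cost_per_cycle": 2900.0,
             "transition_key": "tnfi_2"},
        ],
        "taper_ladder": [
            {"name": "low-dose MTX", "drug_cost_per_cycle": 15.0,
             "transition_key": "mtx_low"},
            {"name": "medication-free", "drug_cost_per_cycle": 0.0,
             "transition_key": "med_free_su"},
        ],
        "sustained_remission_cycles": 2,
    },
    INITIAL_COMBINATION: {
        "name": "initial-combination",
        "escalation_ladder": [
            {"name": "csDMARD combination low dose", "drug_cost_per_cycle": 60.0,
             "transition_key": "combo_low"},
            {"name": "csDMARD combination high dose", "drug_cost_per_cycle": 95.0,
             "transition_key": "combo_high"},
            {"name": "biological 1", "drug_cost_per_cycle": 2900.0,
             "transition_key": "bio_1"},
            {"name": "biological 2", "drug_cost_per_cycle": 2900.0,
             "transition_key": "bio_2"},
            {"name": "biological 3", "drug_cost_per_cycle": 2900.0,
             "transition_key": "bio_3"},
        ],
        "taper_ladder": [
            {"name": "low-dose csDMARD combination", "drug_cost_per_cycle": 30.0,
             "transition_key": "combo_taper"},
            {"name": "medication-free", "drug_cost_per_cycle": 0.0,
             "transition_key": "med_free_ic"},
        ],
        "sustained_remission_cycles": 2,
    },
}


def build_strategy(preset_or_config) -> StrategySpec:
    """Build a :class:`StrategySpec` from a preset name or a config mapping.

    ``"STEP_UP"`` is the 4-step MTX-first ladder (MTX mono -> MTX+csDMARD ->
    adalimumab -> second TNFi); ``"INITIAL_COMBINATION"`` is the 5-step
    csDMARD-combination-first ladder with three biologic rungs.  Any mapping
    with ``escalation_ladder``/``taper_ladder`` entries defines a custom
    strategy.
    """
    if isinstance(preset_or_config, StrategySpec):
        return preset_or_config
    if isinstance(preset_or_config, str):
        key = preset_or_config.upper().replace("-", "_")
        if key not in _PRESETS:
            raise ConfigError(
                f"unknown strategy preset {preset_or_config!r}; "
                f"expected one of {sorted(_PRESETS)}"
            )
        return StrategySpec.from_dict(_PRESETS[key])
    if isinstance(preset_or_config, Mapping):
        return StrategySpec.from_dict(preset_or_config)
    raise ConfigError(
        f"cannot build strategy from {type(preset_or_config).__name__}"
    )


@dataclass(frozen=True)
class TreatmentPosition:
    """Position of a patient on a strategy's full ladder.

    ``consecutive_remission_cycles`` counts cycle starts spent in remission
    since the last treatment change; it is reset by any non-remission cycle
    start and by every ladder move.  ``last_effective_index`` remembers the
    ladder index on which sustained remission was last achieved.
    """

    strategy: StrategySpec = field(compare=False)
    index: int
    consecutive_remission_cycles: int = 0
    last_effective_index: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.index < len(self.strategy.full_ladder):
            raise ConfigError(f"ladder index {self.index} out of range")
        if self.consecutive_remission_cycles < 0:
            raise ConfigError("consecutive_remission_cycles must be >= 0")

    @property
    def step(self) -> TreatmentStep:
        return self.strategy.full_ladder[self.index]

    @property
    def mode(self) -> TreatmentMode:
        if self.index == 0:
            return TreatmentMode.MEDICATION_FREE
        if self.index < self.strategy.entry_index:
            return TreatmentMode.TAPERING
        return TreatmentMode.ESCALATING

    @property
    def last_effective_step(self) -> TreatmentStep | None:
        if self.last_effective_index is None:
            return None
        return self.strategy.full_ladder[self.last_effective_index]


def initial_position(strategy: StrategySpec) -> TreatmentPosition:
    """Entry position: first escalation step, counter zero."""
    return TreatmentPosition(strategy=strategy, index=strategy.entry_index)


def advance_treatment(
    pos: TreatmentPosition,
    state_at_cycle_start: HealthState,
    strategy: StrategySpec | None = None,
) -> TreatmentPosition:
    """Apply the treat-to-target protocol rules at a cycle start.

    Remission increments the sustained-remission counter; when it reaches
    ``sustained_remission_cycles`` the patient moves one ladder step down
    (taper; absorbing at medication-free).  Non-remission moves the patient
    one medication step up (capped at the top of the ladder) and resets the
    counter.
    """
    strategy = strategy if strategy is not None else pos.strategy
    top = len(strategy.full_ladder) - 1
    if state_at_cycle_start == HealthState.REMISSION:
        counter = pos.consecutive_remission_cycles + 1
        if counter >= strategy.sustained_remission_cycles:
            new_index = max(pos.index - 1, 0)
            last_eff = pos.index if pos.index > 0 else pos.last_effective_index
            return replace(
                pos,
                index=new_index,
                consecutive_remission_cycles=0,
                last_effective_index=last_eff,
            )
        return replace(pos, consecutive_remission_cycles=counter)
    # Flare / treatment failure: one medication step up.
    if (
        pos.index == 0
        and strategy.flare_from_free == "last_effective"
        and pos.last_effective_index is not None
    ):
        new_index = pos.last_effective_index
    else:
        new_index = min(pos.index + 1, top)
    return replace(pos, index=new_index, consecutive_remission_cycles=0)
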