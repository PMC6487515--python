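"""Estimation of per-treatment-step transition matrices from visit records.

Longitudinal visit records (one row per clinic visit with a DAS28 score and
the treatment step in use) are converted into 3-monthly state transitions by
pairing each visit with a later visit whose time gap falls inside a tolerance
window around one cycle.  Sample proportions of destination states, grouped
by the treatment step at the earlier visit, give row-stochastic 4x4 matrices.
A chi-squared homogeneity test checks stability of each row over calendar
time, and observed counts map directly onto Dirichlet concentration vectors
for probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import N_STATES, HealthState, classify_das28

#: Default cycle length and pairing window, in days (3 months / 1.5 months).
CYCLE_DAYS = 91
WINDOW_DAYS = 46

VISIT_COLUMNS = [
    "patient_id", "visit_day", "das28", "treatment_key",
    "mo", "sc", "ua", "pd", "ad", "interval_cost", "sick_days",
]


class MissingDataError(KeyError):
    """A requested treatment key has no observed transitions."""


class Transition(NamedTuple):
    """One observed 3-monthly state transition."""

    treatment_key: str
    from_state: HealthState
    to_state: HealthState
    source_day: float


def read_visits_csv(path) -> pd.DataFrame:
    """Read a visit-record CSV (columns ``patient_id,visit_day,das28,
    treatment_key,mo,sc,ua,pd,ad,interval_cost,sick_days``)."""
    df = pd.read_csv(path)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit CSV is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"visit CSV {path} contains no records")
    return df


def window_transitions(
    visits: pd.DataFrame,
    cycle_days: int = CYCLE_DAYS,
    window_days: int = WINDOW_DAYS,
    treatment_key_map: dict | None = None,
) -> list[Transition]:
    """Pair visits into 3-monthly transitions.

    For each visit, candidate successors are the same patient's later visits
    with time gap in ``[cycle_days - window_days, cycle_days + window_days]``;
    the candidate with gap closest to ``cycle_days`` is paired (ties go to the
    earlier visit).  The transition is labelled with the treatment key at the
    earlier visit.  Visits with no successor in the window contribute nothing.

    ``treatment_key_map`` optionally maps raw treatment labels onto pooled
    transition keys (e.g. several dose levels of one drug onto a single
    treatment step); unmapped labels pass through unchanged.

    ``visits`` must be sorted by ``visit_day`` (strictly increasing) within
    each patient.
    """
    required = {"patient_id", "visit_day", "das28", "treatment_key"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visits frame is missing columns: {sorted(missing)}")
    if len(visits) == 0:
        return []
    lo, hi = cycle_days - window_days, cycle_days + window_days
    out: list[Transition] = []
    for pid, grp in visits.groupby("patient_id", sort=False):
        days = grp["visit_day"].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError(
                f"visit days for patient {pid!r} are not strictly increasing"
            )
        states = np.array([classify_das28(s) for s in grp["das28"]])
        keys = grp["treatment_key"].to_numpy()
        if treatment_key_map:
            keys = np.array([treatment_key_map.get(k, k) for k in keys])
        left = np.searchsorted(days, days + lo, side="left")
        right = np.searchsorted(days, days + hi, side="right")
        for i in range(len(days)):
            if left[i] >= right[i]:
                continue
            gaps = days[left[i]:right[i]] - days[i]
            j = left[i] + int(np.argmin(np.abs(gaps - cycle_days)))
            out.append(
                Transition(keys[i], HealthState(states[i]),
                           HealthState(states[j]), float(days[i]))
            )
    return out


@dataclass
class TransitionModel:
    """Per-treatment-step 4x4 transition matrices with underlying counts.

    ``probs[key]`` rows are row-stochastic; ``counts[key]`` holds the observed
    transition counts the probabilities were estimated from (all zeros for a
    model constructed directly from probabilities, e.g. a PSA draw).
    """

    counts: dict[str, np.ndarray]
    probs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for key, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (N_STATES, N_STATES):
                raise ValueError(f"matrix for {key!r} has shape {p.shape}")
            if np.any(p < -1e-12):
                raise ValueError(f"negative probabilities for {key!r}")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {key!r} do not sum to 1")
            self.probs[key] = p

    @property
    def keys(self) -> list[str]:
        return list(self.probs)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, np.ndarray],
        prior_per_cell: float = 0.0,
        zero_row: str = "identity",
    ) -> "TransitionModel":
        """Normalise count matrices into probabilities.

        Rows with no observations (and zero prior) fall back to a
        self-transition (``zero_row="identity"``) or raise
        (``zero_row="error"``).
        """
        probs: dict[str, np.ndarray] = {}
        for key, c in counts.items():
            c = np.asarray(c, dtype=float)
            smoothed = c + prior_per_cell
            rowsum = smoothed.sum(axis=1)
            p = np.empty_like(smoothed)
            for r in range(N_STATES):
                if rowsum[r] > 0:
                    p[r] = smoothed[r] / rowsum[r]
                elif zero_row == "identity":
                    p[r] = np.eye(N_STATES)[r]
                else:
                    raise ValueError(
                        f"no observations for {key!r} from state "
                        f"{HealthState(r).name} and prior 0"
                    )
            probs[key] = p
        return cls(counts={k: np.asarray(v) for k, v in counts.items()},
                   probs=probs)

    @classmethod
    def from_probs(cls, probs: dict[str, np.ndarray]) -> "TransitionModel":
        return cls(
            counts={k: np.zeros((N_STATES, N_STATES)) for k in probs},
            probs={k: np.asarray(v, dtype=float) for k, v in probs.items()},
        )

    def stacked(self, key_order: Sequence[str]) -> np.ndarray:
        """(K, 4, 4) probability array in the given key order."""
        try:
            return np.stack([self.probs[k] for k in key_order])
        except KeyError as exc:
            raise MissingDataError(f"no transition matrix for key {exc}") from exc

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: treatment_key, from_state, to_state, count,
        probability."""
        rows = []
        for key in self.keys:
            for fs in HealthState:
                for ts in HealthState:
                    rows.append({
                        "treatment_key": key,
                        "from_state": fs.name,
                        "to_state": ts.name,
                        "count": float(self.counts[key][fs, ts]),
                        "probability": float(self.probs[key][fs, ts]),
                    })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionModel":
        counts: dict[str, np.ndarray] = {}
        probs: dict[str, np.ndarray] = {}
        for key, grp in df.groupby("treatment_key", sort=False):
            c = np.zeros((N_STATES, N_STATES))
            p = np.zeros((N_STATES, N_STATES))
            for _, row in grp.iterrows():
                i = HealthState[row["from_state"]]
                j = HealthState[row["to_state"]]
                c[i, j] = row["count"]
                p[i, j] = row["probability"]
            counts[key] = c
            probs[key] = p
        return cls(counts=counts, probs=probs)


def count_transitions(
    transitions: Iterable[Transition],
) -> dict[str, np.ndarray]:
    """Tally transitions into per-key 4x4 count matrices."""
    counts: dict[str, np.ndarray] = {}
    for t in transitions:
        c = counts.setdefault(t.treatment_key, np.zeros((N_STATES, N_STATES)))
        c[t.from_state, t.to_state] += 1
    return counts


def estimate_matrices(
    transitions: Iterable[Transition],
    required_keys: Sequence[str] | None = None,
    prior_per_cell: float = 0.0,
) -> TransitionModel:
    """Estimate transition probabilities as sample proportions.

    ``required_keys`` lists treatment keys that must be present in the data;
    any that are absent raise :class:`MissingDataError` naming them.  Source
    states never observed under a key get an identity (self-transition) row.
    """
    counts = count_transitions(transitions)
    if not counts and not required_keys:
        raise ValueError("no transitions to estimate from")
    if required_keys is not None:
        absent = [k for k in required_keys if k not in counts]
        if absent:
            raise MissingDataError(
                f"no observed transitions for treatment keys: {absent}"
            )
    return TransitionModel.from_counts(counts, prior_per_cell=prior_per_cell)


def stationarity_test(
    transitions: Sequence[Transition],
    split_day: float | None = None,
) -> pd.DataFrame:
    """Chi-squared homogeneity test of each transition row over time.

    Destination-state counts before vs after ``split_day`` (default: median
    source day over all transitions) are compared with a Pearson chi-squared
    test.  Rows with any expected cell count below 5, or with all transitions
    on one side of the split, are flagged as untestable rather than tested.
    """
    transitions = list(transitions)
    if not transitions:
        raise ValueError("no transitions supplied")
    if split_day is None:
        split_day = float(np.median([t.source_day for t in transitions]))
    rows = []
    keys = sorted({t.treatment_key for t in transitions})
    for key in keys:
        for fs in HealthState:
            sub = [t for t in transitions
                   if t.treatment_key == key and t.from_state == fs]
            if not sub:
                continue
            table = np.zeros((2, N_STATES))
            for t in sub:
                table[0 if t.source_day < split_day else 1, t.to_state] += 1
            table = table[:, table.sum(axis=0) > 0]
            rec = {
                "treatment_key": key, "from_state": fs.name,
                "n_before": int(table[0].sum()), "n_after": int(table[1].sum()),
                "split_day": split_day,
                "statistic": np.nan, "df": np.nan, "pvalue": np.nan,
                "flagged": False, "reason": "",
            }
            if table[0].sum() == 0 or table[1].sum() == 0:
                rec["flagged"] = True
                rec["reason"] = "all transitions on one side of the split"
            elif table.shape[1] < 2:
                rec["statistic"], rec["df"], rec["pvalue"] = 0.0, 0, 1.0
                rec["flagged"] = True
                rec["reason"] = "single destination state"
            else:
                res = stats.chi2_contingency(table, correction=False)
                expected = res.expected_freq
                rec["statistic"] = float(res.statistic)
                rec["df"] = int(res.dof)
                rec["pvalue"] = float(res.pvalue)
                if np.any(expected < 5):
                    rec["flagged"] = True
                    rec["reason"] = "expected cell count < 5"
            rows.append(rec)
    return pd.DataFrame(rows)


def dirichlet_params(
    count_matrix: np.ndarray, prior_per_cell: float = 1.0
) -> np.ndarray:
    """Dirichlet concentration vectors for each row of a count matrix.

    Concentration = counts + ``prior_per_cell``; rows with fewer observations
    imply wider (more uncertain) Dirichlet distributions.  An all-zero row
    with zero prior has no proper Dirichlet and raises.
    """
    c = np.asarray(count_matrix, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if prior_per_cell < 0:
        raise ValueError("prior_per_cell must be >= 0")
    conc = c + prior_per_cell
    if np.any(conc.sum(axis=1) == 0):
        raise ValueError("all-zero count row with prior 0 has no distribution")
    return conc
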