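"""Incremental cost-effectiveness outputs: ICER, CE plane, CEAC, NMB.

Convention: intervention I is the comparator (here: step-up therapy) and
intervention II the alternative (initial combination therapy);
ICER = (C_II - C_I) / (E_II - E_I).  A negative ICER is ambiguous on its own
— it arises both when II is cheaper and more effective (dominant) and when
it is costlier and less effective (dominated) — so every comparison also
carries an explicit dominance/quadrant label.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WTP_GRID = tuple(np.linspace(0, 100_000, 101))


class Dominance(enum.Enum):
    DOMINANT_II = "II dominant (less costly, more effective)"
    DOMINATED_II = "II dominated (more costly, less effective)"
    TRADEOFF_NE = "trade-off (II more costly, more effective)"
    TRADEOFF_SW = "trade-off (II less costly, less effective)"


@dataclass(frozen=True)
class CEComparison:
    """Pairwise cost-effectiveness comparison of interventions I and II."""

    cost_i: float
    effect_i: float
    cost_ii: float
    effect_ii: float
    delta_cost: float
    delta_effect: float
    icer: float | None
    icer_label: str
    dominance: Dominance | None

    def summary(self) -> dict:
        return {
            "cost_I": round(self.cost_i, 2),
            "cost_II": round(self.cost_ii, 2),
            "effect_I": round(self.effect_i, 3),
            "effect_II": round(self.effect_ii, 3),
            "delta_cost": round(self.delta_cost, 2),
            "delta_effect": round(self.delta_effect, 4),
            "icer": None if self.icer is None else round(self.icer),
            "icer_label": self.icer_label,
            "dominance": None if self.dominance is None else self.dominance.name,
        }


def icer(
    cost_i: float, effect_i: float, cost_ii: float, effect_ii: float
) -> CEComparison:
    """ICER of intervention II vs I with dominance disambiguation.

    A zero effect difference yields a labelled, non-numeric ICER.  Exact ties
    in either dimension carry no dominance label.
    """
    for v in (cost_i, effect_i, cost_ii, effect_ii):
        if not math.isfinite(v):
            raise ValueError("costs and effects must be finite")
    dc = cost_ii - cost_i
    de = effect_ii - effect_i
    if dc < 0 and de > 0:
        dom = Dominance.DOMINANT_II
    elif dc > 0 and de < 0:
        dom = Dominance.DOMINATED_II
    elif dc > 0 and de > 0:
        dom = Dominance.TRADEOFF_NE
    elif dc < 0 and de < 0:
        dom = Dominance.TRADEOFF_SW
    else:
        dom = None
    if de == 0:
        value, label = None, "undefined (zero effect difference)"
    else:
        value = dc / de
        label = f"{value:,.0f}"
        if dom is Dominance.DOMINANT_II:
            label += " (dominating)"
        elif dom is Dominance.DOMINATED_II:
            label += " (dominated)"
    return CEComparison(
        cost_i=cost_i, effect_i=effect_i, cost_ii=cost_ii,
        effect_ii=effect_ii, delta_cost=dc, delta_effect=de,
        icer=value, icer_label=label, dominance=dom,
    )


@dataclass(frozen=True)
class PlaneSummary:
    """Quadrant shares of a cost-effectiveness plane sample cloud."""

    n: int
    fractions: dict
    wtp: float | None
    cost_effective_fraction: float | None


def ce_plane_summary(
    delta_costs: Sequence[float],
    delta_effects: Sequence[float],
    wtp: float | None = None,
) -> PlaneSummary:
    """Quadrant fractions of paired incremental samples, and the fraction
    cost-effective at a willingness-to-pay threshold.

    Quadrants partition the plane exactly (east: delta effect > 0; north:
    delta cost > 0; axis points fall west/south respectively), so the four
    fractions sum to 1.  Cost-effective at WTP lambda means
    ``delta_cost <= lambda * delta_effect`` (the net-benefit rule).
    """
    dc = np.asarray(delta_costs, dtype=float)
    de = np.asarray(delta_effects, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need non-empty, equal-length sample arrays")
    n = dc.size
    east = de > 0
    north = dc > 0
    fractions = {
        "NE": float(np.sum(east & north)) / n,
        "SE": float(np.sum(east & ~north)) / n,
        "NW": float(np.sum(~east & north)) / n,
        "SW": float(np.sum(~east & ~north)) / n,
    }
    ce_frac = None
    if wtp is not None:
        if wtp < 0:
            raise ValueError("WTP must be >= 0")
        ce_frac = float(np.mean(dc <= wtp * de))
    return PlaneSummary(n=n, fractions=fractions, wtp=wtp,
                        cost_effective_fraction=ce_frac)


def ceac(
    delta_costs: Sequence[float],
    delta_effects: Sequence[float],
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Each point is the fraction of samples with net monetary benefit >= 0,
    i.e. :func:`ce_plane_summary`'s cost-effective fraction at that WTP.
    """
    dc = np.asarray(delta_costs, dtype=float)
    de = np.asarray(delta_effects, dtype=float)
    if dc.size == 0:
        raise ValueError("need non-empty samples")
    grid = np.asarray(sorted(wtp_grid), dtype=float)
    probs = [float(np.mean(dc <= w * de)) for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})


def net_monetary_benefit(
    delta_cost: float, delta_effect: float, wtp: float
) -> float:
    """Incremental net monetary benefit ``wtp * dE - dC`` of II vs I."""
    return wtp * delta_effect - delta_cost
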