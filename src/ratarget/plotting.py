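"""Optional plotting helpers (cost-effectiveness plane, occupancy, CEAC)."""

from __future__ import annotations

import numpy as np

from .states import HealthState


def plot_ce_plane(delta_effects, delta_costs, wtp: float | None = None,
                  ax=None):
    """Scatter the incremental sample cloud on the CE plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(delta_effects, delta_costs, s=8, alpha=0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, color="tab:red", lw=0.8, ls="--",
                label=f"WTP = {wtp:,.0f}")
        ax.legend()
    ax.set_xlabel("Incremental effect (QALY)")
    ax.set_ylabel("Incremental cost (EUR)")
    return ax


def plot_occupancy(occupancy, cycle_years: float = 0.25, ax=None):
    """State-occupancy fractions over the model horizon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(occupancy.shape[0]) * cycle_years
    for s in HealthState:
        ax.plot(t, occupancy[:, s], label=s.name.lower())
    ax.set_xlabel("Years")
    ax.set_ylabel("Fraction of cohort")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_ceac(ceac_frame, ax=None):
    """Cost-effectiveness acceptability curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ceac_frame["wtp"], ceac_frame["prob_cost_effective"])
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1.02)
    return ax
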