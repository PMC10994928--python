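"""Raster and time-course figures."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bursts import BurstInterval, NetworkBurstEvent
from .core import WellRecording
from .timecourse import ConditionAggregate

__all__ = ["raster_plot", "timecourse_plot"]


def raster_plot(
    well: WellRecording,
    bursts: Optional[Mapping[str, Sequence[BurstInterval]]] = None,
    events: Optional[Sequence[NetworkBurstEvent]] = None,
    ax: Optional[plt.Axes] = None,
    window: Optional[tuple] = None,
):
    """Spike raster of one well with optional burst / network-burst overlays."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    eids = sorted(well.trains)
    for row, eid in enumerate(eids):
        t = well.trains[eid].times
        ax.vlines(t, row + 0.6, row + 1.4, color="k", lw=0.4)
        if bursts:
            for b in bursts.get(eid, []):
                ax.plot([b.start, b.end], [row + 1, row + 1], color="tab:orange", lw=3, alpha=0.7)
    if events:
        for e in events:
            ax.axvspan(e.start, e.end, color="tab:red", alpha=0.15)
    if window:
        ax.set_xlim(*window)
    ax.set_ylim(0.4, len(eids) + 0.6)
    ax.set_yticks(range(1, len(eids) + 1), eids)
    ax.set_xlabel("time (s)")
    ax.set_title(f"{well.well_id} | {well.condition} | t = {well.timepoint_h:g} h")
    return ax


def timecourse_plot(
    aggregates: Sequence[ConditionAggregate],
    metric: str = "nbr",
    ax: Optional[plt.Axes] = None,
):
    """Mean +/- SEM bands of a normalized metric per condition over hypoxia."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for agg in aggregates:
        mu = agg.mean[metric]
        sem = agg.sem[metric]
        ax.plot(agg.timepoints, mu, marker="o", label=agg.condition)
        ax.fill_between(agg.timepoints, mu - sem, mu + sem, alpha=0.25)
    ax.set_xlabel("hours in hypoxia")
    ax.set_ylabel(f"normalized {metric.upper()}")
    ax.axhline(1.0, color="grey", lw=0.5, ls="--")
    ax.legend()
    return ax
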