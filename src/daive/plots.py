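"""Diagnostic plots: cost–outcome frontier, concentration curves, Q–NHV hulls."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt

from .equity import EquityResult
from .frontiers import CostOutcomePoint, NetHealthEquityFrontier, NetHealthPoint

__all__ = [
    "plot_value_frontier",
    "plot_concentration_curves",
    "plot_equitability_bars",
    "plot_equity_frontier",
]


def plot_value_frontier(
    points: Sequence[CostOutcomePoint], frontier_labels: Sequence[str], ax=None
):
    """Cost vs expected-gain scatter with the value efficiency frontier."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter([p.cost for p in points], [p.gain for p in points], color="0.4", s=25)
    for p in points:
        ax.annotate(p.condition, (p.cost, p.gain), fontsize=8,
                    textcoords="offset points", xytext=(4, 3))
    on = [p for p in points if p.condition in set(frontier_labels)]
    on.sort(key=lambda p: p.cost)
    ax.plot([p.cost for p in on], [p.gain for p in on], "-o", color="C0")
    ax.set_xlabel("cost $C_t$")
    ax.set_ylabel(r"expected outcome gain $\hat{Y}_t$")
    ax.set_title("Value efficiency frontier")
    return ax


def plot_concentration_curves(
    results: Mapping[str, EquityResult],
    conditions: Sequence[str] | None = None,
    ax=None,
):
    """Concentration curves h_t(R) with the 45° equal-distribution reference."""
    if ax is None:
        _, ax = plt.subplots()
    labels = conditions or [c for c, r in results.items() if not r.excluded]
    for label in labels:
        r = results[label]
        if r.excluded or r.curve is None:
            continue
        ranks, heights = r.curve.as_arrays()
        ax.plot(ranks, heights, "-o", ms=3, label=label)
    ax.plot([0, 1], [0, 1], "--", color="0.5", label="45° line")
    ax.set_xlabel("cumulative population rank $R_g$ (by advantage)")
    ax.set_ylabel("cumulative share of expected gains $h_t(R_g)$")
    ax.set_title("Concentration curves")
    ax.legend(fontsize=8)
    return ax


def plot_equitability_bars(results: Mapping[str, EquityResult], ax=None):
    """Equitability Q_t per included condition, sorted ascending."""
    if ax is None:
        _, ax = plt.subplots()
    rows = sorted(
        ((r.condition, r.equitability) for r in results.values() if not r.excluded),
        key=lambda item: item[1],
    )
    ax.bar([c for c, _ in rows], [q for _, q in rows], color="C0")
    ax.axhline(0.0, color="0.3", lw=0.8)
    ax.set_ylabel("equitability $Q_t$")
    ax.set_title("Intervention equitability")
    return ax


def plot_equity_frontier(
    points: Sequence[NetHealthPoint], frontier: NetHealthEquityFrontier, ax=None
):
    """Q vs NHV scatter at one λ with the net health equity frontier hull."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter([p.equitability for p in points], [p.nhv for p in points],
               color="0.4", s=25)
    for p in points:
        ax.annotate(p.condition, (p.equitability, p.nhv), fontsize=8,
                    textcoords="offset points", xytext=(4, 3))
    ax.plot(
        [p.equitability for p in frontier.members],
        [p.nhv for p in frontier.members],
        "-o",
        color="C1",
    )
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("equitability $Q_t$")
    ax.set_ylabel(rf"net health value $NHV_t(\lambda={frontier.wtp:g})$")
    ax.set_title(rf"Net health equity frontier, $\lambda$ = {frontier.wtp:g}")
    return ax
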