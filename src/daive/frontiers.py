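"""Value efficiency and net health equity frontiers.

Two convex-hull constructions drive the decision analysis:

* The **value efficiency frontier** in the (cost C_t, expected gain Ŷ_t)
  plane: the lower-right convex hull anchored at the least costly condition.
  Non-members are dominated (cost more, gain less) or extended-dominated
  (their incremental cost-effectiveness ratio, ICER = Δcost/Δgain, is beaten
  by skipping them); along the frontier the ICER sequence strictly increases.

* The **net health equity frontier** in the (equitability Q_t, net health
  value NHV_t(λ)) plane at a given willingness-to-pay λ, where
  NHV_t(λ) = λ·Ŷ_t − C_t: the upper-right convex hull running from the
  maximum-NHV condition to the maximum-Q condition.  Its members are the
  decision contenders; everything else is dominated in both criteria at once
  or falls below a hull chord.

Both hulls operate on point estimates; posterior uncertainty is reporting
metadata only.  Ties are broken deterministically (higher gain at equal cost;
fewer On components, then lexicographic label, at exact ties) and collinear
points are excluded by default (strict hull) with a switch to keep them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CostOutcomePoint",
    "ValueEfficiencyFrontier",
    "NetHealthPoint",
    "NetHealthEquityFrontier",
    "net_health_value",
    "value_efficiency_frontier",
    "icers",
    "representative_wtp",
    "net_health_equity_frontier",
    "quadrant",
]


def net_health_value(gain: float, cost: float, wtp: float) -> float:
    """Net health value NHV(λ) = λ · Ŷ − C (gains monetized at λ, net of cost)."""
    if not wtp > 0:
        raise ValueError("willingness-to-pay must be positive")
    return wtp * gain - cost


@dataclass(frozen=True)
class CostOutcomePoint:
    """One condition in the cost–expected-outcome plane."""

    condition: str
    cost: float
    gain: float
    n_components: int | None = None

    def _tiebreak(self) -> tuple:
        n = self.n_components if self.n_components is not None else len(self.condition)
        return (n, self.condition)


@dataclass(frozen=True)
class ValueEfficiencyFrontier:
    """Ordered frontier members (increasing cost) with their ICERs."""

    members: tuple[CostOutcomePoint, ...]
    icers: tuple[float, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.condition for p in self.members)


def value_efficiency_frontier(
    points: Sequence[CostOutcomePoint], include_collinear: bool = False
) -> ValueEfficiencyFrontier:
    """Lower-right convex hull of cost vs gain, anchored at the least costly point.

    Greedy minimum-ICER construction: starting from the cheapest condition,
    repeatedly step to the strictly costlier and strictly higher-gain point
    with the smallest incremental ratio.  This drops strictly dominated points
    and extended-dominated points in one pass and yields strictly increasing
    ICERs; with ``include_collinear`` points lying exactly on a hull segment
    are kept as members.
    """
    if not points:
        raise ValueError("need at least one cost-outcome point")
    anchor = min(points, key=lambda p: (p.cost, -p.gain) + p._tiebreak())
    members = [anchor]
    ratios: list[float] = []
    current = anchor
    while True:
        candidates = [
            p for p in points if p.cost > current.cost and p.gain > current.gain
        ]
        if not candidates:
            break
        def ratio(p: CostOutcomePoint) -> float:
            return (p.cost - current.cost) / (p.gain - current.gain)
        best = min(ratio(p) for p in candidates)
        at_best = [
            p for p in candidates if np.isclose(ratio(p), best, rtol=0.0, atol=1e-12)
        ]
        # Strict hull: jump to the farthest point on the minimum-ICER ray,
        # skipping collinear intermediates; inclusive hull: take the nearest
        # first so collinear points become members too.
        if include_collinear:
            nxt = min(at_best, key=lambda p: (p.gain,) + p._tiebreak())
        else:
            nxt = min(at_best, key=lambda p: (-p.gain,) + p._tiebreak())
        members.append(nxt)
        ratios.append(ratio(nxt))
        current = nxt
    return ValueEfficiencyFrontier(tuple(members), tuple(ratios))


def icers(frontier: ValueEfficiencyFrontier) -> tuple[float, ...]:
    """ICERs between consecutive frontier members (strictly increasing)."""
    if len(frontier.members) < 2:
        raise ValueError("ICERs need at least two frontier members")
    return frontier.icers


def representative_wtp(
    icer_values: Sequence[float] | None = None,
    values: Sequence[float] | None = None,
    below_factor: float = 0.5,
    above_factor: float = 1.5,
) -> tuple[float, ...]:
    """Representative willingness-to-pay thresholds.

    An explicit ``values`` list passes through verbatim (sorted, validated).
    Otherwise the bracketing strategy interleaves the frontier ICERs: half of
    the smallest ICER, the midpoints of consecutive ICERs, and
    ``above_factor`` times the largest — one λ per decision regime of the
    value efficiency frontier.
    """
    if values is not None:
        out = tuple(sorted(float(v) for v in values))
        if not out or any(v <= 0 for v in out):
            raise ValueError("explicit willingness-to-pay values must be positive")
        return out
    if not icer_values:
        raise ValueError("need frontier ICERs or an explicit willingness-to-pay list")
    ic = sorted(float(v) for v in icer_values)
    out = [below_factor * ic[0]]
    out.extend((a + b) / 2.0 for a, b in zip(ic[:-1], ic[1:]))
    out.append(above_factor * ic[-1])
    return tuple(out)


@dataclass(frozen=True)
class NetHealthPoint:
    """One condition in the equitability–net-health-value plane."""

    condition: str
    equitability: float  # Q_t
    nhv: float  # NHV_t(λ)
    n_components: int | None = None

    def _tiebreak(self) -> tuple:
        n = self.n_components if self.n_components is not None else len(self.condition)
        return (n, self.condition)


@dataclass(frozen=True)
class NetHealthEquityFrontier:
    """Contenders at one λ, ordered from highest NHV to highest Q."""

    wtp: float
    members: tuple[NetHealthPoint, ...]
    dominated: tuple[NetHealthPoint, ...] = field(default=())

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.condition for p in self.members)


def _pareto_upper_right(points: Sequence[NetHealthPoint]) -> list[NetHealthPoint]:
    keep: list[NetHealthPoint] = []
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            if q.equitability >= p.equitability and q.nhv >= p.nhv:
                if q.equitability > p.equitability or q.nhv > p.nhv:
                    dominated = True
                    break
                # exact (Q, NHV) tie: deterministic preference
                if q._tiebreak() < p._tiebreak():
                    dominated = True
                    break
        if not dominated:
            keep.append(p)
    return keep


def net_health_equity_frontier(
    points: Sequence[NetHealthPoint],
    wtp: float,
    include_collinear: bool = False,
) -> NetHealthEquityFrontier:
    """Upper-right convex hull over (Q, NHV) at willingness-to-pay λ.

    Input points must already have failed-exclusion conditions removed.  The
    hull starts at the maximum-NHV point, ends at the maximum-Q point, and its
    chord slopes are strictly decreasing (non-strictly when
    ``include_collinear``).
    """
    if not points:
        raise ValueError("need at least one point")
    pareto = _pareto_upper_right(points)
    # order from highest NHV to highest Q (Q ascending; NHV descends on the
    # Pareto set)
    pareto.sort(key=lambda p: (p.equitability, -p.nhv))
    hull: list[NetHealthPoint] = []
    for p in pareto:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # b is below (or on) the chord a->p  <=>  cross product <= 0
            cross = (b.equitability - a.equitability) * (p.nhv - a.nhv) - (
                b.nhv - a.nhv
            ) * (p.equitability - a.equitability)
            drop = cross >= 0 if not include_collinear else cross > 0
            if drop:
                hull.pop()
            else:
                break
        hull.append(p)
    members = tuple(hull)
    member_set = {p.condition for p in members}
    dominated = tuple(p for p in points if p.condition not in member_set)
    return NetHealthEquityFrontier(float(wtp), members, dominated)


def quadrant(q: float, nhv: float, tolerance: float = 0.0) -> str:
    """Quadrant label of a (Q, NHV) point by the signs of its coordinates.

    Q on the x-axis, NHV on the y-axis; values within ``tolerance`` of zero
    on either coordinate give ``"on-axis"``.
    """
    if abs(q) <= tolerance or abs(nhv) <= tolerance:
        return "on-axis"
    vertical = "upper" if nhv > 0 else "lower"
    horizontal = "right" if q > 0 else "left"
    return f"{vertical}-{horizontal}"
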