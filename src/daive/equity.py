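"""Health-gain concentration curves, concentration index, and equitability.

Individuals are ranked by systemic advantage and stratified into G groups
(quintiles by default).  For an intervention t with per-group expected gains
Ŷ_{t,g} and population shares w_g, the concentration curve plots the
cumulative share of expected gains against the cumulative population rank
R_g = Σ_{j≤g} w_j.  The health-gain concentration index H_t is twice the
signed area between the 45° line and the piecewise-linear curve — positive
when gains concentrate among the advantaged — and equitability is its
reversal, Q_t = −H_t, so that higher values mean equity-enhancing.

Unlike the classical income-rank concentration index, H_t is not confined to
[−1, 1]: group gains may be negative (iatrogenic effects), which can push the
curve far outside the unit square.  Interventions whose *total* expected gain
is non-positive are excluded up front — their curve is undefined or
meaningless — via :func:`apply_exclusion`; a small positive tolerance treats
"approximately zero" estimated gains as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupGains",
    "ConcentrationCurve",
    "ExclusionDecision",
    "EquityResult",
    "rank_boundaries",
    "apply_exclusion",
    "concentration_curve",
    "concentration_index",
    "equitability",
    "evaluate_equity",
    "equity_frame",
]


def rank_boundaries(weights: Sequence[float]) -> np.ndarray:
    """Cumulative rank boundaries R_0..R_G from population shares w_1..w_G.

    R_0 = 0 by construction, R_g = Σ_{j≤g} w_j, R_G = 1.  Weights must be
    positive and sum to one.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-d sequence")
    if np.any(w <= 0):
        raise ValueError("group weights must be strictly positive")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError(f"group weights must sum to 1, got {w.sum()}")
    r = np.concatenate([[0.0], np.cumsum(w)])
    r[-1] = 1.0  # pin against accumulated rounding
    return r


@dataclass(frozen=True)
class GroupGains:
    """Per-group expected gains of one condition, ordered by increasing advantage."""

    gains: tuple[float, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.gains) == 0:
            raise ValueError("need at least one group")
        if self.weights is not None and len(self.weights) != len(self.gains):
            raise ValueError("weights and gains must have equal length")

    @property
    def n_groups(self) -> int:
        return len(self.gains)

    def weight_array(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_groups, 1.0 / self.n_groups)
        return np.asarray(self.weights, dtype=float)

    def total(self) -> float:
        """Population-weighted total expected gain Σ_g w_g Ŷ_{t,g}."""
        return float(self.weight_array() @ np.asarray(self.gains, dtype=float))


@dataclass(frozen=True)
class ExclusionDecision:
    excluded: bool
    total_gain: float
    reason: str | None = None


def apply_exclusion(gains: GroupGains, tolerance: float = 0.0) -> ExclusionDecision:
    """Rule out conditions with zero-or-negative cumulative expected gains.

    Excluded iff Σ_g w_g Ŷ_{t,g} ≤ ``tolerance``.  The default 0 is the
    literal rule; a small positive tolerance excludes conditions whose
    estimated total gain is only approximately zero (noise-level estimates).
    """
    rank_boundaries(gains.weight_array())  # validates the weights
    total = gains.total()
    if total <= tolerance:
        return ExclusionDecision(
            True, total, f"total expected gain {total:.6g} <= {tolerance:.6g}"
        )
    return ExclusionDecision(False, total)


@dataclass(frozen=True)
class ConcentrationCurve:
    """Piecewise-linear concentration curve: points (R_g, h(R_g)), g = 0..G."""

    ranks: tuple[float, ...]
    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(self.heights) or len(self.ranks) < 2:
            raise ValueError("curve needs matching ranks/heights with >= 2 points")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.ranks), np.asarray(self.heights)


def concentration_curve(gains: GroupGains) -> ConcentrationCurve:
    """Cumulative-gain-share curve of one (non-excluded) condition.

    h(R_g) is the share of total population-weighted expected gains accruing
    to groups 1..g; h(0) = 0 and h(1) = 1 by construction.  With equal group
    weights the shares reduce to plain cumulative sums of Ŷ_{t,g}.  The
    curve need not be monotone when some group gains are negative.
    """
    w = gains.weight_array()
    r = rank_boundaries(w)
    weighted = w * np.asarray(gains.gains, dtype=float)
    total = weighted.sum()
    if total == 0.0:
        raise ValueError(
            "total expected gain is zero; exclude the condition before "
            "computing its concentration curve"
        )
    h = np.concatenate([[0.0], np.cumsum(weighted) / total])
    h[-1] = 1.0
    return ConcentrationCurve(tuple(r), tuple(h))


def concentration_index(curve: ConcentrationCurve) -> float:
    """Health-gain concentration index H_t.

    Twice the signed area between the 45° line and the piecewise-linear
    curve, accumulated trapezoid by trapezoid:

        H_t = Σ_g (R_g − R_{g−1}) · ((R_{g−1} − h(R_{g−1})) + (R_g − h(R_g)))

    Positive when gains concentrate among high-advantage groups; zero when
    gains are distributed proportionally to population shares.
    """
    r, h = curve.as_arrays()
    d = r - h
    return float(np.sum(np.diff(r) * (d[:-1] + d[1:])))


def equitability(index: float) -> float:
    """Equitability Q_t = −H_t: higher values are equity-enhancing."""
    return 0.0 - index  # 0.0 - x rather than -x keeps zero signless


@dataclass(frozen=True)
class EquityResult:
    """Equity summary of one condition."""

    condition: str
    total_gain: float
    excluded: bool
    reason: str | None = None
    curve: ConcentrationCurve | None = None
    index: float | None = None  # H_t
    equitability: float | None = None  # Q_t


def evaluate_equity(
    gain_table: pd.DataFrame,
    weights: Sequence[float] | None = None,
    tolerance: float = 0.0,
) -> dict[str, EquityResult]:
    """Equity metrics for every condition in a condition × group gain table.

    ``gain_table`` rows are conditions, columns advantage groups ordered by
    increasing advantage (as produced by
    :func:`daive.outcomes.group_gain_table`).  ``weights`` are population
    shares per group (equal by default).  Conditions failing the exclusion
    rule carry no curve, H, or Q.
    """
    results: dict[str, EquityResult] = {}
    w = tuple(weights) if weights is not None else None
    for condition, row in gain_table.iterrows():
        gains = GroupGains(tuple(float(v) for v in row.to_numpy()), w)
        decision = apply_exclusion(gains, tolerance)
        if decision.excluded:
            results[str(condition)] = EquityResult(
                str(condition), decision.total_gain, True, decision.reason
            )
            continue
        curve = concentration_curve(gains)
        h = concentration_index(curve)
        results[str(condition)] = EquityResult(
            str(condition), decision.total_gain, False, None, curve, h, equitability(h)
        )
    return results


def equity_frame(results: Mapping[str, EquityResult]) -> pd.DataFrame:
    """Flat export table: condition, total gain, excluded flag, H, Q."""
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "total_gain": r.total_gain,
                "excluded": r.excluded,
                "H": r.index,
                "Q": r.equitability,
            }
            for r in results.values()
        ]
    ).set_index("condition")
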