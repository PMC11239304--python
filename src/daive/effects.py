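"""True effect models: expected outcome gain as a function of advantage.

The generator's ground truth is an :class:`EffectModel`: each component
contributes a gain function of the continuous systemic-advantage score
S ∈ [0, 1], and selected component sets contribute an extra interaction gain
when all their members are On.  The expected gain of a condition at advantage
S is the baseline plus the sum of its On components' gains plus the active
interaction gains — so components without a listed interaction combine purely
additively.

Declarative gain forms (``LinearGain``, ``constant``) keep configurations
serializable; arbitrary callables S -> gain are accepted programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import quad

from .design import InterventionCode

__all__ = [
    "GainFunction",
    "LinearGain",
    "constant",
    "EffectModel",
    "true_gain",
    "true_mean_gain",
    "true_group_gains",
]

GainFunction = Callable[[np.ndarray | float], np.ndarray | float]


@dataclass(frozen=True)
class LinearGain:
    """Gain linear in advantage: ``intercept + slope * S``."""

    intercept: float
    slope: float = 0.0

    def __call__(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(s, dtype=float)


def constant(value: float) -> LinearGain:
    """A gain function that ignores advantage."""
    return LinearGain(float(value), 0.0)


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth expected gains for every condition.

    Parameters
    ----------
    main
        Mapping from component name to its gain function of S.  Components
        absent from the mapping contribute zero gain.
    interactions
        Mapping from a frozenset of component names to an extra gain function
        applied when *all* members are On.
    baseline
        Expected gain of the all-Off condition (default 0: outcomes are
        gains relative to the minimal intervention).
    """

    main: Mapping[str, GainFunction]
    interactions: Mapping[frozenset[str], GainFunction] = field(default_factory=dict)
    baseline: float = 0.0

    def true_gain(self, code: InterventionCode, s: np.ndarray | float):
        return true_gain(code, s, self)


def _check_domain(s: np.ndarray) -> None:
    if np.any(s < 0.0) or np.any(s > 1.0) or not np.all(np.isfinite(s)):
        raise ValueError("advantage score S must lie in [0, 1]")


def true_gain(
    code: InterventionCode, s: np.ndarray | float, effects: EffectModel
) -> np.ndarray | float:
    """Expected outcome gain of ``code`` at advantage score(s) ``s``.

    baseline + Σ main gains of On components + Σ interaction gains whose
    members are all On.  Raises ``ValueError`` when S falls outside [0, 1].
    """
    arr = np.asarray(s, dtype=float)
    _check_domain(arr)
    total = np.full(arr.shape, float(effects.baseline))
    for name in code.on_set:
        fn = effects.main.get(name)
        if fn is not None:
            total = total + np.asarray(fn(arr), dtype=float)
    for members, fn in effects.interactions.items():
        if frozenset(members) <= code.on_set:
            total = total + np.asarray(fn(arr), dtype=float)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(total)
    return total


def true_mean_gain(
    code: InterventionCode,
    effects: EffectModel,
    lo: float = 0.0,
    hi: float = 1.0,
) -> float:
    """Population-average expected gain over S ~ Uniform(lo, hi).

    With the default bounds this is the full-sample estimand
    ∫₀¹ μ_t(S) dS; with stratum bounds it is a group estimand.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"invalid advantage stratum [{lo}, {hi}]")
    value, _ = quad(lambda x: float(true_gain(code, x, effects)), lo, hi)
    return value / (hi - lo)


def true_group_gains(
    code: InterventionCode, effects: EffectModel, n_groups: int
) -> np.ndarray:
    """Stratum-averaged expected gains over the G equal-width advantage strata.

    Group g (1-based, increasing in advantage) covers S in
    ((g-1)/G, g/G]; the returned array is ordered by increasing advantage.
    These are the estimands the per-group outcome models target.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    edges = np.linspace(0.0, 1.0, n_groups + 1)
    return np.array(
        [true_mean_gain(code, effects, edges[g], edges[g + 1]) for g in range(n_groups)]
    )
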