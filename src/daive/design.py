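"""Two-level (2^k) factorial intervention designs.

A design holds an ordered list of candidate intervention components, each a
two-level factor (On/Off) with a delivery cost per level.  A *condition* (one
of the 2^k alternative interventions) is identified by the subset of
components set to On; the all-Off condition is the minimal intervention,
labelled ``Min``.  Condition costs are additive: the cost of delivering an
alternative intervention is the sum of the On-level costs of its components
(plus any Off-level costs, which default to zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "MIN_LABEL",
    "DesignError",
    "ComponentSpec",
    "InterventionCode",
    "FactorialDesign",
    "enumerate_conditions",
    "intervention_cost",
    "parse_label",
]

#: Reserved label for the all-Off (minimal intervention) condition.
MIN_LABEL = "Min"


class DesignError(ValueError):
    """Raised for invalid designs, codes, or condition labels."""


@dataclass(frozen=True)
class ComponentSpec:
    """One candidate intervention component (a two-level factor).

    Parameters
    ----------
    name
        Short case-sensitive label, e.g. ``"A"``.  Must be non-empty, must
        not contain whitespace, and must not equal the reserved ``"Min"``.
    cost_on
        Delivery cost (money units) when the component is set On; must be
        non-negative.
    cost_off
        Delivery cost when set Off.  Defaults to 0 (Off is costless).
    """

    name: str
    cost_on: float
    cost_off: float = 0.0

    def __post_init__(self) -> None:
        if not self.name or any(ch.isspace() for ch in self.name):
            raise DesignError(f"invalid component name: {self.name!r}")
        if self.name == MIN_LABEL:
            raise DesignError(f"component name {MIN_LABEL!r} is reserved")
        if self.cost_on < 0:
            raise DesignError(f"cost_on must be >= 0, got {self.cost_on}")


@dataclass(frozen=True)
class InterventionCode:
    """One of the 2^k conditions: the set of components switched On.

    ``label`` is the concatenation of the On component names in design order,
    or ``"Min"`` when no component is On.  Codes are constructed through
    :meth:`FactorialDesign.code` or :meth:`FactorialDesign.parse_label` so the
    label is always canonical.
    """

    on_set: frozenset[str]
    label: str

    @property
    def n_components(self) -> int:
        return len(self.on_set)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class FactorialDesign:
    """A 2^k factorial optimization-trial design.

    Parameters
    ----------
    components
        Ordered sequence of :class:`ComponentSpec`; names must be unique.
        The order fixes condition enumeration (first component = lowest bit)
        and label canonicalization.
    """

    def __init__(self, components: Sequence[ComponentSpec]):
        components = list(components)
        if not components:
            raise DesignError("a design needs at least one component (k >= 1)")
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate component names in design: {names}")
        self.components: list[ComponentSpec] = components
        self._by_name = {c.name: c for c in components}

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def __iter__(self) -> Iterator[ComponentSpec]:
        return iter(self.components)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FactorialDesign({self.component_names})"

    def code(self, on_names: Iterable[str]) -> InterventionCode:
        """Build the canonical :class:`InterventionCode` for a set of On names."""
        on = set(on_names)
        unknown = on - set(self.component_names)
        if unknown:
            raise DesignError(f"unknown component(s): {sorted(unknown)}")
        ordered = [n for n in self.component_names if n in on]
        return InterventionCode(frozenset(ordered), "".join(ordered) or MIN_LABEL)

    def parse_label(self, text: str) -> InterventionCode:
        """Parse a condition label back into a code.

        Order-insensitive: ``"CBA"`` parses to the canonical ``"ABC"``.
        Multi-character component names are matched greedily, longest first.
        """
        if text == MIN_LABEL:
            return self.code([])
        by_length = sorted(self.component_names, key=len, reverse=True)
        rest = text
        seen: set[str] = set()
        while rest:
            for name in by_length:
                if rest.startswith(name) and name not in seen:
                    seen.add(name)
                    rest = rest[len(name):]
                    break
            else:
                raise DesignError(
                    f"cannot parse condition label {text!r} (stuck at {rest!r})"
                )
        return self.code(seen)

    def conditions(self) -> list[InterventionCode]:
        """All 2^k conditions; see :func:`enumerate_conditions`."""
        return enumerate_conditions(self)

    def cost(self, code: InterventionCode) -> float:
        """Cost of a condition; see :func:`intervention_cost`."""
        return intervention_cost(code, self)


def enumerate_conditions(design: FactorialDesign) -> list[InterventionCode]:
    """Enumerate all 2^k conditions in deterministic binary-counting order.

    The first listed component is the lowest bit, so the sequence starts with
    ``Min`` (all Off) and ends with the all-On condition.
    """
    names = design.component_names
    return [
        design.code([name for bit, name in enumerate(names) if (i >> bit) & 1])
        for i in range(2 ** design.k)
    ]


def intervention_cost(code: InterventionCode, design: FactorialDesign) -> float:
    """Additive delivery cost of one condition.

    Sum of ``cost_on`` over On components plus ``cost_off`` over Off
    components (the latter zero by default).
    """
    unknown = code.on_set - set(design.component_names)
    if unknown:
        raise DesignError(f"code references unknown component(s): {sorted(unknown)}")
    return sum(
        c.cost_on if c.name in code.on_set else c.cost_off for c in design.components
    )


def parse_label(text: str, design: FactorialDesign) -> InterventionCode:
    """Module-level convenience wrapper for :meth:`FactorialDesign.parse_label`."""
    return design.parse_label(text)
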