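"""Simulate individual-level data from a factorial optimization trial (ORCT).

The generator emulates a 2^k factorial trial stratified by a continuous
systemic-advantage score S on [0, 1]: participants are grouped into G
equal-probability advantage strata (quintiles when G=5), ``per_cell_n``
individuals in each (group, condition) cell, and each outcome is drawn from a
normal distribution centred on the condition's true expected gain at that
individual's advantage score.

Balance is exact by construction: within each stratum, S is drawn uniformly
from that stratum's interval ((g-1)/G, g/G), which is the conditional law of
S ~ Uniform(0, 1) given its population quantile group.  Each (condition,
group) cell gets its own random substream derived from the root seed, so
changing one cell's size never perturbs another cell's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorialDesign, MIN_LABEL
from .effects import EffectModel, true_gain

__all__ = [
    "SchemaError",
    "SimulationConfig",
    "ORCTDataset",
    "assign_groups",
    "simulate",
]

#: Non-factor columns of the individual-level dataset, in order.
ID_COLUMN = "subject_id"
S_COLUMN = "S"
GROUP_COLUMN = "group"
OUTCOME_COLUMN = "outcome"


class SchemaError(ValueError):
    """Raised when a dataset violates the individual-level record schema."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one simulated trial.

    Defaults are the reference trial conditions: quintile advantage groups
    (G=5), 10 individuals per group per condition, and unit outcome noise.
    """

    design: FactorialDesign
    effects: EffectModel
    group_count: int = 5
    per_cell_n: int = 10
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.group_count < 2:
            raise ValueError("group_count must be >= 2")
        if self.per_cell_n < 1:
            raise ValueError("per_cell_n must be >= 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_records(self) -> int:
        return self.group_count * self.per_cell_n * 2 ** self.design.k


def _columns(design: FactorialDesign) -> list[str]:
    return [ID_COLUMN, S_COLUMN, GROUP_COLUMN, *design.component_names, OUTCOME_COLUMN]


def validate_records(data: pd.DataFrame, design: FactorialDesign) -> None:
    """Check the record schema; raise :class:`SchemaError` naming offenders."""
    expected = _columns(design)
    missing = [c for c in expected if c not in data.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    problems: list[str] = []
    for name in design.component_names:
        values = data[name]
        if not np.isin(values, (0, 1)).all():
            bad = sorted(set(values) - {0, 1})
            problems.append(f"factor column {name!r} has non-0/1 level(s): {bad}")
    s = data[S_COLUMN].to_numpy(dtype=float)
    if not (np.isfinite(s).all() and (s >= 0).all() and (s <= 1).all()):
        problems.append("column 'S' must lie in [0, 1]")
    groups = data[GROUP_COLUMN]
    if not ((groups == groups.astype(int)) & (groups >= 1)).all():
        problems.append("column 'group' must hold 1-based integer labels")
    if not np.isfinite(data[OUTCOME_COLUMN].to_numpy(dtype=float)).all():
        problems.append("column 'outcome' must be finite numeric")
    if problems:
        raise SchemaError("; ".join(problems))


@dataclass
class ORCTDataset:
    """Individual-level ORCT records plus the design they belong to.

    ``data`` columns: subject_id, S, group, one 0/1 column per component
    (Off/On), outcome.  Outcomes are gains relative to the minimal
    intervention's baseline.
    """

    design: FactorialDesign
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_records(self.data, self.design)
        self.data = self.data[_columns(self.design)].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_groups(self) -> int:
        return int(self.data[GROUP_COLUMN].max())

    @property
    def group_sizes(self) -> pd.Series:
        return self.data[GROUP_COLUMN].value_counts().sort_index()

    def condition_labels(self) -> pd.Series:
        """Per-record condition label derived from the factor columns."""
        names = self.design.component_names
        onoff = self.data[names].to_numpy(dtype=int)
        labels = [
            "".join(n for n, on in zip(names, row) if on) or MIN_LABEL for row in onoff
        ]
        return pd.Series(labels, index=self.data.index, name="condition")

    def to_csv(self, path) -> None:
        """Write records as CSV with full float precision (lossless reload)."""
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, design: FactorialDesign) -> "ORCTDataset":
        data = pd.read_csv(path, float_precision="round_trip")
        validate_records(data, design)
        data[GROUP_COLUMN] = data[GROUP_COLUMN].astype(int)
        for name in design.component_names:
            data[name] = data[name].astype(int)
        return cls(design, data)


def assign_groups(s, n_groups: int) -> np.ndarray:
    """Assign 1-based advantage-group labels by sample quantiles.

    Labels are monotone nondecreasing in the rank of ``s`` with equal group
    sizes up to ±1 (earlier groups take the remainder, matching the usual
    empirical-quantile convention).  Used for loaded datasets; simulated data
    is grouped by population quantile boundaries at generation time.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("s must be a non-empty 1-d array")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if np.unique(s).size < n_groups:
        raise ValueError(
            f"cannot form {n_groups} groups from {np.unique(s).size} distinct value(s)"
        )
    order = np.argsort(s, kind="stable")
    base, extra = divmod(s.size, n_groups)
    labels = np.empty(s.size, dtype=int)
    start = 0
    for g in range(1, n_groups + 1):
        size = base + (1 if g <= extra else 0)
        labels[order[start : start + size]] = g
        start += size
    return labels


def simulate(config: SimulationConfig, seed: int) -> ORCTDataset:
    """Draw one complete trial dataset.

    For each of the 2^k conditions and each of the G advantage strata,
    ``per_cell_n`` individuals get S ~ Uniform over the stratum interval and
    outcome Y = μ_t(S) + Normal(0, noise_sd).  Bit-identical for a fixed
    seed; cell substreams are independent across (condition, group).
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    design, effects = config.design, config.effects
    g_count, n = config.group_count, config.per_cell_n
    edges = np.linspace(0.0, 1.0, g_count + 1)
    frames: list[pd.DataFrame] = []
    for ci, code in enumerate(design.conditions()):
        onoff = {
            name: int(name in code.on_set) for name in design.component_names
        }
        for g in range(1, g_count + 1):
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), ci, g)))
            s = rng.uniform(edges[g - 1], edges[g], size=n)
            y = np.asarray(true_gain(code, s, effects)) + rng.normal(
                0.0, config.noise_sd, size=n
            )
            cell = pd.DataFrame({S_COLUMN: s, GROUP_COLUMN: g, **onoff,
                                 OUTCOME_COLUMN: y})
            frames.append(cell)
    data = pd.concat(frames, ignore_index=True)
    data.insert(0, ID_COLUMN, np.arange(1, len(data) + 1))
    return ORCTDataset(design, data)
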