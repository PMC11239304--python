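"""Run configuration: declarative YAML/JSON description of a full analysis.

A run config pins down everything a reproducible decision analysis needs:
the factorial design with component costs, the true effect functions (for
simulation), either simulation settings or a path to an existing dataset,
the outcome model, the equity settings, and the willingness-to-pay values or
strategy.  See ``examples/case_study.yaml`` for the bundled reference config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .design import ComponentSpec, FactorialDesign
from .effects import EffectModel, GainFunction, LinearGain
from .outcomes import ModelSpec
from .simulate import SimulationConfig

__all__ = [
    "ConfigError",
    "EquitySettings",
    "ValuationSettings",
    "RunConfig",
    "load_config",
    "parse_config",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configurations."""


@dataclass(frozen=True)
class EquitySettings:
    """Equity-stage settings: group weights (None = equal) and exclusion tolerance."""

    weights: tuple[float, ...] | None = None
    exclusion_tolerance: float = 0.0


@dataclass(frozen=True)
class ValuationSettings:
    """Valuation-stage settings: an explicit λ list, or the bracketing strategy."""

    wtp: tuple[float, ...] | None = None
    strategy: str = "bracketing"

    def __post_init__(self) -> None:
        if self.wtp is None and self.strategy != "bracketing":
            raise ConfigError(f"unknown willingness-to-pay strategy {self.strategy!r}")


@dataclass
class RunConfig:
    """Everything needed for one end-to-end, seeded decision-analysis run."""

    design: FactorialDesign
    effects: EffectModel
    simulation: SimulationConfig | None = None
    dataset_path: Path | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    equity: EquitySettings = field(default_factory=EquitySettings)
    valuation: ValuationSettings = field(default_factory=ValuationSettings)
    seed: int = 0
    output_dir: Path | None = None
    raw: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.dataset_path is None):
            raise ConfigError(
                "exactly one of simulation settings or a dataset path is required"
            )

    def config_hash(self) -> str:
        """Stable hash of the declarative form (for report provenance)."""
        payload = self.raw if self.raw is not None else {"seed": self.seed}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _gain_function(spec: Mapping[str, Any], where: str) -> GainFunction:
    form = spec.get("form")
    if form == "linear":
        return LinearGain(float(spec.get("intercept", 0.0)), float(spec.get("slope", 0.0)))
    if form == "constant":
        return LinearGain(float(spec.get("value", 0.0)), 0.0)
    raise ConfigError(f"{where}: unknown gain form {form!r} (use 'linear' or 'constant')")


def _parse_design(block: Any) -> FactorialDesign:
    if not isinstance(block, Mapping) or "components" not in block:
        raise ConfigError("config needs a 'design' block with a 'components' list")
    comps = []
    for item in block["components"]:
        try:
            comps.append(
                ComponentSpec(
                    str(item["name"]),
                    float(item["cost_on"]),
                    float(item.get("cost_off", 0.0)),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"design component missing field: {exc}") from exc
    return FactorialDesign(comps)


def _parse_effects(block: Any, design: FactorialDesign) -> EffectModel:
    block = block or {}
    main: dict[str, GainFunction] = {}
    for name, spec in (block.get("components") or {}).items():
        if name not in design.component_names:
            raise ConfigError(f"effects reference unknown component {name!r}")
        main[name] = _gain_function(spec, f"effects.components.{name}")
    interactions: dict[frozenset[str], GainFunction] = {}
    for item in block.get("interactions") or []:
        members = frozenset(item.get("components", ()))
        unknown = members - set(design.component_names)
        if unknown or len(members) < 2:
            raise ConfigError(f"bad interaction members: {sorted(members)}")
        interactions[members] = _gain_function(item, f"effects.interactions.{sorted(members)}")
    return EffectModel(
        main=main,
        interactions=interactions,
        baseline=float(block.get("baseline", 0.0)),
    )


def parse_config(raw: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    base = base_dir or Path.cwd()
    design = _parse_design(raw.get("design"))
    effects = _parse_effects(raw.get("effects"), design)

    simulation = None
    dataset_path = None
    if "simulation" in raw and "dataset" in raw:
        raise ConfigError("give either 'simulation' or 'dataset', not both")
    if "simulation" in raw:
        sim = raw["simulation"] or {}
        simulation = SimulationConfig(
            design=design,
            effects=effects,
            group_count=int(sim.get("group_count", 5)),
            per_cell_n=int(sim.get("per_cell_n", 10)),
            noise_sd=float(sim.get("noise_sd", 1.0)),
        )
    elif "dataset" in raw:
        dataset_path = base / str(raw["dataset"])
    else:
        raise ConfigError("config needs a 'simulation' block or a 'dataset' path")

    model_block = raw.get("model") or {}
    model = ModelSpec(
        interaction_order=int(model_block.get("interaction_order", 2)),
        coding=model_block.get("coding", "effect"),
        backend=model_block.get("backend", "closed_form"),
        draws=int(model_block.get("draws", 4000)),
        seed=int(model_block.get("seed", 0)),
    )

    eq = raw.get("equity") or {}
    weights = eq.get("weights")
    equity = EquitySettings(
        weights=tuple(float(w) for w in weights) if weights is not None else None,
        exclusion_tolerance=float(eq.get("exclusion_tolerance", 0.0)),
    )

    val = raw.get("valuation") or {}
    wtp = val.get("wtp")
    valuation = ValuationSettings(
        wtp=tuple(float(v) for v in wtp) if wtp is not None else None,
        strategy=val.get("strategy", "bracketing"),
    )

    output_dir = raw.get("output_dir")
    return RunConfig(
        design=design,
        effects=effects,
        simulation=simulation,
        dataset_path=dataset_path,
        model=model,
        equity=equity,
        valuation=valuation,
        seed=int(raw.get("seed", 0)),
        output_dir=base / str(output_dir) if output_dir else None,
        raw=dict(raw),
    )


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration from disk."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)  # YAML is a JSON superset, so .json loads too
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config root must be a mapping")
    return parse_config(raw, base_dir=path.parent)
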