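"""End-to-end pipeline: simulate/load → fit → equity → frontiers → report.

``run`` executes the full decision analysis described by a
:class:`~daive.config.RunConfig` and returns a :class:`DecisionReport`
aggregating, per condition: cost, full-sample and per-group expected gains,
the exclusion flag, concentration index H and equitability Q; plus the value
efficiency frontier with ICERs and, for each willingness-to-pay λ, the net
health equity frontier with quadrant labels.  Reports regenerate
byte-identically from the same config and seed; all floats are serialized at
12 significant digits.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .design import FactorialDesign
from .equity import EquityResult, equity_frame, evaluate_equity
from .frontiers import (
    CostOutcomePoint,
    NetHealthPoint,
    net_health_equity_frontier,
    net_health_value,
    quadrant,
    representative_wtp,
    value_efficiency_frontier,
)
from .outcomes import fit_by_group, fit_expected_outcomes, group_gain_table
from .simulate import GROUP_COLUMN, ORCTDataset, simulate

__all__ = ["PipelineError", "DecisionReport", "run", "read_dataset", "write_dataset"]

logger = logging.getLogger("daive")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_dataset(path, design: FactorialDesign) -> ORCTDataset:
    """Load an individual-level CSV dataset (schema-checked)."""
    return ORCTDataset.from_csv(path, design)


def write_dataset(dataset: ORCTDataset, path) -> None:
    """Write a dataset as CSV; :func:`read_dataset` inverts it losslessly."""
    dataset.to_csv(path)


def _sig12(value):
    """Round floats to 12 significant digits, recursively, for stable diffs."""
    if isinstance(value, float):
        return float(f"{value:.12g}")
    if isinstance(value, dict):
        return {k: _sig12(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_sig12(v) for v in value]
    return value


@dataclass
class DecisionReport:
    """Aggregated results of one run; serializable to JSON."""

    metadata: dict
    conditions: list[dict]
    value_frontier: dict
    wtp: list[float]
    equity_frontiers: list[dict]
    narrative: list[str]
    equity_results: dict[str, EquityResult] = field(repr=False, default_factory=dict)

    def as_dict(self) -> dict:
        return _sig12(
            {
                "metadata": self.metadata,
                "conditions": self.conditions,
                "value_efficiency_frontier": self.value_frontier,
                "willingness_to_pay": list(self.wtp),
                "net_health_equity_frontiers": self.equity_frontiers,
                "narrative": self.narrative,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.as_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def condition_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.conditions).set_index("condition")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(name, exc) from exc
        logger.info("stage %s finished in %.3fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run(config: RunConfig) -> DecisionReport:
    """Execute the full decision analysis and (optionally) write artifacts.

    Stages: data (simulate or load), fit (full-sample and per-group outcome
    models), equity (exclusion rule, H, Q), valuation (value efficiency
    frontier, ICERs, λ set, per-λ net health equity frontiers), report.
    When ``config.output_dir`` is set, the dataset (if simulated), fit
    summaries, equity table, and report JSON are written there.
    """
    design = config.design
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- data -----------------------------------------------------------
    if config.simulation is not None:
        dataset = _stage("data")(simulate, config.simulation, config.seed)
        simulated = True
    else:
        dataset = _stage("data")(read_dataset, config.dataset_path, design)
        simulated = False

    # --- fit ------------------------------------------------------------
    full_fit = _stage("fit")(fit_expected_outcomes, dataset, config.model, "full")
    group_fits = _stage("fit")(fit_by_group, dataset, config.model)
    gains_by_group = group_gain_table(group_fits)

    # --- equity ---------------------------------------------------------
    if config.equity.weights is not None:
        weights = config.equity.weights
    elif simulated:
        weights = None  # equal by construction
    else:
        sizes = dataset.data[GROUP_COLUMN].value_counts().sort_index()
        weights = tuple(float(s) / dataset.n for s in sizes)
    equity_results = _stage("equity")(
        evaluate_equity, gains_by_group, weights, config.equity.exclusion_tolerance
    )

    # --- valuation ------------------------------------------------------
    costs = {code.label: design.cost(code) for code in design.conditions()}
    n_comp = {code.label: code.n_components for code in design.conditions()}
    points = [
        CostOutcomePoint(label, costs[label], float(full_fit.expected[label]),
                         n_comp[label])
        for label in full_fit.expected.index
    ]
    frontier = _stage("valuation")(value_efficiency_frontier, points)
    wtp = _stage("valuation")(
        representative_wtp,
        frontier.icers if config.valuation.wtp is None else None,
        config.valuation.wtp,
    )

    equity_frontiers = []
    narrative = []
    for lam in wtp:
        nh_points = [
            NetHealthPoint(
                r.condition,
                float(r.equitability),
                net_health_value(float(full_fit.expected[r.condition]),
                                 costs[r.condition], lam),
                n_comp[r.condition],
            )
            for r in equity_results.values()
            if not r.excluded
        ]
        nh_frontier = _stage("valuation")(net_health_equity_frontier, nh_points, lam)
        members = [
            {
                "condition": p.condition,
                "Q": p.equitability,
                "NHV": p.nhv,
                "quadrant": quadrant(p.equitability, p.nhv),
            }
            for p in nh_frontier.members
        ]
        equity_frontiers.append(
            {
                "wtp": lam,
                "members": members,
                "dominated": sorted(p.condition for p in nh_frontier.dominated),
            }
        )
        summary = ", ".join(f"{m['condition']} ({m['quadrant']})" for m in members)
        narrative.append(f"At willingness-to-pay {lam:g}: contenders {summary}.")

    # --- report ---------------------------------------------------------
    conditions = []
    for code in design.conditions():
        label = code.label
        r = equity_results[label]
        conditions.append(
            {
                "condition": label,
                "n_components": code.n_components,
                "cost": costs[label],
                "expected_gain": float(full_fit.expected[label]),
                "sd": float(full_fit.sd[label]),
                "group_gains": {
                    str(g): float(gains_by_group.loc[label, g])
                    for g in gains_by_group.columns
                },
                "total_gain": r.total_gain,
                "excluded": r.excluded,
                "H": r.index,
                "Q": r.equitability,
            }
        )
    metadata = {
        "package": "daive",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": dataset.n,
        "simulated": simulated,
    }
    report = DecisionReport(
        metadata=metadata,
        conditions=conditions,
        value_frontier={
            "members": list(frontier.labels),
            "icers": list(frontier.icers),
        },
        wtp=list(wtp),
        equity_frontiers=equity_frontiers,
        narrative=narrative,
        equity_results=equity_results,
    )

    if out_dir is not None:
        if simulated:
            write_dataset(dataset, out_dir / "dataset.csv")
        fits = {"full": full_fit.to_dict(),
                "groups": [s.to_dict() for s in group_fits.values()]}
        (out_dir / "fits.json").write_text(
            json.dumps(_sig12(fits), indent=2, sort_keys=True) + "\n"
        )
        equity_frame(equity_results).to_csv(out_dir / "equity.csv")
        report.to_json(out_dir / "report.json")
        logger.info("artifacts written to %s", out_dir)
    return report
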