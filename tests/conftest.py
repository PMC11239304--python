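"""Shared fixtures: the reference case-study design, effects, and datasets."""

from __future__ import annotations

import pandas as pd
import pytest

import daive
from daive.examples import (
    CASE_STUDY_WTP,
    case_study_design,
    case_study_effects,
    case_study_simulation,
)


@pytest.fixture(scope="session")
def design():
    return case_study_design()


@pytest.fixture(scope="session")
def effects():
    return case_study_effects()


@pytest.fixture(scope="session")
def wtp_set():
    return CASE_STUDY_WTP


@pytest.fixture(scope="session")
def trial_dataset(design, effects):
    """One simulated reference trial (N=800, unit noise), fixed seed."""
    return daive.simulate(case_study_simulation(), seed=0)


@pytest.fixture(scope="session")
def true_mean_gains(design, effects):
    """Analytic full-sample expected gains ∫₀¹ μ_t(S) dS per condition."""
    return {
        code.label: daive.true_mean_gain(code, effects)
        for code in design.conditions()
    }


@pytest.fixture(scope="session")
def true_group_gain_table(design, effects):
    """Analytic quintile-averaged gains, conditions × groups (increasing advantage)."""
    rows = {
        code.label: daive.true_group_gains(code, effects, 5)
        for code in design.conditions()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(1, 6))


@pytest.fixture(scope="session")
def condition_costs(design):
    return {code.label: design.cost(code) for code in design.conditions()}


def make_cost_outcome_points(gains, costs, design):
    return [
        daive.CostOutcomePoint(c.label, costs[c.label], gains[c.label], c.n_components)
        for c in design.conditions()
    ]


@pytest.fixture(scope="session")
def analytic_points(true_mean_gains, condition_costs, design):
    return make_cost_outcome_points(true_mean_gains, condition_costs, design)
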