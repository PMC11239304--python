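"""Bundled case study: optimizing an HIV medication-adherence intervention.

A hypothetical 2^4 factorial trial of four candidate components —
Motivational Interviewing (A), Peer Support (B), a Navigator (C), and
Skill-Building Sessions (D) — whose effects depend on a participant's
systemic advantage S:

* A helps everyone but the advantaged more: μ_A(S) = 0.5 + 0.5·S
* B scales directly with advantage: μ_B(S) = S
* C is inert on its own (μ_C = 0) but offsets B's shortfall for the less
  advantaged: when both B and C are On an extra (1 − S) accrues, so
  μ_BC(S) = 1 at every S
* D targets the disadvantaged: μ_D(S) = 1 − S

Delivery costs are $100 / $125 / $200 / $250 for A–D, additive across On
components.  The trial stratifies S ~ Uniform(0, 1) into quintiles with 10
participants per quintile per condition (N = 800) and unit-variance normal
outcome noise.  The reference willingness-to-pay set is
{$170, $330, $580, $830}.
"""

from __future__ import annotations

from .design import ComponentSpec, FactorialDesign
from .effects import EffectModel, LinearGain, constant
from .simulate import SimulationConfig

__all__ = [
    "CASE_STUDY_WTP",
    "CASE_STUDY_EXCLUSION_TOLERANCE",
    "case_study_design",
    "case_study_effects",
    "case_study_simulation",
]

#: Reference willingness-to-pay thresholds (money per unit adherence gain).
CASE_STUDY_WTP: tuple[float, ...] = (170.0, 330.0, 580.0, 830.0)

#: Exclusion tolerance used when reproducing the case-study decision analysis
#: from noisy estimates: roughly two posterior SDs of a condition-mean
#: estimate at the trial's sample size, so conditions whose estimated total
#: gain is statistically indistinguishable from zero are ruled out.
CASE_STUDY_EXCLUSION_TOLERANCE = 0.2


def case_study_design() -> FactorialDesign:
    """Four-component adherence-intervention design with additive costs."""
    return FactorialDesign(
        [
            ComponentSpec("A", 100.0),  # Motivational Interviewing
            ComponentSpec("B", 125.0),  # Peer Support
            ComponentSpec("C", 200.0),  # Navigator
            ComponentSpec("D", 250.0),  # Skill-Building Sessions
        ]
    )


def case_study_effects() -> EffectModel:
    """Advantage-dependent true effect functions of the case study."""
    return EffectModel(
        main={
            "A": LinearGain(0.5, 0.5),
            "B": LinearGain(0.0, 1.0),
            "C": constant(0.0),
            "D": LinearGain(1.0, -1.0),
        },
        interactions={frozenset({"B", "C"}): LinearGain(1.0, -1.0)},
        baseline=0.0,
    )


def case_study_simulation(
    per_cell_n: int = 10, noise_sd: float = 1.0
) -> SimulationConfig:
    """Simulation settings of the case-study trial (override cell size to scale)."""
    return SimulationConfig(
        design=case_study_design(),
        effects=case_study_effects(),
        group_count=5,
        per_cell_n=per_cell_n,
        noise_sd=noise_sd,
    )
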