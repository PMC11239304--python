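# Reference configuration: four-component HIV medication-adherence case study.
# 2^4 factorial trial, quintile advantage groups, 10 participants per cell
# (N = 800), unit outcome noise, additive delivery costs.
design:
  components:
    - {name: A, cost_on: 100}   # Motivational Interviewing
    - {name: B, cost_on: 125}   # Peer Support
    - {name: C, cost_on: 200}   # Navigator
    - {name: D, cost_on: 250}   # Skill-Building Sessions
effects:
  baseline: 0.0
  components:
    A: {form: linear, intercept: 0.5, slope: 0.5}
    B: {form: linear, intercept: 0.0, slope: 1.0}
    C: {form: constant, value: 0.0}
    D: {form: linear, intercept: 1.0, slope: -1.0}
  interactions:
    # Navigator offsets Peer Support's shortfall for the less advantaged
    - {components: [B, C], form: linear, intercept: 1.0, slope: -1.0}
simulation:
  group_count: 5
  per_cell_n: 10
  noise_sd: 1.0
model:
  interaction_order: 2
  coding: effect
  backend: closed_form
equity:
  # ~2 posterior SDs of a condition-mean estimate at this sample size:
  # rules out conditions whose estimated total gain is approximately zero.
  exclusion_tolerance: 0.2
valuation:
  wtp: [170, 330, 580, 830]
seed: 7
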