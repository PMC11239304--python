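# daive

Optimizing multi-component health interventions for **value** and **equity**.

Intervention scientists running a factorial optimization trial (an ORCT in
the multiphase optimization strategy, MOST) must pick one of 2^k candidate
interventions — one per combination of On/Off components — by balancing
overall effectiveness, cost, and, increasingly, *equitability*: whether the
intervention's benefits spread evenly or concentrate among participants who
are already advantaged.  `daive` implements a decision-analysis workflow
(decision analysis for intervention value efficiency, extended with an
equitability criterion) that turns trial data into an explicit set of
decision contenders:

1. **Simulate or load** individual-level trial data: advantage score
   S ∈ [0, 1], advantage group g (quintiles by default), factor levels, and
   a continuous outcome gain.
2. **Estimate** posterior expected outcome gains Ŷ_t per condition with a
   main-effects + two-way-interaction regression — full sample and
   separately within each advantage group.
3. **Score equitability**: per condition, a concentration curve of
   cumulative expected gains over advantage rank, the health-gain
   concentration index H_t (twice the signed area between the curve and the
   45° line), and equitability Q_t = −H_t.  Conditions with total expected
   gain ≤ τ are excluded.
4. **Build frontiers**: the value efficiency frontier (lower-right convex
   hull of cost C_t vs Ŷ_t, with incremental cost-effectiveness ratios
   Δcost/Δgain) and, at each willingness-to-pay λ, the net health equity
   frontier (upper-right hull of Q_t vs net health value
   NHV_t(λ) = λ·Ŷ_t − C_t) whose members are the contenders, tagged by
   quadrant.

See `docs/methods.md` for the model, defaults, and numerical conventions.

## Worked example

The bundled config `examples/case_study.yaml` describes a hypothetical 2^4
trial of an HIV medication-adherence intervention: Motivational Interviewing
(A, $100, works better for the advantaged), Peer Support (B, $125, likewise),
a Navigator (C, $200, inert alone but making B work for everyone), and
Skill-Building (D, $250, favoring the disadvantaged); quintile advantage
groups, 10 participants per cell (N = 800), unit outcome noise, and
λ ∈ {170, 330, 580, 830}.

```bash
daive run --config examples/case_study.yaml --seed 7 --outdir results/
```

prints

```text
At willingness-to-pay 170: contenders A (upper-left), D (lower-right), CD (lower-right).
At willingness-to-pay 330: contenders ABC (upper-left), D (lower-right), CD (lower-right).
At willingness-to-pay 580: contenders ABC (upper-left), ABCD (upper-right), CD (lower-right).
At willingness-to-pay 830: contenders ABCD (upper-right), CD (lower-right).
report written to results/report.json
```

and the report shows the value efficiency frontier
`Min → A → AB → ABC → ABCD` with ICERs
`138.14, 224.52, 292.70, 625.18` for this seed.  Reading the output: at low
willingness-to-pay the cheap, effective-but-inequitable A (positive NHV,
negative Q: upper-left) trades off against the equity-enhancing D and CD
(positive Q, negative NHV: lower-right); at high willingness-to-pay the
maximally effective ABCD becomes affordable and sits in the upper-right
(positive on both axes).  `Min` and the inert `C` are excluded — their
estimated total gains (−0.030 and −0.035 here) fall below the exclusion
tolerance.  D and CD have identical true effects (1 − S) and differ only in
cost, so noisy seeds may place either (or both) at the high-equity end of the
frontier; with analytic true gains the contenders at λ = 170 are exactly
A and D.

The same analysis is available as a library:

```python
import daive
from daive.examples import case_study_simulation

dataset = daive.simulate(case_study_simulation(), seed=7)
fit = daive.fit_expected_outcomes(dataset)          # full-sample Ŷ_t
gains = daive.group_gain_table(daive.fit_by_group(dataset))  # Ŷ_{t,g}
equity = daive.evaluate_equity(gains, tolerance=0.2)
print(equity["D"].equitability)                     # 0.361 for this seed
```

Other CLI subcommands: `simulate`, `fit`, `equity`, `frontier` (stage by
stage on a saved dataset) and `plot` (cost–outcome frontier, concentration
curves, equitability bars, and per-λ Q–NHV hull figures).

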