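# Methods

`daive` implements a posterior-expected-value decision analysis for choosing
an optimized intervention from a 2^k factorial optimization trial, balancing
three criteria: overall effectiveness, efficiency (cost per unit of outcome
gain), and equitability (how evenly outcome gains are distributed across
levels of systemic advantage).  This note records the model, the defaults,
the numerical choices, and the limits of what the bundled synthetic trial can
show.

## The decision problem

A trial crosses k candidate components (two-level factors, On/Off), giving
T = 2^k alternative interventions ("conditions") indexed by the set of On
components; the all-Off condition is the minimal intervention `Min`.
Delivery costs are additive: C_t is the sum of On-component costs.  Each
participant i carries a continuous systemic-advantage score S_i ∈ [0, 1]
(increasing in advantage) and is stratified into one of G equal-probability
advantage groups g (quintiles when G = 5).  The outcome Y_i is a continuous
gain relative to the `Min` baseline.

Three derived quantities drive the selection:

1. **Net health value.** At willingness-to-pay λ (money per unit outcome),
   NHV_t(λ) = λ·Ŷ_t − C_t, where Ŷ_t is the posterior expected outcome
   gain of condition t in the full sample.  NHV folds effectiveness and
   efficiency into one axis; its sign says whether the condition is worth
   its opportunity cost at that λ.

2. **Equitability.** From per-group expected gains Ŷ_{t,g} and population
   shares w_g, the concentration curve height at cumulative rank
   R_g = Σ_{j≤g} w_j is the cumulative share of expected gains,
   h_t(R_g) = Σ_{j≤g} w_j Ŷ_{t,j} / Σ_{j≤G} w_j Ŷ_{t,j}, with h(0) = 0 and
   h(1) = 1.  (With equal weights this is the plain cumulative-sum form;
   carrying the weights generalizes it to unequal group sizes in loaded
   data.)  The health-gain concentration index is twice the signed area
   between the 45° line and the curve,

       H_t = Σ_g (R_g − R_{g−1}) ((R_{g−1} − h(R_{g−1})) + (R_g − h(R_g))),

   which is exact for the piecewise-linear curve (it *is* the trapezoid
   rule).  Equitability is Q_t = −H_t: positive when gains favor the less
   advantaged.  Because group gains may be negative (iatrogenic effects),
   H is not confined to [−1, 1].  Conditions with total expected gain
   Σ_g w_g Ŷ_{t,g} ≤ τ are excluded before any curve is drawn; τ = 0 is the
   library default (the literal rule), while the bundled reproduction config
   uses τ = 0.2 ≈ two posterior SDs of a condition mean at the reference
   trial size, so conditions whose estimated gains are statistically
   indistinguishable from zero (here `Min` and the inert `C`) are ruled out
   rather than entering with noise-dominated, wildly unstable Q values.

3. **Two frontiers.**  The *value efficiency frontier* is the lower-right
   convex hull of (C_t, Ŷ_t) anchored at the least costly condition; the
   incremental cost-effectiveness ratios (ICERs = Δcost/Δgain) between
   consecutive members strictly increase, and interior points are dominated
   or extended-dominated.  The *net health equity frontier* at each λ is the
   upper-right convex hull of (Q_t, NHV_t(λ)), from the maximum-NHV member
   to the maximum-Q member; its members are the decision contenders, and
   each is tagged by quadrant (signs of Q and NHV).

Both hulls operate on posterior means; posterior SDs are carried through for
reporting but never alter membership (a point-estimate decision rule).
Tie-breaks are deterministic: at equal cost the higher gain wins; at exact
(cost, gain) or (Q, NHV) ties the condition with fewer On components, then
the lexicographically smaller label, wins; exactly collinear hull points are
excluded by default (`include_collinear=True` keeps them).  The greedy
minimum-ICER construction and the cross-product hull are each validated in
the test suite against independent brute-force dominance/segment
enumeration.

## Willingness-to-pay values

λ is context: it encodes the payer's opportunity cost.  Reproduction runs
take an explicit list (the bundled config uses {170, 330, 580, 830}).  When
no list is given, a *bracketing* strategy derives representative values from
the value efficiency frontier's ICERs — half the smallest ICER, midpoints of
consecutive ICERs, and 1.5× the largest — one λ per regime in which the
frontier-based decision would differ.  The factors 0.5 and 1.5 are
arbitrary-but-documented defaults; any principled elicitation can replace
them by passing explicit values.

## Outcome model

The working regression includes the intercept, all k main effects, and all
two-way interactions of the effect-coded (±1) factors; `interaction_order`
raises or lowers the order (k = saturated cell-means model, whose
predictions equal raw condition means).  Predictions Ŷ_t are invariant to
the coding convention for a fixed term set; effect coding is the default.
The default backend is the flat-prior conjugate posterior, whose mean equals
ordinary least squares (computed via statsmodels), with classical SEs of the
fitted cell mean as the uncertainty.  A `sampling` backend draws from the
flat-prior normal–inverse-gamma posterior (σ² scaled inverse-χ², then
β | σ² multivariate normal) and agrees with the closed form up to
Monte-Carlo error; it exists for workflows that want posterior draws rather
than moments.  Weakly-informative priors would shrink estimates slightly at
this sample size but do not change the estimand; they are out of scope.

Per-group gains Ŷ_{t,g} come from separate fits on each group's records
(160 at the reference trial size) — no partial pooling across groups, which
keeps the equity metric an honest reflection of subgroup evidence.

Rank deficiency (e.g. a term inestimable because cells are empty) raises an
error naming the offending term(s), found by column-elimination rank checks.

## Synthetic trial generator

The generator emulates a single-level, fixed-intervention factorial trial
with advantage-dependent true effects.  The bundled case study uses k = 4
components (A = Motivational Interviewing $100, B = Peer Support $125,
C = Navigator $200, D = Skill-Building $250) with gain functions
μ_A = 0.5 + 0.5S, μ_B = S, μ_C = 0, μ_D = 1 − S, and a single B×C
interaction adding (1 − S) so that μ_BC ≡ 1; all other combinations are
purely additive.  Defaults: G = 5 quintiles, 10 participants per
(group, condition) cell (N = 800), outcome noise SD 1, `Min` gain 0.

Two stated properties — S_i ~ Uniform(0, 1) with quintile grouping, and
exactly n participants per group per condition — are honored simultaneously
by stratified sampling: within group g, S is drawn uniformly from
((g−1)/G, g/G), the conditional law of a uniform score given its population
quantile group.  Group labels of simulated data use these population
boundaries; loaded datasets are grouped by sample quantiles
(`assign_groups`).  Randomness uses one root seed with a
`SeedSequence((seed, condition, group))` substream per cell, so resizing one
cell never perturbs another; identical seeds give bit-identical datasets.

What the generator does *not* emulate: covariates beyond S, measurement
error in S, missing data, non-normal or heteroscedastic outcomes,
clustering/multilevel structure, and informative sampling across advantage
strata.  Passing tests therefore demonstrate correctness of the decision
machinery under a clean, well-specified data-generating process — not
robustness of the equity conclusions to real-world sampling problems.

## Problem sizes used in the checks

The automated checks run the reference trial (N = 800) for single-dataset
properties, 50 replicate trials for frontier-membership stability, and one
large trial at 1000 participants per cell (N = 80,000) for parameter
recovery; these sizes make every Monte-Carlo tolerance interpretable against
the analytic standard errors noted below.

A structural feature of the case-study effect functions is worth knowing
when reading replicate results: conditions ABC and ABD share the identical
true gain function 1.5 + 0.5S, as do D and CD (1 − S).  Only cost separates
each pair, so at trial scale their *estimated* gains and equitabilities tie
essentially at random, and frontier membership can swap within a pair from
one seed to the next (e.g. CD claiming the maximum-Q endpoint from D).  The
analytic (true-gain) frontiers are unambiguous: value efficiency
{Min, A, AB, ABC, ABCD} with ICERs {133.33, 250, 400, 500}, and net health
equity contenders {A, D} at λ=170, {AB, ABC, D} at λ=330, and {ABCD, D} at
λ=580 and λ=830.

On per-group estimation precision: a group fit at 1000 per cell has
prediction SE σ·√(11/16000) ≈ 0.026 per condition, so the maximum absolute
error across all 80 condition×group estimates typically lands near 2.5 SE
≈ 0.065 even though each individual estimate is unbiased; recovery checks
are therefore phrased in terms of bias and RMSE at the theoretical level.

## Numerical conventions

* Analytic condition means ∫ μ_t(S) dS (full-sample and per-stratum) use
  adaptive quadrature (`scipy.integrate.quad`); for the bundled linear
  effects these equal stratum-midpoint values exactly.
* The concentration index needs no integration tolerance — the trapezoid
  form is exact for the piecewise-linear curve (verified to 1e−12 against a
  knot-refined numeric oracle in tests).
* ICER ties in hull construction are compared with absolute tolerance
  1e−12; quadrant boundaries use exact zero by default with a configurable
  tolerance for noisy estimates.
* Reports serialize all floats at 12 significant digits and regenerate
  byte-identically from the same config and seed; dataset CSVs are written
  at full precision and re-read with round-trip float parsing.

## Known limitations

Single outcome only (no multi-outcome value functions); fixed interventions
(no adaptive/sequential designs); single-level randomization; no inference
on H or Q (no CIs — the decision rule is point-estimate based, and sampling
uncertainty in Q is substantial at realistic per-group sample sizes, as the
replicate analyses above make concrete); exclusion is a hard threshold
rather than a probabilistic rule.
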