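# Methods

## Problem setting

Given a real table R and a synthetic table S sharing one schema, we audit
whether S represents every protected subgroup fairly. A schema declares
protected attributes (categorical, closed level sets), optional temporal
feature blocks (m features × T ordered columns), and the aggregation
statistic used for temporal collapsing. A subgroup is a conjunction of
single levels, g(x) = 1 iff the row matches every assigned level; its
complement g(x) = 0 is all remaining rows of the *same* table, never the
sibling level. The full lattice over attributes with L1..Ld levels has
∏(Li+1) − 1 subgroups; enumeration order is deterministic (order ascending,
then schema attribute order, then level order).

R and S are treated as independent samples — nothing assumes row alignment,
and unequal row counts are expected.

## Rate disparity

With p_S, p_R the subgroup's occurrence rates and odds(p) = p/(1−p),

    LD = ln( odds(p_S) / odds(p_R) ),

positive when the subgroup is over-represented in S. The sign convention is
fixed by the underlying equivalence: for a finite population with real- and
synthetic-sampling indicators y, y′ jointly independent of each other and of
g, the disparate impact ratio P(y′=1|g=1)/P(y′=1|g=0) equals
odds(p_S)/odds(p_R) exactly. `disparate_impact_oracle` verifies this by
brute-force frequency counting on product-form populations; the test suite
and acceptance script exercise it on 100+ seeded populations at agreement
1e−12, and the same identity gives binary attributes exactly antisymmetric
LDs (up to one float ulp — asserted at 1e−12).

Edge cases are deliberate choices:

- count_S = 0 with count_R ≥ 1 → the **missing** sentinel/category, the
  mode-collapse signal. It takes precedence over the continuity correction.
- count_R = 0 → a reference error: with no real-data baseline the subgroup
  is not evaluable (batch evaluation skips such subgroups rather than
  inventing a category).
- count = n on either side → degenerate (odds of 1 undefined).
- An optional Haldane–Anscombe +0.5 on all four implied 2×2 cells is
  offered behind a flag for sparse tables; it is off by default because the
  plain estimator is the quantity the equivalence above speaks about.

### Categorization

Six levels from two symmetric thresholds on the log scale, t1 = |ln 0.9| ≈
0.1054 (90% rule) and t2 = |ln 0.8| ≈ 0.2231 (80% rule): adequate below t1,
over/under in [t1, t2), highly over/under at ≥ t2, plus missing. Boundary
ties go to the *more severe* side (|LD| exactly t1 is already over/under):
when in doubt, flag. The same scale categorizes the time-series metric.

Report colors: only missing = red (#d7191c) carries fixed semantics; the
other five hexes are this package's documented choice of a diverging
teal/orange palette.

### Significance

Null hypothesis p_S = p_R per subgroup, tested with the pooled
two-proportion z-test

    z = (p_S − p_R) / sqrt( p(1−p)(1/n_S + 1/n_R) ),  p = (c_S + c_R)/(n_S + n_R),

two-sided (over- and under-representation are equally interesting). When
any expected cell of the 2×2 table under the pooled proportion falls below
5 (the textbook rule, configurable), Fisher's exact test replaces it; the
two agree within 0.01 on balanced tables at 10,000 rows per arm. Because a
run tests the entire subgroup family at once, Benjamini–Hochberg is applied
once per run and `significant` always means adjusted p < α (default 0.05).
Non-significant subgroups are *starred* in exports, never suppressed — the
category is still reported, the star marks how seriously to take it.
Under a global null (both tables drawn from one multinomial, 10,000
replicates of 2,000 rows per arm) the measured raw rejection rate is ≈0.05
and the BH any-false-discovery rate ≈0.05, as the acceptance script
recomputes.

## Time-series disparity

Per temporal feature, a subgroup's rows collapse to one length-T series via
the statistic f: mean and sum are arithmetic; count counts rows with a
nonzero value at each time point (the natural reading for binary diagnosis
indicators). Mean is the default — it is the right statistic for both
average-minutes data and binary prevalence panels. Resemblance between the
real and synthetic aggregated series is either

- **mapped PCC**, (r+1)/2 with r the Pearson correlation (population
  moments; the normalisation cancels), range [0,1]; undefined for constant
  series — reported as a named flag, not imputed, because any imputed value
  would invent information; or
- **directional symmetry**, the percentage of consecutive steps whose
  increments have non-negative product, range [0,100]; ties (a flat step on
  either side) count as agreement.

The time-series log disparity is ln(res_g1 / res_g0) against the
complement; common scale factors cancel, so DS on [0,100] and PCC on [0,1]
feed the same categorization thresholds. The expectation over a subgroup's
series is realised as: the single resemblance value when one aggregated
series exists, and the arithmetic mean over features in multivariate
per-feature summaries (per-feature values are the primary output; the mean
is a convenience summary). In concatenated mode features are joined in
schema order into one m·T series before scoring. A zero resemblance on
either side makes the ratio undefined; batch evaluation reports the worst
category on the side the zero implies (subgroup → highly under, complement
→ highly over) with a `zero_resemblance` flag.

PCC and DS probe different failure modes — location/scale-free linear
association vs micro-step concordance — and can legitimately disagree in
category on the same subgroup (a high-correlation zigzag scores DS ≈ 50);
both are reported for that reason. No significance machinery is attached to
the time-series metric.

## The fixture generator

Audits need ground truth; the generator plays the role of a (possibly
biased) synthetic-data generator with known parameters.

**Categorical bias.** The real table samples cells from a declared joint
over protected-attribute cells; the synthetic table samples from the same
joint after multiplying chosen subgroups' *odds* by ω and renormalising
(p′ = ωp/(1−p+ωp); cells inside the subgroup scale by p′/p, outside by
(1−p′)/(1−p), multipliers applied sequentially). Injecting on odds rather
than probabilities makes ω exactly the disparity ratio the rate metric
estimates, so parameter recovery is a sharp test: ω = 0.8 at 50,000 rows
per arm is recovered within ±0.02, and ω = 0 forces the missing category.

**Temporal structure.** Each protected cell gets a deterministic smooth
base curve (template families: a sinusoidal minutes-of-sleep curve, a
clipped prevalence curve in (0,1) for binary panels, a plain ramp for exact
tests). Real rows are the base curve plus iid Gaussian noise (or Bernoulli
draws around the prevalence curve). Synthetic rows rebuild the curve from
its increments, each sign-flipped independently with probability q,
optionally only for rows of one target subgroup. q = 0.5 destroys
directional information — the flipped subgroup's DS concentrates near 50
and its mapped PCC near 0.5 — while the complement stays faithful, so the
generator produces known-answer inputs for the time-series metric too.

One caveat that matters when interpreting tests: with noise and flips both
zero, single-cell (full-order) subgroups resemble *exactly*; marginal
subgroups aggregate a mixture of cell curves whose weights are
independently re-sampled in the two tables, so their resemblance is
near-perfect but not exact. This is a property of independent sampling, not
of the metric.

**Presets.** Three shapes mirror common audit scenarios: an ICU mortality
extract (race 5 × gender 2 × age 4 × mortality 2; 13 univariate subgroups,
269 in the full lattice), a time-use sleep survey (gender 2 × age 7, one
30-point series; gender marginals 0.4303/0.5697 match the published survey
proportions), and a pediatric claims panel (gender × race, seven binary
diagnosis series over ten half-year periods). Default sample sizes are
10,000 rows per arm. All sampling is driven by one seed split per table via
`SeedSequence.spawn`; output is byte-identical across runs.

What the generator does *not* emulate: correlations between protected
attributes beyond the declared joint, unprotected covariates, within-row
temporal autocorrelation of the noise, or any actual generative-model
artifacts beyond rate re-weighting, curve distortion and cell deletion.
Passing tests demonstrate metric correctness and recovery of injected bias
under these controlled conditions, not the behaviour of any particular
generator on real data.

## Problem sizes used in checks

The standing test suite and acceptance script use: 50,000 rows per arm for
odds-multiplier recovery; 10,000 replicates × 2,000 rows per arm (via the
multinomial sufficient-statistic fast path `null_level_counts`) for null
calibration; 120 seeded finite populations (≤10,000 subjects) for the
disparate-impact equivalence; and 200 seeded replicates of 300 rows per arm
for the direction-flip distortion study. The published sleep-survey gender
totals (13,135/17,391 real; 12,806/17,194 synthetic) are used as printed
inputs for the worked example: male log disparity −0.01397, disparity ratio
0.9861, category adequate.

## Known limitations

- Protected attributes must be categorical and pre-binned; no on-the-fly
  discretization, no missing values in protected or temporal cells.
- Subgroups are conjunctions of single levels — no level unions or
  negations, matching the table/sunburst reporting structure.
- The BH pass treats the family of subgroup tests as exchangeable; the
  tests are positively/negatively dependent through shared rows, for which
  BH is known to be robust in practice (and measured at nominal level
  here), but no formal dependence correction is attempted.
- Zero-variance aggregated series (possible for constant binary prevalence)
  make PCC undefined by design; use DS, whose tie rule handles flat
  segments, when panels can be constant.
- No significance testing for time-series disparity; choosing a test for
  dependent resemblance statistics is an open problem.
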