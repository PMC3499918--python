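# Methods

## The problem and the model

A single reading performance — *k* syllables read in *t* seconds — yields
two interchangeable-looking speed scores: sec/syll (x = t/k, higher =
worse) and syll/sec (y = k/t, lower = worse). They are exact reciprocals,
y = 1/x, a strictly decreasing hyperbola. z-scores, however, are computed
against the normative mean and SD *on one chosen scale*, and the
reciprocal transform does not commute with standardization.

Let the normative sec/syll scores be X ~ Normal(μ, σ) and write
r = μ/σ for the mean/SD ratio. A child at z_x SDs above the sec/syll
mean has raw score μ(1 + z_x/r); on the syll/sec scale their z-score is

    z_y = ( 1/(μ(1 + z_x/r)) − E[1/X] ) / SD[1/X].

Both E[1/X] and SD[1/X] scale as 1/μ, so z_y depends on r only — the
normative mean/SD ratio is the sole parameter of the z-to-z mapping.
The mapping is strictly decreasing and convex: it is approximately
−z_x near the center (gap ≈ z_x²/r), but compresses hard in the deficit
direction because y is bounded below by 0 while x is unbounded above.
The practical consequence quantified here: at r = 5 every sec/syll
z between +2 and ≈3.95 is *pathological* by the +2 SD criterion on the
time scale and *normal* by the −2 SD criterion on the rate scale.

## The conditioning floor (estimand definition)

The reciprocal of a normal variable has no finite unconditional mean:
the density is positive at the pole x = 0. Any Monte Carlo or analytic
statement about E[1/X] therefore needs a conditioning convention. Two
floors are used, and every simulated normative draw at or below the
applicable floor is redrawn (the count is recorded; a `reject_run`
policy aborts instead):

- a **hard positivity floor** ε = μ/1000, the absolute lower bound for
  any admissible score;
- a **normative conditioning floor** μ − 3.89σ for normative cohorts,
  3.89 being |Φ⁻¹(1/20000)|: the z below which a normative sample of
  the default size N = 20,000 expects fewer than one observation.

The larger of the two applies to normative cohorts; at r = 3 the
positivity floor binds (≈27 redraws per 20,000), at r ≥ 4 the z-floor
does. The z-floor is what makes "simulation equals analytic oracle" a
well-posed statement: without it, the conditional second moment of 1/X
at small r is dominated by a sliver of near-zero scores (mass ~10⁻⁵)
that a 20,000-draw sample essentially never contains, so the simulated
reciprocal SD would systematically undershoot any fixed ε-conditioned
analytic value while being wildly unstable replicate to replicate.
Conditioning at the edge of what a normative sample of this size can
realize matches what an empirical normative SD measures. Deterministic
patient placements and pre/post subjects are *not* subject to the
z-floor — only to positivity — since placing patients far below the
normative range (z = −4) is the point of those scenarios.

## Monte Carlo estimates

`reciprocal_stats_mc` draws N = 20,000 scores per replicate and 10
replicates by default, each replicate on its own deterministic child
stream spawned from the root seed and keyed by the mean/SD ratio — so
any table cell is independently reproducible, and configurations that
share a ratio reuse identical standard-normal draws (making the
unit-invariance of the mapping exact to machine precision, not just
statistical). Reported values are replicate means ± standard errors.
A single-replicate mode reproduces the character of the original
single-run study.

`crossing_point` solves g(z) = −cutoff for the frozen per-replicate
reciprocal statistics by Brent's method (xtol 1e−6) on the bracket
[0, 10⁶·r]; the statistics are estimated once per replicate and never
re-simulated inside the solver, keeping the solved function monotone
and the root unique. The solver fails loudly, naming the plateau, when
the cut-off is unattainable (at r = 3 the mapped z bottoms out above
−2, so no crossing exists).

## Analytic oracle

`conditional_reciprocal_moments` integrates x⁻¹ and x⁻² against the
renormalized Normal(μ, σ) density between the conditioning floor and
μ + 10σ (mass beyond is < 10⁻²³ of the total) by adaptive quadrature
with relative tolerance 10⁻¹⁰, raising if the integrator's error
estimate exceeds it. The delta-method series

    E[1/X]  ≈ (1/μ)(1 + v + 3v² + 15v³ + 105v⁴),
    E[1/X²] ≈ (1/μ²)(1 + 3v + 15v² + 105v³ + 945v⁴),   v = (σ/μ)²,

is a second, independent cross-check; it is asymptotic (coefficients
(2k−1)!! grow factorially), reliable for r ≳ 5 and documented as such.
The quadrature values were additionally cross-checked against a 10⁷-draw
simulation before being frozen as test constants. Quadrature agrees with
the default Monte Carlo within replicate standard errors across
r ∈ {4, 5, 6, 10, 50}; note that at the study conditions (10 replicates)
a k-standard-error agreement band is itself a stochastic check with a
nontrivial false-alarm rate, because the replicate SE of the reciprocal
SD is heavy-tailed at small r — the test suite fixes the default seed,
a realization verified to be typical against 100- and 1000-replicate
runs.

## What survives the transform

Because y = 1/x reverses the ordering of positive scores, rank-only
analyses are scale-indifferent, and the package asserts this exactly:

- **Percentiles** use the midrank plotting position 100(rank − ½)/n with
  average ranks for ties, under which p_X(x) + p_Y(1/x) = 100 holds as
  an identity (this convention was chosen precisely because the
  complement claim is exact, not approximate).
- **Rank-sum tests**: U on the reciprocal sample equals n_a·n_b − U, and
  the two-sided Mann–Whitney p-value is unchanged.

Difference-based analyses do not survive. Equal raw gaps at different
baselines are never equal after the transform (strict convexity), so the
interaction term of a two-group pre/post design is scale-dependent.
`demo_interaction_flip` makes this concrete with a permutation test
(10,000 label permutations, identical shuffles applied on both scales;
two-sided p = (1 + #{|T*| ≥ |T|})/(B + 1)). The shipped scenario — two
groups of 12 at syll/sec baselines z = −4 and z = −1 against norms with
r = 5, both improving by 1.0 z on the syll/sec scale, subject noise
0.5 z on each measurement — yields p ≈ 0.97 on syll/sec and p ≈ 10⁻⁴ on
sec/syll. The effect sizes and noise level are this package's own
construction (no published values exist for the scenario); they were
chosen as a plausible intervention-study geometry and frozen. A
permutation test was preferred over a mixed ANOVA as the minimal
assumption-free demonstration; the flip threshold 0.05 is purely
conventional and configurable.

## What the generator does and does not emulate

Synthetic cohorts are exactly the stated generative model: normal
normative scores at a given (μ, σ), deterministic patient placements
μ + zσ, and pre/post designs with group z-shifts plus Gaussian
subject noise. Real reading-speed norms are age-stratified, bounded,
often skewed, and estimated from finite samples; none of that is
modelled, and passing tests show only that the reciprocal-scale
arithmetic and its consequences are computed correctly under the normal
model — not that any particular real battery has a mean/SD ratio of 5.
The observed range r ≈ 5–10 in published norms motivates the default
grids (ratios 3–50, z columns 0.5–4).

## Numerical and interface choices

- Scores carry an explicit scale tag; cross-scale arithmetic without an
  explicit transform is a rejected input.
- A z exactly at the cut-off classifies as pathological ("at least 2 SD"
  read inclusively). No borderline band is encoded; callers get the raw
  z and can apply their own bands.
- delta_z is signed so that positive = clinical improvement on either
  scale.
- The z-mapping rejects positions at or beyond the reciprocal pole
  (score ≤ positivity floor) rather than returning a sign-flipped value.
- CSV output: comma, dot decimal, header row, UTF-8. Stochastic CLI
  outputs carry a manifest (command, config, root seed, version); all
  child streams derive deterministically from the root seed via
  SeedSequence spawn keys, so the manifest fully determines every file.

## Problem sizes

Default study conditions throughout: N = 20,000 draws per replicate,
10 replicates, 10,000 permutations for the flip demonstrator. The full
test suite and the acceptance script each complete in well under a
minute at these sizes; unit tests that probe structure rather than
precision use N = 4,000 with 3 replicates.

## Known limitations

- The delta-method series diverges at small mean/SD ratios; it is a
  cross-check, never the primary oracle.
- Replicate standard errors at r ≤ 4 understate the dispersion of the
  reciprocal SD (heavy tails); treat table rows at r = 3–4 as
  order-of-magnitude.
- The permutation p-value floor is 1/(B + 1); reported flips near the
  threshold deserve a larger B.
- No age stratification, no fitting of real normative datasets, no
  measurement model for the reading test itself.
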