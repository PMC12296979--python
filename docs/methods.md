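# Methods

## Measurement model

The observed data are an N × K matrix of ordinal responses coded 1..c
(default c = 4) with an explicit missing code. Internally categories are
scored 0..c−1; a single conversion layer owns the 1-based external coding.
The generalized partial credit model gives

P(X = x | θ) = exp(Σ_{j≤x} α(θ − τ_j)) / Σ_k exp(Σ_{j≤k} α(θ − τ_j)),

normalized over all c categories (the empty cumulative sum for the lowest
category contributes the baseline term 1). Estimation uses the equivalent
cumulative-intercept form, logit_x = x·α·θ + d_x with d_0 = 0 and
d_x = −α Σ_{j≤x} τ_j, which stays well defined for slopes arbitrarily
close to zero; exact converters between the two forms are provided. All
probability evaluations go through log-sum-exp and remain stable for
cumulative logits of several hundred in magnitude. Missing cells contribute
nothing to the likelihood (ignorable missingness), matching the replication
scheme below.

For multidimensional scales each item loads on exactly one of V traits
(between-item dimensionality); the traits are standard normal with a
correlation matrix R under a uniform LKJ(1) prior (V = 1 fixes R = 1).
Remaining priors: α ~ N(1, 5) — read as variance 5, untruncated so negative
slopes remain admissible — and free intercepts ~ N(0, 5·I). The trait prior
fixes the scale, so no slope sign constraint is imposed; for V > 1 a
residual reflection (majority-negative slopes on a dimension) is detected
after sampling and flipped, with a log entry.

## Sampler

Posterior draws come from Metropolis-within-Gibbs with mode-matched
independence proposals:

* **Persons.** Conditional on items, persons are independent and the 1-D
  conditional posterior of each trait coordinate is log-concave (the GPCM
  score in θ is Σ_i α_i(x_i − E[X_i|θ]) with observed information
  Σ_i α_i² Var[X_i|θ]). Four Newton steps from the conditional prior mean
  locate the mode; a Gaussian proposal there with 1.1-inflated curvature
  scale is accepted by exact Metropolis-Hastings. All N persons (one
  dimension at a time) update in parallel array operations.
* **Items.** Conditional on persons, each item's (α, d₁..d_{c−1}) has a
  log-concave multinomial-logit posterior. Four Newton steps from a
  data-based start (slope 1, intercepts at observed log count ratios) give
  a per-item 4-D Laplace proposal (covariance inflated ×1.2), again
  MH-corrected, all items in parallel.
* **Correlation (V > 1).** One adapted scalar random-walk Metropolis update
  per off-diagonal entry, with positive-definiteness checked by Cholesky;
  the flat LKJ(1) prior makes the target the multivariate-normal density
  of θ alone. Proposal scales adapt during burn-in by a Robbins-Monro
  recursion toward 0.44 acceptance.

Because both conditional families are log-concave, the Newton searches are
globally convergent and proposal acceptance is high; the sampler reaches
rank-normalized split-R̂ < 1.01 and bulk/tail ESS > 400 on every monitored
parameter at the default two chains of 1000 burn-in + 2000 retained sweeps.
Starts are state-independent (proposal validity), chains are seeded from a
spawned seed sequence, and everything is reproducible from one integer
seed. A run that misses the diagnostics bar is retried with doubled
sampling length and a fresh derived seed (at most twice), then returned
with `passed=False` and a warning — never silently discarded. Split-R̂ is
implemented in-package (rank-normalized, maximum of the bulk and folded
statistics); effective sample sizes delegate to ArviZ's implementation of
the same framework.

## Posterior predictive checks

For each retained draw t, a replicated dataset samples every observed cell
from the GPCM probabilities at (θ⁽ᵗ⁾, α⁽ᵗ⁾, d⁽ᵗ⁾); missing cells stay
missing, so observed and replicated statistics share each person's
observed-item denominator. Replicates are streamed draw by draw — per-draw
random substreams spawned from one seed make the streaming computation
bit-identical to a fully materialized one.

* PPP_ER⁽ⁿ⁾ = T⁻¹ Σ_t [I(ER_rep > ER_obs) + ½·I(ER_rep = ER_obs)]. The
  extreme-response proportion is discrete, so ties are frequent; counting
  them as ½ keeps the two-sided index conservative. Equality is decided on
  integer extreme counts — never on floating-point proportions.
* PPP_D⁽ⁿ⁾ = T⁻¹ Σ_t I(D_rep ≥ D_obs) with D = (NE − E[NE])², where
  E[NE⁽ᵗ'ⁿ⁾] sums P(bottom) + P(top) over the person's observed items.
  One-sided (< .1 flags); ties count fully. Direction of a flag comes from
  the sign of NE_obs − mean_t E[NE]; an exact tie is reported as
  `indeterminate` rather than resolved arbitrarily.
* Group PPP_D compares Σ_n D_rep with Σ_n D_obs per draw.
* Group PPP_ER compares the across-person sample variance (denominator
  N − 1; the indicator is invariant to that choice) of ER proportions:
  individual ERS differences inflate the observed variance even when the
  overall extreme rate is unchanged, so the test is one-sided and tends to
  0 under ERS. Variances are computed on sorted values so that the
  indicator can never flip on floating-point summation order.

Cutoffs (.05/.95 two-sided, .1 one-sided) are configurable defaults.
Persons with no observed responses are excluded with a warning.

## Synthetic data generator

The generator emulates a three-node IRTree response process for
four-category items: node 1 (agree vs disagree), node 2 (category 1 vs 2
within disagree), node 3 (category 4 vs 3 within agree). Each node is
logistic in the item's substantive trait and the ERS trait; the ERS slope
is 0 in node 1 and enters nodes 2 and 3 with opposite signs (−1.4 / +1.4),
so a positive ERS value raises both endpoint probabilities at every θ and
never moves agreement. Substantive slopes are 1.9 (node 1) and 1.1 (nodes
2–3); node difficulties b = (0, −1, 1) map to intercepts d = −α_sub·b.
These defaults give exactly 50% marginal agreement and a θ-marginal
category distribution of [0.2, 0.3, 0.3, 0.2] (at θ = 0 the pointwise
distribution is [0.125, 0.375, 0.375, 0.125] up to the 4th decimal —
logistic(1.1) is 0.7503, not 0.75).

Design cells vary the item count (12/24/48), dimension count (1 or 4,
items in contiguous equal blocks; the 4-dimension 12-item cell is
excluded), and a difficulty shift of 0 or −1 added to every node
difficulty. Per-item staggering constants e, the K equally spaced points
of [−0.5, 0.5] assigned in ascending item order, are added to all three
node difficulties of their item. N = 250 persons per replication; traits
are N(0, I). ERS is 0 for everyone (null cells) or drawn from the discrete
grid −3..3 in steps of 0.5 with probabilities proportional to the
standard-normal density at each point (experimental cells), which keeps
"has ERS" well defined per person so true-positive rates can be computed
per grid value.

With the ERS trait removed, a tree item is practically indistinguishable
from a GPCM item: `ccc_max_difference` fits the closest GPCM item over
θ ∈ [−4, 4] and reports a maximum per-category curve gap below 0.05
(default tolerance) for the default items — so misfit the checks detect in
simulated data is attributable to ERS, not to the generator-model gap.

What the generator does **not** emulate: real questionnaires have
heterogeneous slopes across items, correlated substantive traits,
non-normal trait distributions, other response styles (acquiescence,
midpoint), and non-ignorable missingness. Passing operating-characteristic
tests on this generator therefore demonstrates correctness of the method
under its stated conditions, not performance guarantees on arbitrary real
data.

## Study harness and problem sizes

`run_condition` generates, fits, and checks every replication, deriving
per-replication seeds from the master seed by a counter-based scheme
(cell key × replication index), so subsets rerun independently and results
are identical for any parallel worker count. Non-converged fits are kept
with a marker; aggregates excluding them are available. Outcomes follow
the study design: group flag rates per PPP (FPR in null cells, TPR in
experimental cells), pooled person-level FPR among true-ERS-zero persons,
and person-level TPR per nonzero ERS grid value, with a
negative-vs-positive asymmetry diagnostic.

Full-scale cells use 200 replications and the default chain lengths
(2 × (1000 + 2000)); they take hours of CPU per cell and reproduce the
published operating characteristics of this design (e.g. the group
variance check's FPR inflation only in shifted four-dimensional cells, and
person-level TPR ≥ .8 for ERS ≤ −2.5 with 12 items). The test suite and
the acceptance script run desk-scale versions: 10 replications with
2 × (300 + 700) chains and correspondingly relaxed convergence thresholds
(R̂ < 1.05, ESS > 50). At these settings one K = 12 replication takes
roughly 20 s and one K = 24 replication roughly 30 s on a single core, and
the desk-scale operating characteristics match the full-scale qualitative
pattern (person FPR ≈ .02–.03, group TPR = 1, negative ERS easier to
detect than positive).

## Numerical choices and edge cases

* Tie comparisons in PPP_ER use integer counts; tie comparisons of
  variances use order-fixed summation (sorted values); both are exact.
* `thresholds ↔ intercepts` conversion is exact to 1e−10 round-trip; the
  inverse is undefined at α = 0 and raises unless the intercepts are zero.
* Zero-variance diagnostic inputs warn and return a defined fallback
  (R̂ = 1 for constant chains, NaN ESS).
* All-missing persons are excluded from checks with a warning; all-missing
  items contribute nothing to the likelihood; a fully missing dataset
  reproduces the prior.
* The χ² covariate utility drops empty flag rows, flags expected counts
  below 5, and reports a Bonferroni-adjusted α over the number of PPP
  families tested (default 2).

## Known limitations

* Posterior-predictive p-values are conservative (they concentrate near .5
  under the null); no calibration of PPP distributions is provided.
* The IRTree model is generator-only; the package does not estimate it.
* Graded-response and nominal-response measurement models, and checks for
  other response styles, are out of scope.
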