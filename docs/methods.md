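# Methods

## Model and assumptions

The package evaluates truncation selection on a linear phenotypic index
I = b′X over an ordered panel of n traits. Throughout, G denotes the n×n
additive genetic variance–covariance matrix, P the phenotypic matrix, and
E = P − G the residual (environmental) matrix, all in squared trait units
and all in panel order. The core assumptions are the standard ones of
index-selection theory:

- breeding values and phenotypes are multivariate normal, so the index of
  a random candidate is normal with variance b′Pb;
- candidates are phenotyped directly (no relationship-matrix weighting of
  information from relatives);
- the breeding objective is to be achieved in a single generation, so the
  required selection intensity equals the index standard deviation,
  i = σ_I = √(b′Pb), and the correlated response of trait j collapses to
  (Gb)_j (in general it is i·cov(g_j, I)/σ_I);
- the population is large enough that the infinite-population intensity
  formula i(p) = φ(z)/p applies (a Burrows finite-N correction is exposed
  for simulation comparisons, default off and used nowhere else).

Three weight constructions are provided. Smith–Hazel solves Pb = Ga from
economic values a. The desired-gains construction with every trait
constrained solves Gb = Q. The restricted desired-gains index for m < n
constrained traits is b = P⁻¹G*[G*′P⁻¹G*]⁻¹Q with G* = G[:, mask]; it is
the unique minimiser of the index variance b′Pb subject to the expected
responses hitting Q on the constrained traits, which the test suite
verifies against an independent constrained-quadratic-programming solver
(SLSQP) rather than by re-deriving the same algebra. Implied economic
values invert the Smith–Hazel relation, a = G⁻¹Pb, and are reported as
ratios to a reference trait (dry biomass per plant, ratio 1); when that
trait carries zero implied value the ratios are reported as undefined
(NaN) with a warning rather than failing the pipeline.

One printed equation in this literature gives the intensity as
i = σ_I = (b′Pb); the radical is applied here, since only σ_I = √(b′Pb)
is consistent with the univariate breeder's equation i = R/(h²σ_P) and
with the published intensity values.

## Units, conventions, tunable parameters

- Trait order is canonical: the panel fixes it, and file readers align
  labelled matrices to it, never trusting position.
- "Increase by x %" always means x % of the trait's current population
  mean; reports print absolute changes to 2 decimals and percentages to 1.
- Economic-value ratios print as integers when |ratio| ≥ 10 and with one
  decimal otherwise; unrounded values are always available.
- Intensity↔fraction inversion is by bisection on p to |Δp| < 1e-10,
  valid because i(p) is strictly decreasing. Printed pairs are only
  guaranteed consistent in the fraction direction: i is computed exactly
  from the index, while its 2-decimal printed form re-forwarded through
  i(p) can disagree in the last digit (1.41 at p = 0.20 vs the exact
  1.3998; 2.18 at p = 0.038 vs the exact 2.175).
- Monetisation: tonnes/ha = density × Δ × w / 10⁶ with density 4444
  plants/ha (a 1.5 m × 1.5 m grid) and w the implied economic value in
  grams of biomass per plant per trait unit; currency/ha applies a price
  of €70 per tonne. Defaults are arguments of `EconomicAssumptions`.
  Which Δ is monetised follows the field's mixed convention
  ("as_printed" mode): absolute gains use their absolute value, gains
  specified as percent of mean use the percent figure itself, and
  hold-unchanged constraints are valued per unit of the trait (Δ = 1).
  A uniform "absolute" mode is also provided because the per-unit basis
  for percent-specified cell-wall traits is genuinely ambiguous; every
  report records which mode produced it.
- PSD handling: G and E must be positive semi-definite to a relative
  tolerance of 1e-8. Repair (clipping negative eigenvalues to 1e-8 of the
  largest, with a logged warning) is opt-in and off by default, because
  marker-estimated covariance matrices are often slightly indefinite and
  silent repair would mask genuine data errors. Condition numbers above
  1e12 in any solve trigger a warning naming the matrix; all inversions
  are symmetric linear solves, never explicit inverses.

## The synthetic-data generator

`default_panel()` emulates a 16-trait *Miscanthus sinensis* evaluation
(two phenology, eleven morphology/biomass, three cell-wall traits) with
the published current means and broad-sense heritabilities (0.48–0.89).
Genetic correlations stated in the literature are set explicitly:
flowering–yield 0.19, flowering–moisture +0.85, flowering–senescence
−0.85 (the magnitude is the published |r| > 0.8; the sign follows the
direction of the observed correlated responses — delayed flowering goes
with wetter, less senesced biomass), senescence–moisture −0.7 for
coherence of that triad, and height–yield 0.3. All unstated genetic
correlations default to 0.2 within a trait group and 0.05 between groups —
small rather than zero so G is full-rank without repair; environmental
correlations default to 0.1 within groups. Phenotypic standard deviations
are not published for this panel, so a uniform 20 % coefficient of
variation (sd_p = 0.2·mean) is used as a realistic field-trial figure;
this choice was fixed once at design time. The assembled correlation
matrices are projected to the nearest PSD correlation matrix if the
pairwise defaults leave them slightly indefinite (for the shipped
defaults they are already PSD, as a test asserts).

Covariances follow G = D_g r_g D_g with D_g = diag(sd_p√h²) and E
analogously with √(1−h²), so P = G + E recovers the heritabilities
exactly. Populations are drawn as breeding values ~ N(0, G) plus
per-replicate residuals ~ N(0, E) around the panel means — a balanced
clonal-replicate design. `estimate_covariances` uses the classical
among/within-genotype moment decomposition (within-genotype covariance
estimates E; covariance of clone means minus E/reps estimates G), which
is unbiased and serves parameter-recovery testing only.

What the emulation does *not* model: marker data and LD (G is drawn
directly, not estimated from SNPs), estimation noise in G and P (the
pipeline consumes them as known), genotype-by-environment interaction,
non-normal traits (several panel traits are ordinal scores treated as
continuous), and selection over multiple generations. The published H²
values are broad-sense while the index algebra treats G as additive; the
generator follows the source analysis in conflating the two. Passing
simulation tests therefore show internal consistency of the machinery
under its own assumptions — not that any real breeding population has
this covariance structure, and the emulation never claims to reproduce
the published scenario tables, which depend on the supplementary
estimated matrices.

## Numerical and design choices

- Rank-deficiency of G*′P⁻¹G* (genetically redundant constraints) raises
  a "desired gains unattainable/degenerate" error rather than silently
  pseudo-inverting.
- Selection ties are broken by stable genotype order; degenerate
  selection (all scores equal) warns and returns the group mean anyway.
- One seeded `numpy` generator drives each simulated population; every
  stochastic operation takes an explicit seed, so populations are
  bit-reproducible.
- Report writing is byte-deterministic for fixed input; reads and writes
  round-trip at the printed precision.
- Problem sizes for the validation analyses: 20 000 genotypes for
  response recovery (agreement judged at 2 Monte-Carlo standard errors
  per trait) and 50 populations of 1000 genotypes × 4 replicates for
  estimator unbiasedness (3 standard errors elementwise) — sizes at which
  Monte-Carlo error is small relative to the effects being checked while
  the whole suite stays interactive.

## Known limitations

- The scenario solver requires invertible P and full-rank constraint
  sets; it does not regularise near-singular marker-estimated matrices
  beyond the opt-in eigenvalue clipping.
- Monetisation is linear and single-year: no discounting, no
  bioconversion-efficiency effects, no cost side.
- The intensity map assumes an infinitely large, normally distributed
  candidate pool; small-program corrections beyond Burrows' approximation
  (e.g. order-statistic exact values) are out of scope.
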