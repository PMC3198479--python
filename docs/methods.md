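# Methods

## The question

In most purely hereditary genetic models, a child's risk of disease does
not depend on where it falls in the birth order of its sibship. Several
demographic and biological mechanisms break that symmetry: curtailment
of reproduction after an affected birth, parental-age-dependent de novo
mutation, maternal-fetal incompatibility that sensitises later
pregnancies, and heterogeneous mixtures of such effects. `birthorder`
tests whether, in a collection of nuclear families, affected offspring
are distributed uniformly across birth ranks — and quantifies, by
simulation, how well the tests detect specific departures.

## The permutation null

Let family *i* have *N_i* offspring ordered by birth, with binary
affection indicators *y_ij* and per-family affected count *A_i*. The
null hypothesis is that, conditional on *N_i* and *A_i*, every
assignment of the *A_i* affecteds to the *N_i* birth positions is
equally likely. The null distribution of any statistic is obtained by
shuffling each family's affection vector uniformly at random, which
preserves sibship sizes, per-family affected counts, and all
between-family structure. With *T_1..T_K* the statistics of *K* random
shuffles and *T̄* their mean, the two-sided p-value is

    p = #{ k : |T_k − T̄| ≥ |T_obs − T̄| } / K .

Ties count toward the numerator, and the raw fraction is reported (zero
attainable); `PermutationConfig(plus_one=True)` switches to the
conventional (#+1)/(K+1) estimator.

### Discreteness caveat

Rank statistics take integer values and every family orbit is symmetric
about its own mean, so the pooled null often carries a probability atom
exactly at the reflection point 2*T̄* − *T_obs*. Because *T̄* is
estimated from the same *K* shuffles, the centred rule counts that atom
according to the (vanishingly small) sign of the estimation error: the
Monte-Carlo p-value converges to one of two exact limits that differ by
the atom's mass. For collections of realistic size the atoms are tiny
and the effect is irrelevant; the test suite's exact-enumeration oracle
therefore brackets the Monte-Carlo estimate between the two limits
rather than asserting a single value.

## The three statistics

**Rank-sum** — T = Σ_ij r_ij y_ij, the sum of birth ranks of affected
offspring. Most powerful for monotone (linear-like) risk trends in
rank; insensitive to symmetric patterns.

**Inverse rank-sum** — the same sum with rank *z* in a sibship of size
*N* replaced by the V-shaped weight w_z = |2z − N − 1|: largest at the
first and last births, smallest in the middle (0 for odd *N*, 1 for
even). Sensitive to V-shaped profiles in which middle births carry
systematically different risk from extreme births. Size-2 sibships get
equal weights and are uninformative for this statistic. Because
per-family affected counts are conserved by the permutation, any
constant offset added to all weights shifts every orbit value equally
and leaves the p-value unchanged — so only the weights' shape matters,
not their origin.

**χ²-type** — X² = Σ_z (O_z − E_z)² / E_z over birth ranks, where O_z
counts affected offspring at rank *z* across all sibships of size ≥ *z*
and E_z assumes affecteds are uniform within each sibship size: with
A_s the total affecteds in sibships of size *s*, E_z = Σ_{s≥z} A_s/s.
Both sides sum to the total affected count. The O_z are dependent
across ranks (each family contributes to several), so the null is *not*
a central χ² distribution and significance is assessed by the same
permutation scheme. Ranks with E_z = 0 can only have O_z = 0 and are
skipped. This statistic is an omnibus compromise: it detects both
monotone and V-shaped patterns, at some cost in power against either
specific alternative.

## Vectorized permutation engine

A within-family shuffle is realised by sorting the keys
`family_index + Uniform(0,1)`: family blocks stay in place while the
order inside each block is uniformly random. Permutations are processed
in blocks of rows (a ~4M-element budget) so a 10,000-family collection
at K=10,000 runs in seconds; the rank statistics are a matrix-vector
product of the permuted affection matrix with the weight vector, and
the χ²-type observed counts are a product with a rank-indicator matrix.
Custom statistics (any callable on a collection) use an object-level
path with one collection copy per shuffle.

## The simulator

The simulator emulates the kind of family material such studies
analyse: nuclear families with at least two children, collected because
they contain affected offspring.

**Sibship sizes** are Poisson with mean λ = 2.39 (the US average number
of children per family), conditioned on ≥ 2 — one-child families cannot
carry birth-order information and are excluded by the study filters
anyway. The conditional mean is (λ − λe^{−λ})/(1 − e^{−λ} − λe^{−λ})
≈ 3.15.

**Rank-risk models** set each child's affection probability directly
from its rank: constant (null); linear `intercept + slope·z`
(increasing, or reflected within the sibship for decreasing); V-shaped
(linear interpolation from `edge_risk` at ranks 1 and N to
`middle_risk` at the middle rank); or a family-level mixture assigning
each family an increasing trend with probability p₀ and a decreasing
one otherwise. Defaults (intercept 0.05, slope 0.05; edge 0.05, middle
0.25) give risks in the 0.05–0.30 range — substantial but not extreme.
Probabilities are validated at model construction for all ranks up to
`max_rank` (default 12; Poisson(2.39) essentially never exceeds it).

**The logistic age-risk model** makes risk a function of parental age
at birth, risk(x) = b / (1 + e^{−β(x−a)}): maximum risk *b* (default
0.1), half-maximum age *a*, rate β. β = 0, a = 0 gives the
age-independent null at constant risk b/2. Parental ages are generated
per family as a truncated-Normal(25, 5, [15, 45]) age at first birth
plus independent Uniform(1, 4)-year inter-birth gaps, so ages strictly
increase with rank and age effects surface as birth-rank effects. One
parental-age process is tracked per family (recorded as both maternal
and paternal age); separate maternal/paternal streams are out of scope.

**Ascertainment.** By default the simulator retains only families with
at least one affected child (`min_affected=1`), drawing candidates
until the requested number is accepted. This is a deliberate design
choice: disease-family collections are assembled through affected
probands, so "a collection of n families" means n ascertained families.
It also matters enormously for power. Under the age models above, the
*population* frequency of affected children is of order 10⁻³–10⁻²
(almost all parents are far younger than a = 45), so an unascertained
150-family sample contains a handful of affecteds at best and no test
can reject anything; an ascertained 150-family collection contains 150+
affecteds whose within-family positions carry the signal. Conditioning
on per-family affected counts leaves the within-family permutation null
exact, so type I error is unaffected — ascertainment changes how
informative a collection of a given size is, not the validity of the
test. Set `min_affected=0` for population sampling (used by the tests
that check marginal per-rank risks against the models).

Sexes are drawn 50/50 independently of affection; the sex-stratified
machinery in `pedigree_io` therefore sees, under these models, no
sex-specific structure — simulating sex-dependent risk is out of scope.

### What the simulator does not emulate

Real collections add features the generator deliberately omits:
ascertainment probability that *grows* with the number of affecteds
(multiplex enrichment) rather than a sharp ≥1 threshold, reproductive
curtailment after an affected birth, twins, missing phenotypes,
diagnostic heterogeneity, and sex-dependent risk. Passing power and
calibration results on simulated data therefore say nothing about
whether a birth-order signal in real data is biological rather than an
artefact of those processes — the tests quantify *departure from
within-family uniformity*, not its cause.

## Power analysis

A power cell simulates R independent collections under a model, runs
one test per collection (p ≤ α rejects, α = 0.05 by default), and
reports the rejection fraction with its binomial standard error
√(p̂(1−p̂)/R). Defaults R = 100 and K = 2,000 keep a desk-scale runtime;
cells near 0 or 1 are insensitive to K beyond ~1,000. All per-replicate
seeds are spawned deterministically from one master seed
(`numpy.random.SeedSequence`), so tables are reproducible cell-by-cell
and insensitive to evaluation order; the grid runner can cache
completed cells keyed by a hash of their full specification, making
interrupted runs resumable.

Under the steep logistic model (β = 0.5, a = 45) the within-family
risk ratio between consecutive births is ≈ e^{0.5·2.5} ≈ 3.5 on the
ramp, so affecteds in ascertained families pile up at late ranks:
rank-sum power saturates by 150 families, and the inverse rank-sum
statistic — through sibships of size ≥ 3, where late ranks carry the
largest V-weights — saturates as well. Under the shallow linear-age
model (β = 0.05, a = 30) the consecutive-birth risk ratio is only
≈ 1.13 and 150-family power is modest for every test, rising with
sample size.

## Study filters and I/O

The PED dialect, inclusion rules and sex-stratification follow the
conventions of family-collection studies: two-parent families with at
least two offspring of known birth order; twin sets (explicit label or
tied birth year) concordant for affection collapse to one individual,
while a discordant twin set excludes the family (a twin pair shares a
birth position, so discordance is uninterpretable for birth order);
ranks renumber 1..N after collapse, and the filter is idempotent.
Sex-stratified subsets keep families whose affected offspring are
*all* of the given sex (unaffected siblings of either sex retained):
under this rule the male-only and female-only family counts do not sum
to the total in multiplex data, since mixed-sex multiplex families
belong to neither subset. Offspring of unknown sex count toward sibship
size but exclude a family from both subsets if affected. Missing
phenotypes drop the individual (with re-ranking) by default, or the
family under `strict_missing`.

## Problem sizes used in the checks

The shipped verification (`scripts/acceptance.py` and the test suite)
uses: type I error at 500–1,000 families with R = 100 and K = 2,000;
power cells at 150 and 1,000 families with R = 100; single-collection
analyses at 10,000 families with K = 10,000; the exact-enumeration
oracle on orbits ≤ 10⁴; null p-value uniformity on 500 replicates of
150 families. These sizes were chosen to match the scale at which the
corresponding quantities stabilise while keeping the whole run in the
minutes range on one core.

## Known limitations

- Two-sided p-values centred at the estimated null mean inherit the
  discreteness caveat above; for a handful of very small families,
  prefer the exact orbit enumeration (trivial at such sizes).
- The inverse rank-sum weights are one linear V-shape; other symmetric
  weightings (e.g. quadratic) are not implemented.
- The χ²-type statistic skips zero-expectation ranks rather than
  pooling sparse tail ranks; with very few large sibships the tail
  contributes noise.
- No covariate adjustment and no asymptotic p-values; the permutation
  scheme is the only inference path.
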