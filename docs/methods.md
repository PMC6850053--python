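# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Tiles, substratum codes, summary habitats

The primary sampling element is the tile: a mosaic of consecutive seabed
photographs covering a known area (default 7.29 m²) annotated with
fractional cover of three substratum components — hard (bedrock, boulder,
cobbles), coarse sediment (gravelly sand, granules, pebbles, shells) and
sand — summing to 1 (tolerance ±0.001).

Coding rules: the primary component is the one with majority cover (≥50%);
the largest remaining component with ≥10% cover is suffixed in lowercase.
A tile whose largest component is below 50% is *unclassifiable*: it is
flagged and excluded from stratified analyses, never dropped silently.
Exact 0.5/0.5 ties take the fixed precedence hard > coarse > sand (logged;
the choice is arbitrary but deterministic).

Summary habitats: `hard` if the primary component is hard; `intermediate`
if hard cover is ≥10% but not primary; `coarse`/`sand` if the respective
sediment exceeds 90% cover. The intermediate rule is applied to the hard
*cover fraction*, not to the code suffix: when two components qualify as
secondary only the larger is suffixed, yet any ≥10% hard cover makes the
tile a hard/sediment mosaic ecologically. Sedimentary tiles with primary
cover in (0.5, 0.9] and <10% hard match no rule exactly; they are assigned
to the primary component's habitat with a `sub_threshold_mosaic` flag.
The sediment-mosaic codes Cs/Sc are producible by the rules though absent
from the motivating survey; `allow_sediment_mosaics=False` collapses them
to C/S.

Biomass is allometric, `a·L^b` gram wet weight from body length L (cm,
≥1 cm detection limit). Coefficients ship as an editable per-morphotype
table with a single wildcard default (a = 0.05, b = 2.8, a mid-range
invertebrate allometry); taxon-specific values can be dropped in without
code change, and fallback use is logged per morphotype.

## Composite sampling units

Within each stratum, tiles are randomly permuted and cut into consecutive
20-tile groups (~150 m²); a final partial group is kept only at ≥15 tiles.
This concrete threshold is the unique simple rule reproducing every
replicate count in the motivating survey's effort table (remainders of
1, 11, 14, 4, 19, 9, 19 tiles: only those ≥15 kept). Composite-individuals
units accumulate randomly ordered tiles until the cumulative count reaches
the target (default 150); a trailing unit below 75% of target is discarded
(our choice; the source is silent). Note the renewal-theory consequence:
closing at the first crossing overshoots the target by ≈E[X²]/2E[X]
individuals for per-tile counts X, e.g. ≈12 for Poisson tiles of mean 23,
so realised means sit above the nominal target.

Per-stratum random streams are children of the global seed keyed by
stratum name (SHA-256), so adding or removing a stratum never perturbs the
others. Discarded tiles are always reported.

`randomization_check` verifies three things: *conservation* (composite
areas/individuals sum to the retained-tile totals exactly),
*unbiasedness* (pooled density over composites equals the retained tiles'
pooled density — an identity under any partition, so a failed check
indicates bookkeeping corruption), and *exchangeability* (the observed
between-composite density variance is ranked within n_perm re-randomized
partitions; under fair pooling the rank is uniform, and a sorted or
otherwise structured grouping lands in the extreme tail).

## Standing stocks

Tile-level metrics (density ind/m², biomass g wwt/m²) are log-transformed
with an offset before summary and testing, because empty tiles are common
in sparse strata. The density offset defaults to one individual per mean
tile area (1/7.29 ≈ 0.137 ind/m²); the biomass offset to the smallest
positive observed biomass density. Geometric means and t-based 95% CIs are
back-transformed with the offset subtracted, so a constant sample returns
itself with a zero-width interval.

Habitat contrasts use Welch's heteroscedastic one-way ANOVA and
Games–Howell pairwise comparisons (each pair: Welch t with
Welch–Satterthwaite df referred to the studentized range via q = √2·|t|
at the full group count) — group sizes and variances differ an order of
magnitude between strata, so classical ANOVA assumptions fail. With two
groups Welch's F is exactly the squared Welch t; with more groups it is
*not* identical to classical ANOVA even under equal sample variances (the
denominator correction term is positive), so cross-checks against the
classical form are exact only for k = 2. An all-constant-and-equal input
returns (F, p) = (0, 1); a zero-variance group otherwise requires the
explicit jitter policy, since Welch weights are undefined.

Scale profiles accumulate tiles *with replacement* (sizes 2…n), computing
the pooled metric per draw and the median over repeats (default 100;
independent stream per size so the curve is stable under axis
subsetting). Density stabilises almost immediately; biomass stabilises
slowly because body sizes are power-law distributed and the pooled total
is dominated by rare large individuals.

## Diversity

Sample-based rarefaction over composite replicates: Sest from random
orderings without replacement (the curve therefore ends exactly at the
observed pooled richness), expH′ and 1/D from draws with replacement,
n_rand = 1000 in the full protocol. Confidence bands are percentile-based
from the randomization distribution (analytic variance estimators are not
reproduced). The combinatorial expectation Σᵢ[1 − C(T−Tᵢ, t)/C(T, t)]
(evaluated via log-gamma) serves as the analytic oracle for the resampled
Sest; both agree in expectation and the resampling route is the default.
The individuals axis of a curve is the randomization mean of cumulative
individuals at each sample count.

Habitats are compared at an equal number of individuals (linear
interpolation along the individuals axis; no extrapolation). The pipeline
uses the largest effort every group's curve reaches; with `clamp` the
target is clipped into each curve's support — an *approximately* equal
effort, needed when a dense habitat's single smallest replicate already
exceeds the common target — and the effort actually used is reported.

## Composition and unit sizing

Bray–Curtis dissimilarity d(A,B) = Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ) on log1p-transformed
densities; all-zero samples make d undefined and are excluded with a
warning. NMDS minimises Kruskal stress-1 (scikit-learn's non-metric MDS,
normalized stress) over random restarts (default 8), returning the best
and recording every restart's stress; the configuration is centred and
principal-axis rotated with a deterministic sign convention so runs are
comparable. ANOSIM is rank-based, R = (r̄_between − r̄_within)/(M/2),
p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm) — never exactly zero; default
999 permutations. Groups with a single member are excluded (global test)
or skipped (pairwise).

Autosimilarity: per composite size s, two *disjoint* s-tile composites are
drawn without replacement (disjointness guarantees without-replacement
semantics between the pair; the alternative of independent draws was
rejected as it can share tiles), each pooled to a density composition,
log1p-transformed, and scored as 1 − Bray–Curtis; the mean over n_rand
repeats (default 1000) is the curve value. Similarity is 1 − dissimilarity
throughout, and the conventional 0.75 self-similarity target equals a 0.25
within-habitat dissimilarity between replicates. `required_unit_size`
interpolates the first crossing linearly and reports it in tiles, m² and
individuals; if the curve never crosses, it raises with the curve maximum —
for very sparse strata the honest answer can be that the survey is too
small to support a unit of the required size.

## Indicator analysis

IndVal per morphotype and group: A (specificity) = group mean abundance /
summed group means; B (fidelity) = occurrence fraction within the group;
score √(A·B) (indicspecies convention) or A·B, maximised over groups,
tested by permuting sample labels (999 by default; p never zero). The
per-group frequency-of-occurrence table is emitted alongside. Note the
granularity of permutation p-values: with few samples the number of
distinct labelings bounds the smallest achievable p.

The two-way classification is a *simplified* TWINSPAN: abundances expand
into pseudospecies at five logarithmic cut levels (≥1, ≥2, ≥5, ≥20, ≥100
individuals per sample — rounded log-spaced counts, configurable since the
original cut values are unknown); samples polarize by the sign of their
first correspondence-analysis axis score (CA via SVD of the standardised
contingency residuals); the split is refined once by the pseudospecies
with the largest between-side frequency contrasts, which are reported as
the division's indicators. Recursion stops at depth 2 or below 4 samples.
Hill's full algorithm (preferential/borderline pseudospecies handling,
deeper recursion) is intentionally not reproduced; depth-2 CA-based
division is sufficient to recover habitat classes and is deterministic.

## Synthetic surveys

The generator emulates: habitat patch structure along transects
(first-order persistence chain over the four summary habitats; persistence
0.8 by default, stationary probabilities from the motivating survey's area
shares), per-tile cover mosaics from per-habitat Dirichlet archetypes
rejection-sampled to satisfy the defining cover rules (so the seven
canonical codes arise with realistic frequencies), per-tile counts Poisson
at per-substratum densities (defaults derived from the survey effort
table: H 3.21, Hc 2.33, Hs 2.50, Ch 0.347, Sh 0.445, C 0.092, S 0.187
ind/m², a ~35-fold range), optional negative-binomial overdispersion
(dispersion is unknown in the source; Poisson is the default), morphotypes
multinomial from per-habitat pools in which the intermediate pool is an
admixture of the hard and sedimentary pools plus a few exclusive taxa
(geometric rank-abundance within pools), and Pareto body lengths with
x_min = 1 cm.

The body-size tail exponent defaults to α = 3.5: the spec of the problem
only requires α > 1, but expected biomass is finite only for α > b, and
with the default allometric exponent b = 2.8 a smaller α would make
biomass densities non-convergent; α = 3.5 keeps a heavy tail (infinite
variance of L^b, hence the slow biomass stabilisation the analysis is
meant to exhibit) with a finite mean.

Not emulated: detection failure (annotation is assumed perfect),
within-habitat spatial aggregation of fauna beyond habitat patchiness
(no calibrated clustering model exists in the source; overdispersion is
the available knob), navigation error, and tile-area variation (tiles are
constant-area; the real survey's per-class mean tile areas vary ~7%).
Passing tests on generated data therefore demonstrate correctness of the
estimators and the recoverability of configured contrasts — not the
field accuracy of photographic annotation.

## Problem sizes and determinism

Default test and example runs use surveys of 750–2640 tiles,
100–500 randomizations and 99–999 permutations; the full protocol values
(1000 randomizations, 999 permutations, accumulation to 724 tiles) are the
package defaults where the source states them and are practical at survey
scale (the complete default pipeline runs in seconds). Every randomized
stage derives child streams from one global seed via SHA-256 of stage and
stratum keys: results are reproducible byte for byte, and no stage's
stream depends on which other strata are present.

## Known limitations

* The TWINSPAN-style classifier is a deliberate simplification (above).
* Permutation p-values are granular at small n; report n_perm alongside.
* Games–Howell p-values rely on the studentized-range approximation with
  per-pair Welch df; for n < ~6 per group they are approximate.
* The composite-individuals unit overshoots its nominal target by the
  renewal bias described above; compare realised, not nominal, efforts.
* Autosimilarity requires 2s tiles for size s; the largest assessable unit
  is half the stratum, which can be binding exactly where the required
  unit is largest (sparse strata).
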