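# Methods

This note documents the statistical procedures, conventions, and design
choices in `intromaps`, and what the synthetic-data generator does and
does not emulate.

## Interval model

All maps are reduced to canonical interval sets: per chromosome, sorted,
non-overlapping, with touching intervals merged. Coordinates are 0-based
half-open (BED); a 1-based variant position `p` becomes `[p−1, p)`.
Merging touching intervals is a deliberate bp-set semantics: every
statistic in the package is a base-pair count, for which adjacency carries
no information. Set operations are computed by a sweep over interval
breakpoints with per-set weights, which also yields, in one pass, per-bp
support counts and exact covering-subset bitmasks for up to 62 maps.
Correctness is established in the test suite against brute-force boolean
membership arrays on toy chromosomes.

Assembly gaps, when provided, are subtracted from both numerator and
denominator of genome-coverage fractions only; interval sets themselves
store coordinates as published. Jaccard statistics use the raw maps
(gap bp are not excised from intersections or unions): published maps
rarely call inside gaps, so this matters only if a callset does, and
keeping the raw maps makes the statistic a pure function of the inputs.

## Harmonization

Published callsets arrive as scored BED-like text with method-specific
score semantics (LOD, posterior probability, S'-type scores, ...). A
single generic reader handles them with a dialect flag (`half_open` or
`closed_end`; the latter increments ends on read) and an optional score
threshold, mirroring the fact that published cutoffs are pre-applied to
the distributed files. Overlapping or touching fragments — typically one
row per population grouping — merge into maximal regions, and each merged
region retains the **maximum** score among its constituents. Files
without a score column get a sentinel score of 1.0 (logged); such maps
participate in all comparisons but order arbitrarily under size-matching.

## Concordance statistics

`jaccard(a, b) = |a ∩ b| / |a ∪ b|` and
`normalized_jaccard(a, b) = |a ∩ b| / min(|a|, |b|)`, both at bp level.
Conventions for degenerate inputs: the Jaccard of two empty maps is 0
(agreement between absent predictions carries no signal), and the
normalized Jaccard is 0 when either map is empty.

**Size-matching** truncates a map to a fixed bp budget of its
highest-scoring regions: whole regions are admitted in descending score
order, ties broken by genome position (chromosome order, then start) for
determinism, and the last admitted region is cut from its right end so
the budget is met exactly. Exact truncation was chosen over dropping the
straddling region because the published budget (793.9 Mb) is stated to
0.1 Mb precision, implying exact matching; the default budget constant
`DEFAULT_SIZE_MATCH_BP = 793_900_000` is exposed in the comparison
module. Size-matching is monotone: a larger budget yields a superset.

**Support profiles** partition the union of maps into maximal runs of
constant support count; per-map unique bp are the support-1 runs
attributed to their single caller. **Highly supported** regions default
to support ≥ 10. **Combination counts** assign every union bp to exactly
one covering subset, so counts are disjoint and sum to the union size.

**Clustering** is agglomerative complete linkage ("farthest point":
`d(u, v) = max dist(u[i], v[j])`) on the distance matrix `1 − J`,
delegated to `scipy.cluster.hierarchy.linkage`; tests verify merge orders
and heights against an exhaustive reference. Output matrices are ordered
by the tree's leaf order.

## Individual-level concordance

For a shared cohort, the pairwise Jaccard is computed per individual and
aggregated to an arithmetic mean and an uncorrected (population) SD per
method pair; the full per-individual distribution is retained. An
individual with an empty map under one method contributes Jaccard 0
rather than being dropped — absence of calls is a prediction difference,
and dropping would bias means upward (`drop_empty_pairs=True` switches
this). Cohorts must be fully shared: a missing (method, individual) map
is an error, because averaging over different individual sets per pair
would make the pair means incomparable.

## Background-selection contrast

The genome is tiled into fixed windows (default 500 bp), keeping the
trailing partial window on each chromosome (it carries fewer bp but a
valid label); windows wholly inside assembly gaps are dropped. A window
is introgressed iff it overlaps at least one called bp. B values are
attached per window as the bp-weighted mean over overlapping B segments;
windows with no B coverage are missing and excluded from both classes.

The contrast reports class means, their ratio, 95% percentile bootstrap
CIs (1,000 iterations; per-class resampling for the class CIs, joint
resampling for the ratio CI), and a two-sided Mann-Whitney U test.
Percentile rather than BCa intervals: the statistic is a mean over
thousands of windows, where the two coincide to within Monte-Carlo noise.
The rank-sum test uses midranks; when both groups have ≤ 7 observations
the permutation null is enumerated exhaustively (tie-safe — two-sided
p = the fraction of reassignments whose U is at least as far from
n₁n₂/2 as observed), otherwise the normal approximation with
tie-corrected variance and continuity correction is used. When every
pooled value is identical, p = 1 with a warning.

## Deserts

Consensus desert regions are maximal merged runs where at least `k`
study desert sets overlap; each merged region is annotated with the
maximum support it attains (region individuation = maximal runs of the
thresholded support track, with touching runs merged). Per-desert
introgression is `raw = |window ∩ map| / |window|`, normalized by the
map's genome-wide introgression proportion computed on the gap-excluded
genome (consistent with the coverage-percentage denominator); a map with
zero genome-wide coverage has no defined normalization and is rejected.

## Synthetic-data generator

The generator injects structure directly at the interval level — no
coalescent or sequence simulation. The default study conditions: a toy
genome of 800 kb + 400 kb; M = 5 maps; a shared core covering 30% of the
genome; 10% private calls per map; mean region length 3 kb with
geometric (discrete exponential) lengths, the shape expected for
introgressed tracts under a recombination clock; two desert zones
(50 kb + 30 kb) where no map ever calls introgression; core regions
scored N(8, 1) and private regions N(3, 1), so size-matching
preferentially retains the core; B tracks with baseline N(600, 120)
quantized to multiples of 50 in [50, 1000] and a multiplicative effect
δ on introgressed windows (δ = 1.06 in recovery tests, matching the
magnitude of published contrasts).

Placement is uniform by stars-and-bars over the concatenated available
space, with per-map private totals hit exactly (lengths resampled until
the running sum crosses the target, then trimmed). One master seed fans
out to per-component substreams, so runs are byte-stable and adding a
map does not perturb earlier maps.

### Closed forms used by the recovery tests

*Support share.* Private coverage per map behaves as a stationary on/off
renewal process on the available space `A` with on-probability
`q = private_bp/|A|` and mean on-length `L`. For the share of union bp
supported by all M maps, the expectation is
`(C + |A|·q^M) / (C + |A|·(1 − (1−q)^M))` with `C` the core size. The
variance of covered bp follows from integrating the union indicator's
autocovariance, `Σ_{j≥2} C(M,j) (1−q)^{2(M−j)} (q(1−q))^j · 2|A|L(1−q)/j`;
the j = 1 term vanishes because per-map totals are fixed exactly by
construction (conditioning removes own-total fluctuation). The ratio's
SD follows by the delta method. The formula was validated against
replicate simulations when it was derived.

*Individual Jaccard.* With per-region detection masks of sensitivity
`s₁, s₂`, the expected per-individual Jaccard is
`s₁s₂ / (s₁ + s₂ − s₁s₂)` for independent masks, and `s₁ + s₂ − 1` when
the methods' missed regions are disjoint (many-regions limit; carried
regions cancel from numerator and denominator).

*B ratio.* Scaling introgressed-window draws by δ before quantization
gives an expected ratio of class means ≈ δ; rounding to multiples of 50
is symmetric for the smooth baseline used, so quantization bias is
negligible relative to the bootstrap CI width.

### What the generator does not emulate

Real maps differ in ways the generator deliberately ignores: LD-driven
autocorrelation of calls, heavy-tailed and method-dependent tract-length
distributions, shared haplotype structure among cohort individuals
(individuals here carry regions independently), spatial autocorrelation
of the B statistic along the genome (windows are drawn i.i.d.), score
distributions with method-specific shapes, and reference/assembly
artifacts. Passing recovery tests therefore demonstrates that the
statistics are computed correctly and are well calibrated under a known
construction — not that any particular real map pair is concordant.

## Problem sizes and numerical choices

Tests and the acceptance script run on toy genomes (tens of kb for
oracle checks, 1.2 Mb for ensemble statistics), chosen so the whole suite
completes in well under a minute of brute-force-verifiable computation
per property: 200 random instances for oracle equivalence, 100 replicates
per core fraction for support-share recovery, 100 simulated tracks for
bootstrap-CI coverage, 500 for rank-sum calibration. Score ties in
size-matching are broken by genome position; bootstrap and generator
randomness always flows from explicit seeds; floating-point output is
formatted with `%.10g` so repeated runs are byte-identical.

## Known limitations

- The bitmask combination engine supports at most 62 maps (int64).
- Per-study parsers for the various published formats are out of scope;
  inputs must be BED-like text (a dialect flag covers closed-end files).
- No liftover: all maps compared must already share an assembly.
- The exact rank-sum path enumerates `C(n₁+n₂, n₁)` assignments and is
  only engaged when both groups are ≤ 7.
- Desert consensus treats each study set as equally credible; there is no
  weighting by study power or cohort size.
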