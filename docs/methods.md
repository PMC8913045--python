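# Methods

This note documents the statistical procedures, the defaults and their
rationale, the synthetic-data model, and the numerical choices made where
the design was genuinely open.

## Augmented-design adjustment

The fieldbook model is `y = mu + block_j + genotype_i + e`, with unreplicated
test entries and a check panel replicated in every block. Block effects are
estimated from checks only: `b_j = mean(checks in block j) − grand mean of
check plots`; a test entry's adjusted value is `y − b_j`, a check's is its
across-block mean. Because every check sees every block, the estimated block
effects sum to zero and check adjusted means are invariant to the block-effect
magnitude; with zero residual noise the adjustment recovers the true genotype
values exactly (both properties are tested). The error mean square is the
block × check interaction of the check sub-table, df = (b−1)(c−1). Mixed-model
(BLUP) alternatives are deliberately out of scope.

Negative adjusted values are floored at zero only when the caller asks for it
(`floor_at_zero`), intended for traits that are physically non-negative such
as plot yield; the schema carries a `non_negative` flag for this purpose.

## Variability statistics

`VP` is the sample variance (n−1 denominator, used consistently everywhere,
including z-scoring) of the adjusted means; `VG = max(VP − error MS, 0)`,
with a `vg_truncated` flag when the subtraction would be negative — variance
components cannot be negative, but the flag preserves the information.
`h² = VG/VP`, `GCV/PCV = 100·√V/mean`, and the expected genetic advance is
`EGA = k·√VP·h²` with `GAM% = 100·EGA/mean`. The `k·√VP·h²` form is the
standard truncation-selection response (it equals `k·h·√VG`); the selection
intensity `k = φ(Φ⁻¹(1−p))/p` evaluates to 2.0627 at p = 0.05.

Category scales: GCV/PCV low < 10, medium 10–20, high > 20; h² (percent)
low < 30, medium 30–60, high > 60; GAM low < 10, moderate 10–20, high > 20.
Boundaries are closed from below for the upper class (a GCV of exactly 10 is
"medium"); one convention had to be picked and it is tested explicitly.

## Gower distance and diversity

For accessions i, j the per-trait contribution is `|x_i − x_j| / range` for a
quantitative trait and a 0/1 mismatch for a qualitative one; the distance is
the mean contribution over traits observed in both accessions (pairwise
deletion, no imputation). Ranges are always taken from the whole collection
so the distance between a fixed pair is identical in every context.
Zero-range traits are dropped from the average with a record in
`dropped_traits_`. Qualitative descriptors are treated as unordered nominal
even when visually ordinal (e.g. spike density lax/intermediate/dense);
Gower is scale-free, so distances are computed on raw values by default,
with an optional pre-standardization switch for parity with tools that
require it.

Shannon–Weaver diversity `H′ = −Σ p ln p` uses observed class frequencies
but the *declared* class count for `H′max = ln k`, so evenness is comparable
between a core and its whole collection even when the core misses rare
classes.

Core distance summaries: E-NE is the mean distance from each core entry to
its nearest other entry (diversity; low values indicate redundancy), A-NE
the mean distance from every collection accession to its nearest entry
(representativeness; core members contribute zero), E-E the mean pairwise
entry distance. E-NE ≤ E-E always, and A-NE is monotone non-increasing as
entries are added.

## Core samplers

Target size is round-half-up of `n × fraction` (default fraction 0.10, the
classic core proportion), never below the forced-inclusion kernel. The
kernel is a user-supplied id list — in practice a curator's pre-selected
accessions — and is honoured by all samplers.

**Distance optimization.** The objective is `w_ene·ENE − w_ane·ANE`
(maximized): E-NE is a diversity criterion to maximize, A-NE a
representativeness *distance* to minimize, hence the sign. The weight pairs
(1,0), (0,1), (1,1), (0.3,0.7), (0.7,0.3) form the default five-strategy
battery. The search is seeded simulated annealing on the single-swap
neighbourhood (non-kernel member ↔ non-member), geometric cooling
(factor 0.995 per proposal, initial temperature 0.02·(w_ene+w_ane), i.e. a
few percent of the distance scale), restart on stagnation (default 4
restarts, patience 600, 3000 proposals per restart), best-ever retained with
a non-decreasing objective trace. On instances small enough to afford the
full swap neighbourhood the result is polished by steepest single-swap (and,
on tiny instances, two-swap) hill climbing; a brute-force enumeration oracle
on 12-choose-4 instances guards correctness. The original tools' parallel
tempering engine is intentionally not replicated: bit-exact replication of
external software is a non-goal, and the annealer is simple, reproducible,
and verified optimal at desk scale.

**Richness maximization.** Quantitative traits are binned per the schema
rule (Sturges `ceil(log2 n + 1)` bins by default, or `fixed:k`); the sampler
greedily adds the accession covering the most yet-uncovered (trait, class)
tokens, breaking small ties by the summed Shannon H′ of the resulting core,
then refines by swaps using incremental coverage counts.

**Class coverage.** Phase 1 is a greedy set cover of every observed class;
phase 2 fills to the target size by maximal-minimum-distance addition
(the accession farthest from the current core joins next). When the minimal
cover already exceeds the target, the cover is returned with a
`size_violation` flag rather than silently dropping classes — the target-size
fill rule is this package's choice, since coverage-driven tools normally
let the cover determine the size.

Determinism: every sampler takes a `random_state`; ties break by accession
id order after a seeded shuffle.

## Evaluation battery

MD% and VD% are *percent of quantitative traits* whose core-vs-whole mean
(Welch t) or variance (Levene, median-centred) difference is significant at
α = 0.05 — so with m traits the values are multiples of 100/m. CR% and VR%
are the mean ratios 100·(core range)/(whole range) and 100·(core CV)/(whole
CV). Thresholds for a good core: VD ≥ 80, CR ≥ 80, VR ≥ 100 (mandatory) and
MD < 20 (advisory: the most diverse cores often shift means while remaining
desirable, so MD does not gate the verdict). No multiplicity correction is
applied across traits — the indices are defined trait-wise — and the core is
treated as an independent sample even though it is a subset of the whole;
the positive dependence makes the mean-difference tests conservative. Both
caveats are deliberate and documented rather than "fixed".

The distribution comparison uses a histogram KL divergence: shared
Freedman–Diaconis bins on the pooled sample (minimum 5), 1/(2n) pseudo-mass
added per bin before normalization, divergence of the core from the whole in
nats. The estimator is consistent (it converges to the 0.5-nat closed form
on a unit-shift Gaussian pair in tests); no specific estimator is canonical
for this index, so the choice is documented here.

The Mantel test correlates the upper triangles of the two trait correlation
matrices, with a two-sided permutation p-value from seeded simultaneous
row/column permutations (default 999; 199 inside the pipeline for speed).
The Student–Newman–Keuls comparison reduces, for two groups, to a
studentized-range test with `q = √2·|t_pooled|`. PCA compares the
eigenstructure of each set's trait correlation matrix (component SD =
√eigenvalue); components beyond the matrix rank are omitted.

Ranking: cores passing all mandatory thresholds come first, then
lexicographically higher E-NE, lower A-NE, higher E-E, higher mean core H′,
with the strategy tag as the final deterministic tie-break.

## Synthetic data

The generator emulates a large barley-type genebank characterization:
defaults are 8 quantitative traits (means, CV%, minima and maxima matching a
~6,800-accession collection, e.g. hundred-grain weight mean 3.99 g in
[1.20, 6.86]) and 9 qualitative descriptors with realistic class frequencies
(89% six-rowed, 13% hulless, 96% awned, 96% spring habit, …). Declared class
counts follow the descriptor definitions (e.g. six awn types, four lodging
levels), including classes that are rare or absent in a given draw.

Quantitative traits are drawn through a Gaussian copula at the target
correlation matrix (nearest-PSD-repaired by eigenvalue clipping if needed),
with each marginal a truncated normal whose *post-truncation* mean and SD
are fixed-point–matched to the targets. The default correlations set the two
strongly established pairs (days to spike emergence × maturity 0.58, plant
height × yield 0.53) and modest positives (0.1–0.5) among yield components
that are known to co-vary but whose magnitudes are not pinned down.
Truncated normals are the simplest family consistent with a mean, a CV and
a range; skewness and genotype × year structure are not modelled, and
qualitative traits are independent of the quantitative block except an
optional off-by-default row-type linkage (two-rowed spikes get ~0.6× the
grain count). Consequences for interpretation: passing tests demonstrate
correct estimation and search behaviour under this structure, not
performance under real-data features such as skewed yields, missing-data
patterns, or trait–descriptor dependence.

Fieldbooks follow the augmented layout (default 40 blocks, 5 checks
replicated in every block, test entries dealt evenly with a possibly smaller
last block) with independent normal block/genotype/residual effects and the
true effects returned for recovery testing.

At n = 5000 the generator reproduces every target correlation within ±0.05
and every class frequency within ±0.02 (seeded tests).

## Problem sizes and numerical choices

The test suite and the acceptance script run the full seven-core battery on
a 1,000-accession synthetic collection (distance matrix 1000², five
annealer configurations plus the two greedy samplers, seven evaluations) —
large enough for the indices to behave as they do at collection scale while
keeping a complete run to well under a minute. Monte-Carlo checks use 5,000
accessions (generator moments), 50 replicates (h² recovery, tolerance
±0.1), 1,000 replicates (test calibration, 0.05 ± 0.02) and 50,000 samples
(KL convergence, ±0.05).

Degenerate inputs are handled explicitly: constant quantitative traits are
rejected by standardization and excluded from Gower; VP = 0 yields a flagged
degenerate variability record with undefined h²; a single observed class
gives H′ = 0; an empty core or invalid selected fraction raises.

## Known limitations

- The Federer check-based adjustment is the only supported design analysis;
  no spatial trends, no multi-year combination.
- The evaluation tests are descriptive indices; their nominal α applies to
  independent samples, not to core-within-whole comparisons.
- MD%/VD% depend on sample size through test power: small collections
  rarely clear VD ≥ 80 even for excellent cores, while very large ones
  flag trivial mean shifts. The thresholds come from the core-collection
  literature and are applied as-is.
- Richness/coverage samplers see quantitative traits only through their
  bins; bin-rule choice changes their objectives.
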