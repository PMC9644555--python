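# Methods

## Problem setting

Microbial amplicon counts are compositional: a sample's reads are a
(roughly multinomial) draw from relative abundances, so naive Pearson
correlations between taxa are confounded by the unit-sum constraint.
The pipeline estimates *basis* correlations — correlations of the latent
absolute log-abundances — and studies their network structure jointly
across the six taxonomic ranks (Phylum … Species), because a genus and
its species share abundance signal that single-rank analyses discard.

## Stacked-taxa matrices

For each rank, feature counts are summed into their assignment names and
the per-rank tables are concatenated column-wise. Choices that needed
making:

- Features unassigned at a rank are excluded from that rank's
  aggregation only (never pooled into an "unclassified" bucket, which
  would fabricate a taxon whose correlations mix unrelated lineages);
  they still contribute at ranks where they are assigned.
- Presence means count > 0; the prevalence filter keeps taxa present in
  **at least** 10% of samples (boundary inclusive) and is applied after
  stacking — the criterion is per-column, so per-rank filtering before
  stacking would be equivalent. This is recorded in the provenance.
- Sample depth filter: library size ≥ 1000 reads, boundary inclusive.
- Taxon identifiers are `<rank-prefix>__<name>` (`g__Bacteroides`), so
  identical names at different ranks cannot collide.
- Counts stay raw integers: SparCC consumes counts, and no normalisation
  or rarefaction is applied anywhere.

## SparCC

Fractions are Dirichlet-posterior draws `x ~ Dir(counts + 1)` per
sample; the deterministic posterior mean `(c_i + 1)/(N + p)` is exposed
separately. From log-fractions, the pairwise log-ratio variance matrix
`t_ij` is inverted for basis variances via the linear system
`M ω = t·1`, `M = 11ᵀ + (p − 2) I`, which encodes the sparsity
approximation `Σ_j r_ij ≈ 0`; then
`r_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j))`, clipped to [−1, 1].

Defaults (all config keys): exclusion threshold 0.1 with at most 10
exclusion rounds (each round removes the strongest remaining |r| pair
from the system and re-solves — strongly correlated pairs violate the
sparsity assumption), and 20 Dirichlet resamples whose estimates are
averaged. A negative estimated basis variance is floored to the smallest
positive estimate with a warning rather than aborting, so parameter
sweeps do not die on one pathological taxon. Below 4 taxa the basis
variances are unidentifiable and the solver refuses to run.

Significance: the "bootstrap" p-values are a permutation null — each
taxon's count column is permuted independently across samples, which
destroys all taxa–taxa association while preserving every marginal, and
SparCC is recomputed per replicate. The two-sided add-one estimator
`p = (1 + #{|r_b| ≥ |r_obs|})/(B + 1)` keeps p strictly positive.
Within-sample Dirichlet re-draws would be an alternative null; the
permutation scheme was chosen because it targets exactly the
no-association hypothesis the edge filter needs. BH adjustment runs over
the upper-triangle p-values and is mirrored.

## Signed TOM

Adjacency `A_ij = ((1 + r_ij)/2)^β` keeps the sign information
(r = −1 → 0, r = +1 → 1). β defaults to **2**: SparCC basis correlations
are weaker and sparser than expression correlations, and the
conventional expression-network default of 12 would annihilate the
network. A scale-free-fit R² diagnostic is provided but never auto-picks
β. A `clip_negative_r` switch zeroes negative correlations before the
transform for users who read "focus on positive correlations" as
discarding negatives outright; default off. The TOM uses the standard
formula with connectivity excluding the diagonal; a fully isolated pair
gets TOM = 0 by an explicit guard.

## Consensus modules

One complete-linkage dendrogram of `1 − TOM` is cut per minimal module
size 3..40. The cut is a tree-variant dynamic cut: a static cut at a
configurable fraction (default 0.5) of the merge-height range gives base
clusters, then clusters below the minimal size are merged into their
nearest cluster by complete-linkage distance, repeatedly. The merging
step is what makes the partition genuinely coarsen as the minimal size
sweeps upward; a leftover undersized cluster with no partner falls to
the reserved unassigned label 0. (A cut at 0.99 of the range was
rejected: signed-TOM dissimilarities occupy a compressed band, and a
near-top cut collapses all real structure into one cluster.)

Duplicate partitions are detected by co-membership equality (invariant
to relabeling); unassigned taxa are co-members of nothing, including
each other. Unique patterns with ≥ 10 modules (config key; the sweep's
stable region) are averaged into the CSPA consensus matrix C, diagonal
forced to 1.

The module count k is chosen on C: candidates are cuts of the `1 − C`
complete-linkage tree into exactly k clusters for k = 2..k_max, where
k_max is the largest module count among the selected patterns (the
patterns bound the granularity worth considering); cuts that cannot
realise k distinct clusters (zero-height ties) are skipped. A candidate
passes the gate when every module's off-diagonal consensus block has
< 10% exact zeros; among gated candidates scanned in ascending k, the
first local maximum of the average silhouette width wins, with one-sided
comparisons at the ends and ties resolved toward the smaller k
(parsimony). Silhouette is computed on `1 − C` with the standard
a(i)/b(i) definition and the singleton-cluster-scores-zero convention.

## Module preservation

Reference-condition modules are scored in the test condition with four
correlation-network statistics: density (mean intramodular test
correlation; mean intramodular test adjacency) and connectivity
(correlation of ref vs test intramodular connectivity vectors;
correlation of ref vs test intramodular correlation entries). The null
permutes module membership over the taxa shared by both conditions (100
permutations by default); `Z = (obs − mean_null)/sd_null`,
`Z_density`/`Z_connectivity` are medians of their pairs and `Z_summary`
their mean. The conventional reading is Z_summary > 10 strong
preservation, < 2 none. `medianRank` is the median over the four
statistics of the module's descending rank among modules, less sensitive
to module size.

Per-module permutation streams are seeded from the module's *membership*
(CRC of the sorted taxon list mixed with the user seed), so Z statistics
are exactly invariant to module relabeling. A null statistic that is
constant across permutations (e.g. comparing a condition against an
identical copy makes the ref/test connectivity correlation identically
1) yields Z = ±∞ with a `degenerate` flag and is excluded from the
medianRank ranking. Both comparison directions (A-as-reference and
B-as-reference) are computed, since either condition may host structure
absent from the other. Eigentaxon-based statistics were deliberately
omitted: the four implemented statistics are the correlation-network
members of the composite, and the per-module component table is exported
so users can recombine them.

## Intra-modular edges and influence

Edges require `r ≥ 0.2` **and** BH `q ≤ 0.05`, both bounds inclusive;
the intra-modular subset additionally requires module co-membership
(label-0 taxa never co-member). Comparing two conditions' intra-modular
edge sets partitions their union into disease-only / control-only /
shared.

The leave-one-out test evaluates each taxon assigned a non-zero module
in either condition. Its evaluation graph is the union of both
conditions' filtered intra-modular edges over {taxon} ∪ its module
members in A ∪ its module members in B (a per-condition mode is
available); graphs are unweighted — the quoted centralities are their
classic unweighted forms. "Removal" deletes the taxon's incident edges
while keeping the node universe, so the (n−1) normalisations of degree
and closeness stay on a common scale and an edge-less taxon is an exact
null (no metric moves — this is what makes the test's null honest).
Closeness uses the Wasserman–Faust per-component convention (scaled by
the reachable fraction; singleton components get 0); local transitivity
is 0 for degree < 2. Each metric's paired differences over the remaining
nodes go into a two-sided Wilcoxon signed-rank test (exact distribution
up to 25 informative pairs, normal approximation with continuity
correction beyond; a metric with fewer than 5 non-zero differences is
untestable and gets p = 1, and a taxon with no testable metric is
flagged underpowered). BH runs per taxon across its three metric
p-values (a global-across-taxa mode exists); any q ≤ 0.05 marks the
taxon influential. Differential-abundance annotations are joined from
user-supplied tables only — the pipeline never recomputes DA.

## Synthetic data

The generator realises the model under which SparCC is consistent:
per sample, basis log-abundances are multivariate normal with a
correlation matrix containing planted blocks (within-block correlation
ρ, background 0 by default); fractions are the softmax; counts are
multinomial at a lognormal depth. Defaults emulate a small 16S study:
150 samples per condition, a balanced 6-rank tree (64 species at the
default fanout), unit log-SD, depths lognormal around 20 000 reads
(SD 0.5 on the log scale) — deep enough that the 1000-read filter is
essentially never triggered, which keeps fixtures focused on the stage
under test. Blocks carry a scope (both / A-only / B-only); out of scope
they are replaced by independence. Condition substreams are spawned from
one seed, so generating B never perturbs A's draws.

What the generator does *not* emulate: overdispersion beyond the
lognormal-multinomial (no zero-inflation beyond sampling zeros), uneven
taxonomies, contaminants, or batch effects. Passing tests therefore
demonstrate correctness of the estimators under their own generative
assumptions, not robustness to real-data pathologies.

## Fixture and test sizes

Chosen as the smallest sizes at which the planted effects are
unambiguous: correlation recovery uses 40 taxa × 200 samples (20 seeds);
null calibration 46 taxa × 100 samples at B = 200 (1035 pairs);
consensus recovery five 12-taxon blocks at ρ = 0.6, 150 samples;
preservation a 20-taxon ρ = 0.6 module among 60 taxa; the end-to-end
two-condition study uses a 32-species taxonomy (~70 stacked taxa),
ρ = 0.7 blocks of 8 species, B = 200 bootstraps. Exact-oracle checks
(TOM, silhouette, BH, Wilcoxon) run on 100 random instances each at
tolerance 1e-12.

## Known limitations

- The tree-cut variant is a simplification of full dynamic tree cutting;
  deeply nested module structure at very different tightness scales may
  need a different `height_fraction`.
- Permutation p-values at B bootstraps are bounded below by 1/(B+1);
  with many taxa, BH-significant edges need B well above the default
  recommendation of at least ten — the 1000 default is sensible for real
  studies.
- Z_summary grows with module size; medianRank is reported alongside
  precisely because of this, and both should be read together.
- The correlation stage accepts a precomputed correlation + p matrix as
  a bypass, but no alternative estimators (COAT, Pearson variants) are
  implemented.
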