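# Methods

## Model and procedure

`coexnet` analyses gene-level expression matrices X (genes × samples),
one per cohort, under the standard weighted co-expression model: the
co-expression network is the soft-thresholded correlation matrix, gene
modules are branches of the average-linkage dendrogram of topological
overlap dissimilarity, each module is summarised by its eigengene (the
first principal component of its standardized expression), and
cross-cohort module preservation and within-module hub status are
assessed by permutation tests. The pipeline assumes data are already
normalized and batch-corrected; its only preprocessing steps are
probe→gene collapse by maximal median absolute deviation and removal
of the lowest-mean fraction of genes.

### Network construction

Pearson correlation is the default and only correlation estimator.
Exactly constant genes are flagged and assigned correlation 0 to all
others. The adjacency is a_ij = |r_ij|^β (unsigned, default) or
((1+r_ij)/2)^β (signed); the network type is a configuration choice
recorded in the soft-threshold report, since published workflows often
leave it implicit ("signed R²" in scale-free plots refers to the fit
statistic, not the network). The scale-free fit bins connectivity
k_i = Σ_{j≠i} a_ij into 10 equal-width bins (empty bins dropped,
non-positive bin means dropped) and regresses log10(fraction of genes)
on log10(mean k); signed R² = −sign(slope)·R². Degenerate inputs
(constant k, fewer than two usable bins) score 0 with a warning. The
chosen power is the smallest in 1..20 reaching signed R² ≥ 0.85; when
no power qualifies, the pipeline falls back to the best-fitting power
(or a configured override) with a warning.

Topological overlap uses the unsigned formula
TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), with the adjacency
diagonal excluded from both l and k; the matrix-product implementation
is property-tested against a triple-loop oracle.

### Module detection

The dynamic hybrid tree cut is a contract-level reimplementation of
the reference algorithm rather than a line-by-line port. A static cut
at 99% of the height range above the 5th-percentile merge height
splits the dendrogram into components; within each component, branches
are carved recursively. A branch qualifies as a module when its core
scatter (mean internal merge height) is at most
ref + m(ds)·(cut − ref) and its gap to the joining height is at least
(1 − m(ds))·(3/4)·(cut − ref), where m(ds) ∈ {0.64, 0.73, 0.82, 0.91,
0.95} is interpolated from `deep_split` exactly as in the reference
method; a qualifying branch is split further only when both children
independently qualify at its own merge height. Branches below
`min_module_size` dissolve. A second stage attaches each leftover gene
to the nearest module by average TOM dissimilarity if that distance is
within the module's internal dissimilarity mean + 3 sd (capped at the
core-scatter bound); everything else stays "unassigned". The PAM-stage
options of the reference implementation are deliberately not exposed;
the simplification is gated on planted-partition recovery tests
(exact recovery of three planted blocks, dissolution of undersized
blocks, all-unassigned on structureless input).

Eigengenes are the leading right singular vector of the z-scored
module submatrix (unit norm, one value per sample), sign-oriented so
the correlation with the mean standardized profile is non-negative;
zero-variance genes are dropped with a warning. Modules whose
eigengenes correlate above 1 − `merge_cut_height` (default 0.05) are
merged iteratively, the merged module keeping the largest
constituent's label; the module count strictly decreases per round, so
merging terminates.

The k-means refinement uses module eigengenes as centroids and
distance 1 − correlation. All assigned genes are reassigned to the
nearest centroid each iteration (current module kept on exact ties),
eigengenes recomputed, and iteration stops when no gene moves or after
`max_iter` (default 30; convergence is typically < 10 iterations on
synthetic data). Unassigned genes never participate — capture of grey
genes is left to the tree cut's attachment stage. Because the
eigengene-centroid update does not mathematically guarantee descent of
the summed 1 − correlation objective, an iteration that would increase
it is rolled back and iteration stops; the objective is thus
non-increasing by construction, which is asserted.

### Module preservation

Seven statistics compare a discovery module against the same genes in
the test cohort: avg_weight (mean off-diagonal test adjacency),
coherence (mean squared node contribution in the test data, where a
node's contribution is its correlation with the module eigengene),
cor_cor / cor_degree / cor_contrib (Pearson concordance of the paired
correlation vectors, intramodular degrees, and node contributions
between cohorts), and avg_cor / avg_contrib (test-side means
sign-adjusted by the discovery side). Node contributions are derived
from the leading eigenpair of the module correlation submatrix
(contribution = sqrt(λ)·v, eigengene oriented to positive mean
contribution), which equals the SVD definition and is unit-tested
against a direct SVD oracle.

The permutation null draws random module-sized subsets of the shared
gene universe (the module's own genes included) and scores each draw
with the same seven formulas — crucially, the discovery-side
quantities of a null draw come from the draw itself, so the null
captures "how preserved does a random gene set look", and the observed
module is exchangeable with the null draws when it is itself a random
set (which is what makes the null calibration test exact). Under the
"less" alternative, p = (#{null ≤ observed} + 1)/(n_perm + 1) per
statistic, with floor 1/(n_perm+1); a NaN statistic (degenerate
Pearson input) reports p = 1 with a warning. A module is non-preserved
iff all seven p < alpha (default 0.05, 10,000 permutations). Table
exports report all seven p-values plus their maximum, the maximum
being the table's single summary column; small p-values are printed in
scientific notation truncated (not rounded) to three significant
figures, so the floor at 10,000 permutations prints as 9.99E-5.

### Hub detection

Five scores per gene of a module: module membership (correlation with
the eigengene), betweenness (Brandes, unnormalized), closeness
(1/Σ dist, unnormalized, per connected component when the graph is
disconnected), PageRank (damping 0.85, weights as strengths; sums to 1
over the module) and Kleinberg's hub score (principal eigenvector of
the weight matrix, scaled to maximum 1). For the path-based metrics
the default `weight_as_cost` mode feeds adjacency values directly as
edge costs — replicating the behaviour of common graph libraries when
an adjacency is passed as "weights" with default settings, which is
what the underlying protocol did — so genes with strong connections
get *cheap* paths through them under `weight_as_strength`
(cost = 1/weight, also available) but *expensive* ones under the
default; the mode is recorded in the score table's notes. Edges of
weight 0 are absent.

Significance: the gene labels of the module adjacency are uniformly
permuted n_perm (default 1000) times, each gene's score re-read at its
label's new position, and p = #(permuted > observed)/n_perm — strict
inequality, no add-one term, so a gene holding the unique maximum gets
p = 0 (reported as "< 1/n_perm" in formatted output, stored as 0).
Since relabelling conjugates the adjacency, the permuted multiset
equals the observed scores and p converges to the within-module rank
fraction — verified by full enumeration of all relabellings on small
modules. A consequence worth noting: at alpha 0.01 a gene must sit in
the top 1% of at least one score, so modules need ≥ 100 genes for any
hub beyond the single top-ranked gene per score to reach significance.
All-tied score columns (complete equal-weight graphs) give p = 0
everywhere and emit a warning.

### Annotation statistics

Over-representation uses the one-sided hypergeometric upper tail with
a user-declared background (default: all genes surviving
preprocessing); each set is intersected with the background first and
the overlap is reported as "k/K" with K the in-background set size.
Raw p-values are reported with an optional Benjamini–Hochberg column,
but nominal thresholds (0.05 for gene sets, 0.01 for TF-style
libraries) remain the significance defaults, matching the underlying
protocol; the threshold used is echoed in the report. The 2×2 Fisher
test uses the probability-mass two-sided definition with a
conditional-MLE odds ratio and exact-test-inversion 95% CI. GWAS
enrichment contrasts non-preserved modules against everything else;
unassigned genes count in the preserved stratum by default (flag
available). The SNP→miRNA join applies both eQTL filters strictly
(p < 1e-4, frequency > 0.10) and intersects miRNAs with the disease
list; thresholds (∞, 0) reproduce the unfiltered join.

### Pipeline

A single master seed fans out to per-stage child seeds by hashing the
stage name, so any stage can be re-run in isolation and full runs are
bit-for-bit reproducible. The preservation test runs in both
directions by default, each cohort's network at its own chosen power.
Graph exports at an adjacency cutoff count total pairs as n(n+1)/2
(upper triangle including the diagonal) and state the convention in
the summary line, since published pair counts mix this convention with
the ordered-pair count n².

## Synthetic data: what it emulates and what it does not

The generator plants latent-factor modules: gene i of module m is
w_i·u_m + ε with u_m ~ N(0,1) per sample, ε ~ N(0, noise_sd²), w_i
uniform on `loading_range` (designated hubs get `hub_loading`), and
background genes pure noise. Within a module the population
correlation is w_i w_j/√((w_i²+σ²)(w_j²+σ²)). Latent factors are drawn
independently per cohort even for preserved modules — preservation is
a property of correlation structure, not of sample values. A
non-preserved module has its cohort-B loadings zeroed; a
`destroy_fraction` < 1 zeroes only a random subset of loadings, giving
a harder partial-perturbation regime (a loading *shuffle* within the
module would leave its correlation structure intact, which is why
graded zeroing is the perturbation primitive). Values are stored
unstandardized; consumers standardize internally.

Defaults are one frozen study condition: 600 genes, module sizes
(220, 60, 50, 130), 150 samples per cohort, loadings 0.5–0.8, hub
loading 1.0, noise sd 0.5, the last module non-preserved. Two of these
deserve explanation. First, the skewed sizes with a dominant backbone
module deliberately mimic the heavy-tailed module-size distributions
of real co-expression networks and the dominant global co-expression
component (e.g. cell-type composition in whole blood) that makes *any*
random gene subset of real data carry shared correlation structure
across cohorts. This matters statistically: the concordance statistics
of a completely destroyed module sit near zero, and they only fall in
the *lower tail* of the permutation null if typical random draws score
clearly positive — which requires that shared backbone. With four
equal small modules in a mostly-noise universe, the all-seven rule
cannot fire on a destroyed module at any sample size; that regime is a
limitation of unstructured simulations, not of the test. Second, the
non-preserved module has ≥ 100 genes and its hub loading is well
separated from the loading range, because hub significance at
alpha 0.01 is a top-1% rank statement (see above) and a hub whose
population module membership is within sampling noise of the best
regular gene cannot stably hold that rank at 150 samples.

The generator does not emulate probe-level artifacts, batch effects,
age/sex covariates, heavy-tailed expression noise, overlapping
modules, or scale-free connectivity — notably, the planted-block
networks are *not* scale-free, so the 0.85 scale-free criterion
selects unusually high powers (14–19) on synthetic data. The
simulation protocol therefore fixes the conventional unsigned default
power β = 6; the scan rule remains the pipeline default for real data.
Passing tests on these simulations demonstrate correctness of the
machinery and calibration of the permutation tests, not performance on
real microarray data.

## Numerical choices and degenerate inputs

- Probe collapse MAD is unscaled (no 1.4826 constant — it cannot
  change the argmax); ties break to the lexicographically smallest
  probe ID. The low-expression filter removes floor(fraction·n) genes
  (conservative rounding), ties at the cut removed smallest-ID-first.
- Exactly constant genes (detected by zero range, robust to
  floating-point means) are zero-correlation in networks and dropped
  from eigengenes.
- Average linkage runs on condensed 1 − TOM; scipy's deterministic
  tie-handling makes dendrograms reproducible.
- p-value floors: preservation (s+1)/(n+1) ∈ [1/(n+1), 1]; hub
  p = s/n ∈ [0, 1]. These are different estimators by design, each
  matching its protocol.
- All randomness flows through numpy Generators seeded explicitly;
  derived child seeds stay below 2^31.

## Problem sizes

Validation simulations use 600-gene universes with 150 samples per
cohort, 1,000 preservation permutations and 1,000 hub permutations for
planted-truth recovery (10 seeds), and 200 random-subset modules at
200 permutations for null calibration — sizes chosen so the full suite
and the reproduction script each run in minutes on a single CPU while
leaving the permutation estimators enough resolution for the 0.05 and
0.01 thresholds they feed.

## Known limitations

- The hybrid tree cut omits the reference method's PAM stage and its
  extended parameter surface; only `deep_split` and `min_module_size`
  are exposed.
- Signed TOM, biweight midcorrelation, Spearman options and block-wise
  construction for very large gene universes are out of scope.
- The preservation test's null recomputes both sides per draw (see
  above); with modules approaching the universe size the null
  degenerates and p-values lose resolution.
- Betweenness on dense weighted modules is O(n·m + n² log n) per
  source via networkx and becomes the bottleneck above ~1,000-gene
  modules.
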