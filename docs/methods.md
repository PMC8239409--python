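# Methods

This note documents the models and procedures `wpcna` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that make the pipeline
deterministic.

## Quantification

The pipeline starts from a peptide table (linear intensities, one row per
peptide × charge × modification variant). Raw spectral processing —
peak detection, database search, FDR control — is upstream and out of
scope.

* **Consolidation** sums a peptide's charge-state (2+…7+) and modification
  variants per sample (total-ion-current logic); a consolidated cell is
  missing only when every variant is missing. Summation is the natural
  choice because variants partition the same analyte's signal; it also
  makes consolidation exactly invertible in the synthetic round-trip test.
* **Protein inference** is parsimonious: a protein whose peptide set is
  contained in another's is redundant and dropped (equal sets keep the
  lexicographically smaller accession, for determinism); peptides still
  shared between retained proteins are discarded; proteins with fewer than
  two unique peptides are dropped. The order matters — containment is
  assessed before shared-peptide removal, otherwise the subset relation
  that defines redundancy would be destroyed by the very peptides that
  witness it.
* **Hi3**: per protein, the up-to-three peptides with the highest mean
  intensity across samples (mean over present cells, so a peptide censored
  in a few samples is not penalized; ties broken lexicographically), then
  per sample the mean of the selected peptides' present values,
  log2-transformed. The mean (rather than the sum) of the top peptides is
  the standard Top3 estimator; `agg="sum"` is available.

## Normalization

Both schemes are purely additive per sample on the log2 scale, so
within-sample differences between proteins are preserved exactly.

* **In vitro (treatment/control)**: the reference set is the proteins
  observed in *every* control sample; each control is shifted so its median
  over this set equals the median of the controls' medians. Then, for each
  (compound, dose, timepoint) group, the common set is the proteins present
  in all of the group's samples and all same-timepoint normalized controls;
  each treated sample is shifted to the median of those controls' medians
  over the common set. "Every treatment" is resolved as each
  (compound, dose) pair — the grain that matches having ~3 control
  replicates per timepoint as the normalization anchor.
* **Biopsy**: the core set is the proteins present in all samples; every
  sample is shifted so its core-set median equals the median of per-sample
  medians (chosen over a grand pooled median for symmetry with the in
  vitro scheme).
* The median of an even-length vector is the mean of the two central
  values; rounding to 6 decimals is half-to-even for cross-platform
  bit-stability. Empty reference/common/core sets are hard errors naming
  the offending group.

## Network construction and module detection

* **Adjacency**: signed, a_ij = ((1 + cor(x_i, x_j))/2)^β with Pearson
  correlation over pairwise-complete samples (the matrices retain up to 50%
  missingness). Pairs with fewer than 3 shared samples get correlation 0
  (adjacency 0.5^β). Defaults β = 2 for the time-course design and β = 5
  for biopsy-like data, following the scale-free-fit diagnostics the
  package also computes (R² of the log-log regression of connectivity-bin
  frequency on bin-mean connectivity, 10 equal-width bins, empty bins
  dropped; the unsigned R² and the slope are reported separately).
* **TOM**: ω_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  l_ij = Σ_{u≠i,j} a_iu a_uj; clustering dissimilarity is 1 − ω, under
  average linkage.
* **Hybrid dynamic tree cut** (reimplemented from its published
  description): deepSplit ∈ 0..4 maps to a maximum core scatter of
  (0.64, 0.73, 0.82, 0.91, 0.95) and a minimum gap of
  (1 − maxCoreScatter)·3/4, both expressed on the span between the 5th
  percentile of merge heights and 0.99× the maximum height. A branch
  qualifies as a module candidate when it has ≥ minClusterSize members
  (default 30), its core scatter (mean of the lowest merge heights over a
  core of ~minClusterSize/2 + √size members) is below the ceiling, and the
  gap between its attachment height and its core scatter exceeds the
  floor. The tree is split recursively wherever a child qualifies; final
  candidates below the size or scatter limits are dissolved. Dissolved and
  never-assigned proteins then pass through a medoid-style stage that
  ignores dendrogram position (`pam_respects_dendro = False`): a protein
  joins the module with the smallest average dissimilarity, but only if
  that average lies below the midpoint (`pam_slack = 0.5`) between the
  module's own mean intra-module dissimilarity and the matrix-wide mean
  dissimilarity; otherwise it stays grey. A flat admission radius at the
  static cut height — the laxest published variant — empirically absorbs
  members of dissolved sub-threshold modules into unrelated modules; the
  cluster-relative radius keeps them grey, which is the behavior the
  planted-truth benchmarks require. Exact numerical equivalence with any
  particular reference implementation is not claimed; recovery of planted
  structure is the contract, and over-split branches are re-united by the
  eigengene merge step below.
* **Eigengenes**: per module, proteins are mean-imputed (per protein),
  z-scored (n−1 denominator), and the first right-singular vector of the
  proteins × samples block is the eigengene (unit norm), with sign oriented
  to correlate non-negatively with the module's average standardized
  profile. Mean imputation is deterministic and avoids an imputation-model
  dependency; an all-missing protein is excluded with a warning. A module
  composed of two anti-correlated halves yields variance explained ≈ 1
  with near-zero mean kME — documented, inherent to PC1 summaries.
* **Merging**: modules whose eigengene dissimilarity 1 − cor falls below
  0.25 (average-linkage flat clusters, strict inequality) are merged into
  the largest member's label; eigengenes are recomputed and the step
  iterates (bounded by the initial module count). Colors are re-issued in
  decreasing size order (grey = unassigned) at the end.
* **kME / weighted proteins**: Pearson correlation between each protein and
  each eigengene over pairwise-complete samples (≥3 required, else
  undefined); a protein is *weighted* when its kME with its own module's
  eigengene is ≥ 0.8 (inclusive).

## Module selection, annotation, enrichment

The published analysis judged affected modules from eigengene bar plots and
PCA scatter by eye; to make the step deterministic and testable the package
uses a quantitative rule: a module is treatment-affected when the
standardized eigengene contrast |treated mean − control mean| / pooled SD
is ≥ 1.0, or the silhouette of treated-vs-control labels on the first two
principal components of the module submatrix is ≥ 0.25. Both thresholds are
config-exposed. Groups with fewer than 2 samples flag the pooled SD as
undefined.

ORA is the hypergeometric upper tail P[X ≥ k] for drawing |query| proteins
from the background with |pathway ∩ background| successes, BH-adjusted
across pathways; "passes" requires p < 0.01 and q < 0.01. The background
defaults to the post-filter protein universe of the analyzed dataset, not
the whole proteome. Disease annotation is plain set counting per module
(total, disease overlap, weighted, weighted ∩ disease).

## Integration and PPI

Integration is set algebra plus per-dataset statistics: proteins present in
both datasets; weighted in at least one (reported as a percentage of the
common set, 1 decimal) and in both; log2FC as difference of group means on
the log2 scale (same-timepoint controls for the time course; the
no-cancer patient group for biopsies), with a cell left empty — never
zero — when either group has no present value; and a high-expression
filter requiring every value present and strictly above log2 = 10.

The PPI network is the induced subgraph of a user-supplied edge list
(SIF or two-column TSV) on the query proteins — "non-adding", no neighbor
expansion — deduplicated, self-loops dropped. Orphans (degree 0) are
removed and counted; hubs are nodes with ≥ 30 unique neighbors (inclusive);
the disease percentage is reported both over the query set (2 decimals, the
published convention) and over the post-orphan node set. Interaction
provenance is deliberately an input file: the six-database union behind the
original network is a service-time artifact that cannot be version-pinned.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study with known truth:

* the factorial harvest design — 3 drugs × 2 doses × 7 timepoints ×
  n replicates plus controls, toxic idarubicin truncated at 168 h and
  reduced to 2 replicates at 2 h and 24 h (read as applying to the toxic
  dose, which makes the 139-sample total exact: 21 + 42 + 42 + 21 + 13);
  and a 16-biopsy 3-group design;
* planted modules: each module has a latent unit-variance per-sample
  template; protein p of module m is
  baseline_p + a_p·T_m + noise_sd·ε with a_p chosen so the expected
  correlation with the template equals a drawn target
  r_p ~ U(0.85, 0.97) — so every protein's true module membership is known
  exactly. Baselines are U(8, 14) log2 units, making the log2 > 10
  high-expression filter non-trivial. Treatment effects shift the template
  additively in configurable conditions (default: treated conditions at
  ≥ 72 h, sign alternating between modules; noise_sd default 0.5 log2
  units);
* peptides: log-normal response factors (σ = 0.5) on the linear scale, a
  configurable fraction split across charge/modification variants whose
  weights sum to one — so Hi3 on noise-free peptides recovers the planted
  log2 profile up to a per-protein constant, to 1e-9;
* missingness: exactly-calibrated overall rate; the intensity-dependent
  mode (default — realistic for label-free LC-MS) censors by exponentially
  rank-weighted sampling without replacement; MCAR is retained for clean
  statistical tests;
* a PPI graph with planted hubs (degree ≥ 30 forced) over an
  Erdős–Rényi background with mean degree ~Poisson(3), and a disease set
  overlapping chosen modules.

It does **not** emulate retention times or raw spectra, peptide-level
biological variation independent of the parent protein, batch effects
beyond per-sample shifts, correlated missingness across samples, or
scale-free network topology per se. Passing the planted-structure
benchmarks therefore demonstrates correctness of the algorithms under the
stated generative assumptions, not performance on any particular real
dataset.

## Benchmark problem sizes

The evaluation studies in `wpcna.benchmarks` use sizes chosen to run in
seconds while keeping each detectable module above the floor imposed by the
missingness filter (intensity-dependent censoring concentrates on
low-baseline proteins and removes whole proteins, shrinking planted modules
by roughly 15–25%):

* *module recovery*: 6 planted modules (60, 45, 35, 25, 20, 10), 47-sample
  design, 20% missingness, 5 seeds. The three modules below
  minClusterSize = 30 are dissolved to grey by construction, which caps the
  attainable adjusted Rand index near 0.86; observed ARI is ≈ 0.85 on
  average (reported as mean and min over the 5 seeds) with weighted-protein
  recall (planted r ≥ 0.9, recovered modules) ≥ 0.9.
* *selection*: 3 planted modules of 50 among 150 background proteins on the
  full 139-sample design; one module shifted by 2 log2 template units in
  all treated conditions. A module that is a minority of the matrix is
  essential here: the median-shift normalization partially re-absorbs a
  shift planted in a large fraction of the proteome, and 2 units is a
  clearly-affected module rather than a borderline one. 20 seeds each for
  the shifted and the null configuration.
* *hub calling*: 242 nodes, 4 planted hubs of degree ≥ 30, Poisson(3)
  background — at which the probability of a background node reaching
  degree 30 is negligible, so exact hub recovery is the correct
  expectation.

## Known limitations

* The dynamic tree cut is a faithful re-implementation of the published
  *criteria*, not a line-by-line port; branch-by-branch agreement with the
  R reference on arbitrary data is not guaranteed (module-level agreement
  on separated structure is tested).
* Pairwise-complete correlations are not jointly positive semi-definite;
  TOM values are clipped only by construction, not re-projected.
* The biopsy normalization's "common median" is the median of per-sample
  medians; a grand pooled median is a defensible alternative the package
  does not currently offer.
* Cross-dataset integration performs no batch harmonization, by design.
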