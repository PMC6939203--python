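# Methods

This note documents the models, parameters and numerical choices behind
`thymod`, in the order data flows through the pipeline.

## The scientific question

Medullary thymic epithelial cells (mTEC) collectively express most of the
protein-coding genome, including tissue-restricted genes (TRGs) whose
ectopic expression drives central tolerance. Each cell, however, detects
only a small fraction of TRGs at a time. Two readouts distinguish ordered
from stochastic expression: (i) whether genes fall into reproducible
co-expression modules across cells, random subsamples and mice, and
(ii) whether marker-positive cells occupy random positions within the
medulla. The package implements both, plus the supporting QC, clustering
and composition statistics, and a synthetic-data generator that makes all
of it testable against known ground truth.

## Synthetic data generator

The generator emulates the statistical shape of a sorted-mTEC single-cell
experiment, not its biology in detail. The model is hierarchical:

- Every cell belongs to one of `n_cell_clusters` subpopulations; every
  gene either belongs to one of `n_modules` planted co-expression modules
  or to an unstructured background.
- A boolean clusters × modules activity matrix switches each module "on"
  in exactly two clusters. This emulates context-specific programmes that
  prefer particular satellite subpopulations; clusters with no active
  module mimic immature subpopulations with little TRG expression. Rows
  are resampled until all cluster profiles are distinct, so subpopulations
  are identifiable in principle.
- A gene of an on-module is detected with `active_detect_prob` (default
  0.25), all other genes with `baseline_detect_prob` (default 0.02) — the
  latter matches the observation that a single cell detects only a few
  percent of TRGs. Setting the two probabilities equal produces the
  structureless null used by calibration tests.
- Sorted conditions couple to marker modules: TSPAN8⁺ (GP2⁺) cells have
  module 1 (2) forced on regardless of cluster, mirroring sorted
  subpopulations carrying their marker programme.
- Per-cell library size: detection probabilities are multiplied by a
  log-normal factor (`depth_sigma` = 0.7, i.e. CV ≈ 0.8, typical of
  droplet libraries; clipped at 0.95). Without this the MAD quality
  filters interact pathologically with the generator's discrete
  biological depth modes — the filters presuppose continuously dispersed
  library sizes, and the chosen sigma is the smallest round value for
  which re-filtering already-filtered data removes < 5% more cells.
- A detected entry draws its UMI count as `1 + NegBin(mean − 1, θ)`
  (defaults: mean 2.0, θ = 1.0). The shift makes the realised detection
  probability exactly the configured one; a plain negative binomial would
  silently deflate detection through its zero mass.
- Gene chromosome and position labels are uniform over 19 chromosomes of
  100 Mb, and TRG category labels (30% of genes) are independent of module
  membership — deliberately structureless, so the genomic composition
  statistics have a true null on default data.

Defaults (2,000 genes; 600 cells in each of the five sort conditions; 4
mice; 8 clusters; 5 modules of 80–120 genes) are the study conditions used
throughout the tests. What the generator does **not** emulate: ambient
RNA, doublets, batch-specific gene effects beyond per-mouse detection
jitter, mean–variance trends across genes, or read-level noise. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under a faithful sparsity/depth regime, not performance on the
full messiness of real tissue data.

Synthetic images contain a medulla channel (union of elliptical blobs,
lightly blurred) and a marker channel (Gaussian spots of width
`spot_radius` = 3 px at points drawn inside the mask, plus optional
noise). Defaults are 512 × 512 px with 50 points: at this scale the spot
footprint is small relative to typical nearest-neighbour distances, so the
point pattern survives detection. The three point processes are uniform
sampling (random), sequential inhibition with radius 0.7/√(n/area)
(even), and a parent–offspring process with 5 parents and offspring spread
5% of the mask diagonal (clustered).

## Quality control and normalisation

Cells are removed when their total counts or detected features fall more
than one median absolute deviation (MAD) below the batch median, or their
mitochondrial fraction rises more than three MADs above it. MADs use the
1.4826 normal-consistency constant (configurable); thresholds are computed
per batch by default (pooled via a flag), and batches under 10 cells pass
through unfiltered with a warning. Filters act on raw totals, not log
scale. Surviving cells are scaled so each total equals the median
pre-normalisation total — a transparent size-factor choice that conserves
within-cell proportions exactly.

Batch correction is a pluggable embedding contract: the built-in default
is PCA of log₂(1 + C) followed by per-batch mean-centring in PC space, and
an externally computed corrected embedding (e.g. a mutual-nearest-
neighbours correction run elsewhere) is accepted wherever an embedding is
consumed. Only graph construction consumes the corrected embedding; the
GF-ICF transform operates on the uncorrected normalised matrix, which is
what the transform is defined on.

## Cell clustering and condition enrichment

The SNN graph joins cells sharing members of their k-nearest-neighbour
sets (k = 10, 50 PCs by default), with Jaccard edge weights, and is
partitioned by Louvain modularity maximisation (resolution 1; seeded).
Recursive sub-clustering of one community is available for heterogeneous
satellite clusters. Condition enrichment per cluster is tested per mouse:
the proportion of a mouse's sorted cells in the cluster is paired with the
proportion of its unselected cells there (the expectation absent sorting
effects), and the paired differences across mice enter a two-sided
Wilcoxon signed-rank test (exact null for ≤ 25 mice). With fewer than two
informative mice, or all differences zero, the result is flagged
untestable rather than given a p-value. The pairing of observed sorted
proportions against unselected proportions is this package's
operationalisation of "expected from the unselected cells"; other
constructions are possible.

## Gene module discovery (GF-ICF)

The transform is computed exactly as stated in the README, with these
numerical choices:

- **Pseudocount.** G_f = log₂(1 + C): the bare logarithm is undefined at
  the (dominant) zero entries; the pseudocount is the minimal repair and
  preserves sparsity.
- **Sub-unit ICF guard.** When Σ_y W_y·N_y/(1 + E) < 1 (a gene detected
  in nearly every cell under sub-unit weights) the logarithm is negative,
  which would invert the transform's intent; such entries are clamped to
  0 and flagged. `clamp_negative=False` keeps raw values.
- **Weights.** The five condition weights default to the population
  shares above and intentionally do not sum to one; `renormalise=True`
  divides by the sum. Conditions with no cells are omitted from the sum.
- **Reduced-space distance.** Cosine distances are computed on U·Σ — the
  rank-50 reconstruction of each gene's GF_ICF row — rather than on the
  unweighted left singular vectors. When the data's effective rank falls
  short of the component count (always the case at desk scale, where the
  planted structure spans ~n_modules + 1 directions), unweighted cosine
  gives the remaining pure-noise components equal influence and erases
  the gene neighbourhood structure; the weighted form degrades
  gracefully and is identical in intent at full rank.
  `weight_by_singular_values=False` restores the unweighted form.
- **t-SNE.** Precomputed-distance mode, random init, perplexity 50
  (reduced automatically below 3·perplexity genes), 1,000 iterations,
  seeded.
- **Module validity.** HDBSCAN (min_cluster_size 20) labels dense map
  regions; genes outside them are noise with membership probability 0. A
  candidate cluster must additionally be internally coherent: clusters
  whose median within-cluster cosine distance exceeds 0.9× the global
  median pairwise distance are returned to noise. The filter exists
  because a large population of mutually unrelated background genes can
  occupy a contiguous region of the map that HDBSCAN bistably reports
  either as noise or as one giant cluster; a co-expression module must be
  tighter than background, and the 0.9 threshold sits far from both the
  observed module ratios (≈ 0.4–0.7) and the background ratio (≈ 1.0).

### Robustness by subsampling

`robustness` re-runs the entire chain (including recomputation of N_y and
E_{y,x}) on random subsets of cells (default fraction 0.8 without
replacement; the 100-subset default mirrors common practice, tests use
2–4 subsets for runtime) and scores all pairwise AMIs. The chain seed is
shared across subsets, so identical subsets give identical partitions and
AMI exactly 1. AMI uses the permutation-model expected MI and the
arithmetic mean of entropies; noise is mapped to a dedicated cluster
first, so agreement about unassignable genes counts as agreement. One
degenerate case is defined explicitly: two partitions that assigned *no*
gene to any module return AMI 0, not the identical-constant-labelling
value 1 — the statistic measures reproducibility of discovered structure,
and rewarding the discovery of nothing would make the structureless null
score perfectly "robust".

## Module composition statistics

All composition tests share one Monte Carlo null: modules of matched size
resampled uniformly without replacement from the clustered gene universe
(assigned or noise). Empirical p-values use the add-one rule
(1 + #{null ≥ obs})/(n_perm + 1), so they are never zero; two-sided
values double the smaller one-sided tail and cap at 1;
Benjamini–Hochberg adjustment is applied across the tested family
(Bonferroni via flag). Chromosome preference is one-sided (enrichment)
per module × chromosome cell, flagged at adjusted p < 0.01. Genomic
distances are |start_i − start_j| between same-chromosome gene starts
(1-based coordinates), compared between subsets by two-sample
Kolmogorov–Smirnov. The default 10,000 permutations reproduce exact
hypergeometric tails to within Monte Carlo error in the single-category
case.

## Cross-mouse co-expression

f(Gˣ,Gʸ) is the fraction of a mouse's cells detecting both genes
(detection = raw count ≥ 1, matching the detection semantics used for
E_{y,x}). Pairs with zero frequency in every mouse are dropped before
correlating (they carry no signal and shrink r toward an arbitrary
value); mouse pairs with a zero-variance vector are excluded with a
warning. Mouse-versus-pooled correlations are reported separately from
mouse-pair correlations, and the quadratic pair set can be capped by a
seeded uniform subsample (`max_pairs`). A cluster-restricted variant
recomputes frequencies on a chosen cell-cluster subset, the analogue of
restricting to mature AIRE⁺ cells.

## Spatial analysis

Medulla segmentation: Gaussian blur (σ = 4 px at 512², scale with image),
Otsu threshold (manual override available), erosion then dilation
(radius 3), small components removed. Positive cells: blur, threshold,
watershed seeded from local maxima, intensity-weighted centroid moments;
features below `min_area` are discarded and centroids outside the medulla
dropped.

G(r) is the empirical CDF of nearest-neighbour distances. No analytic
edge correction is applied; instead all reference patterns are simulated
inside the observed mask, which cancels edge and mask-shape effects from
the comparison. Because spot segmentation merges close pairs below the
blur resolution (~2·√(spot σ² + blur σ²) px), the reference simulations
can be pushed through the same observation process: either rendering and
re-segmenting every simulated pattern (`DetectionModel`, exact) or a
cheap close-pair merge at the resolution scale (`merge_radius`); in both
modes the simulated point count is inflated so the post-detection count
matches the observation on average.

Classification uses a calibrated maximum-deviation (MAD-type) rank test
against the random reference ensemble: the upward and downward deviation
maxima of the observed G from the simulated mean are ranked among the
simulations' own deviations, giving one-sided Monte Carlo p-values at
α = 0.05 split across tails. Upward-only significance means an excess of
short nearest-neighbour distances (clustered); downward-only a deficit
(even); neither, random; both, indeterminate. Pointwise 2.5/97.5%
envelope bands (≥ 99 simulations) are computed for description and
plotting, but a rule that rejects whenever the observed curve exits a
pointwise band mislabels a large fraction of genuinely random patterns —
the ~50 correlated grid points give many chances for a chance excursion —
so the rank test is the inferential rule.

## Problem sizes and runtime

The test-suite runs the full module-recovery chain at 2,000 genes × 3,000
cells (5 seeds), robustness at the same scale with 2–4 subsets, Monte
Carlo calibration with 500 null replicates × 400 permutations, and 100
end-to-end spatial trials at 512 × 512 px with 99-simulation references.
These sizes were chosen so the whole suite completes in minutes on one
CPU while leaving every statistical check adequately powered.

## Known limitations

- The coherence filter assumes background genes vastly outnumber any
  single module's periphery; data in which genuine modules are barely
  tighter than background would need a lower threshold.
- The Wilcoxon pairing for condition enrichment is an interpretation of
  "expected from unselected cells", not a uniquely determined construction.
- The spatial classifier tests only against the random reference;
  patterns that are simultaneously clustered at one scale and inhibited
  at another come back indeterminate.
- `correct_batches` is linear; strongly non-linear batch effects should
  be corrected externally and supplied as an embedding.
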