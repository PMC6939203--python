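# thymod

Order statistics for promiscuous gene expression in medullary thymic
epithelial cells (mTEC).

Single mTEC collectively express most protein-coding genes — including
thousands of tissue-restricted genes (TRGs) — to enforce central immune
tolerance, yet each cell detects only a few percent of TRGs at a time. Is
that sampling stochastic, or does each cell run ordered co-expression
programmes? `thymod` implements the computational machinery for answering
this on sorted single-cell RNA-seq panels (TSPAN8⁺/⁻, GP2⁺/⁻, unselected
mTEC across several mice) and on immunofluorescence images of thymic
sections, and ships a synthetic-data generator with planted ground truth so
every stage is testable end to end.

## The core transform

Gene modules are discovered with a TF-IDF adaptation for sparse UMI counts
that up-weights rarely detected genes. On the normalised gene-by-cell
matrix **C**:

- gene frequency:  G_f = log₂(1 + C), restricted to genes detected in ≥ 2 cells;
- inverse cell frequency, a weighted average over the five sort
  conditions *y* of each gene's inverse detection frequency (a gene
  detected in 25% of a condition's cells has inverse cell frequency 4):

  ICF_x = log₁₀( Σ_y W_y · N_y / (1 + E_{y,x}) )

  with W = {TSPAN8⁺ 0.07, TSPAN8⁻ 0.93, GP2⁺ 0.02, GP2⁻ 0.98,
  unselected 1.00} (each condition's expected share of the total mTEC
  population), N_y the condition's cell count and E_{y,x} its count of
  cells expressing gene *x*;
- GF_ICF = G_f · ICF (each gene row scaled by its ICF).

Genes are embedded by truncated SVD (50 components), pairwise cosine
distance in the reduced space, and 2-D t-SNE; HDBSCAN density clustering of
the map yields mutually exclusive gene modules **GM** with membership
probabilities (unassignable genes are noise). Partition stability is scored
by re-running the whole chain on random cell subsets and computing pairwise
adjusted mutual information (AMI), with noise kept as its own cluster.

Around the core transform the package provides MAD-based cell QC and
median-library normalisation, SNN-graph + Louvain cell clustering with
per-mouse Wilcoxon condition-enrichment tests, Monte Carlo module
composition statistics (TRG/gene-set enrichment, chromosome preference,
genomic-distance ECDFs with KS comparisons), cross-mouse co-expression
reproducibility f(Gˣ,Gʸ), and spatial analysis of marker-positive cells —
segmentation, the nearest-neighbour G-function G(r) inside the medullary
mask, and an envelope/rank test against even, random and clustered
reference processes.

## Worked example

```bash
python examples/discover_gene_modules.py
```

```
genes entering the transform: 2000 (detected in >= 2 cells)
modules found: 5; genes assigned: 510; noise: 1490
AMI against planted truth: 0.969
```

The synthetic panel plants 5 co-expression modules of 80–120 genes in a
2,000-gene × 3,000-cell experiment; the transform-and-cluster chain finds
exactly those 5 modules, assigns 510 genes to them, declares the 1,490
unstructured background genes noise, and agrees with the planted truth at
AMI 0.97 (1.0 would be a perfect match; independent partitions score ≈ 0).

Other examples, one per capability, live in `examples/`: synthetic data +
QC, cell clustering with condition enrichment, module composition
statistics, cross-mouse co-expression reproducibility, and spatial pattern
classification. Each prints the numbers it computes and a line on what
they mean.

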