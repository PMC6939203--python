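"""Recover planted gene co-expression modules with the weighted GF-ICF chain.

Runs the full transform (log2 gene frequency x condition-weighted inverse
cell frequency), embeds genes by SVD + cosine distance + t-SNE, clusters
the map with HDBSCAN, and scores the recovered partition against the
planted truth with adjusted mutual information (noise kept as a cluster).
"""

from thymod import (
    SimConfig,
    adjusted_mutual_information,
    discover_modules,
    filter_cells,
    generate_counts,
    normalise,
    partition_on_universe,
)

config = SimConfig(seed=1)
counts, truth = generate_counts(config)
norm = normalise(filter_cells(counts)[0])

result = discover_modules(norm, seed=0)
part = result.partition
recovered = partition_on_universe(part, norm.n_genes)
ami = adjusted_mutual_information(recovered, truth.gene_module_labels)

print(f"genes entering the transform: {len(part.labels)} "
      f"(detected in >= 2 cells)")
print(f"modules found: {part.n_modules}; "
      f"genes assigned: {(part.labels > 0).sum()}; "
      f"noise: {(part.labels < 0).sum()}")
print(f"AMI against planted truth: {ami:.3f}")
# An AMI near 1 means the density clusters on the 2-D gene map coincide
# with the planted co-expression programmes; the planted truth has 5
# modules of 80-120 genes against a 1,500-gene unstructured background.
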