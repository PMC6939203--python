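"""Cross-mouse reproducibility of pairwise TRG co-expression frequencies.

For every pair of module genes, computes the fraction of each mouse's
cells detecting both genes, then correlates those frequency vectors
between mice. A panel of mice sharing the planted module structure should
correlate strongly; a negative-control panel whose gene-module assignment
is reshuffled independently per mouse should not.
"""

from thymod import (
    SimConfig,
    coexpression_frequencies,
    cross_mouse_correlation,
    generate_mouse_panel,
)

config = SimConfig(seed=8)

for label, permute in (("shared structure", False), ("shuffled control", True)):
    counts, truth = generate_mouse_panel(
        config, permute_modules_per_mouse=permute
    )
    genes = counts.gene_ids[truth.gene_module_labels > 0]
    freqs = coexpression_frequencies(counts, genes, max_pairs=4000, seed=0)
    summary = cross_mouse_correlation(freqs)
    print(f"{label}: mean Pearson r across mouse pairs = {summary.mean_r:.3f} "
          f"(incl. mouse-vs-pooled: {summary.mean_r_including_pooled:.3f})")
# High r for the shared panel and near-zero r for the control shows the
# correlation reflects reproducible module structure, not depth artefacts.
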