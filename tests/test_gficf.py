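"""The weighted GF-ICF transform, gene embedding, module clustering, AMI."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from thymod import (
    CONDITIONS,
    CountMatrix,
    DEFAULT_CONDITION_WEIGHTS,
    IcfWeights,
    adjusted_mutual_information,
    cluster_genes,
    compute_icf_weights,
    discover_modules,
    embed_genes,
    gene_frequency,
    gf_icf,
    inverse_cell_frequency,
    partition_on_universe,
    per_condition_inverse_frequency,
    robustness,
)
from thymod.gficf import NOISE_LABEL


def _matrix(counts, conditions):
    counts = np.asarray(counts, dtype=float)
    n_genes, n_cells = counts.shape
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chromosome": np.ones(n_genes, int),
            "position_bp": np.arange(1, n_genes + 1),
            "category": ["other"] * n_genes,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "mouse_id": ["m0"] * n_cells,
            "condition": conditions,
        }
    )
    return CountMatrix(sp.csr_matrix(counts), genes, cells)


# ---------------------------------------------------------------------------
# Gene frequency
# ---------------------------------------------------------------------------

def test_gene_frequency_log2_with_pseudocount():
    cm = _matrix([[0, 1, 3], [1, 1, 1]], ["unselected"] * 3)
    gf, keep = gene_frequency(cm)
    dense = gf.toarray()
    assert dense[0, 0] == 0.0
    assert dense[0, 1] == pytest.approx(1.0)
    assert dense[0, 2] == pytest.approx(2.0)


def test_gene_detected_in_single_cell_is_dropped():
    cm = _matrix([[0, 0, 5], [1, 2, 3]], ["unselected"] * 3)
    gf, keep = gene_frequency(cm)
    assert list(keep) == [1]


# ---------------------------------------------------------------------------
# Inverse cell frequency
# ---------------------------------------------------------------------------

def test_quarter_detection_gives_inverse_frequency_four():
    assert per_condition_inverse_frequency(400, 100) == pytest.approx(4.0)
    # regularised variant approaches the same value for large subsets
    assert per_condition_inverse_frequency(4000, 1000, regularised=True) == pytest.approx(
        4.0, rel=1e-3
    )


def test_ubiquitous_gene_icf_approaches_log10_of_weight_sum():
    n = 1_000_000
    E = np.full((1, 5), n)
    W = dict(DEFAULT_CONDITION_WEIGHTS)
    weights = IcfWeights(W=W, N={c: n for c in CONDITIONS}, E=E, conditions=CONDITIONS)
    icf, clamped = inverse_cell_frequency(weights)
    assert icf[0] == pytest.approx(np.log10(3.0), abs=1e-3)
    assert not clamped[0]


def test_single_condition_undetected_gene():
    weights = IcfWeights(
        W={"unselected": 1.0}, N={"unselected": 99}, E=np.array([[0]]),
        conditions=("unselected",),
    )
    icf, _ = inverse_cell_frequency(weights)
    assert icf[0] == pytest.approx(np.log10(99))


def test_conditions_without_cells_are_omitted():
    weights = IcfWeights(
        W={"GP2+": 0.02, "unselected": 1.0},
        N={"GP2+": 0, "unselected": 10},
        E=np.array([[0, 4]]),
        conditions=("GP2+", "unselected"),
    )
    icf, _ = inverse_cell_frequency(weights)
    assert icf[0] == pytest.approx(np.log10(10 / 5))


def test_subunit_sum_is_clamped_and_flagged():
    # nearly every cell expresses the gene and the only condition has a
    # sub-unit weight, so the weighted sum falls below 1
    weights = IcfWeights(
        W={"TSPAN8+": 0.07}, N={"TSPAN8+": 10}, E=np.array([[9]]),
        conditions=("TSPAN8+",),
    )
    icf, clamped = inverse_cell_frequency(weights)
    assert clamped[0]
    assert icf[0] == 0.0
    raw, _ = inverse_cell_frequency(weights, clamp_negative=False)
    assert raw[0] < 0


def test_rare_gene_outscores_common_gene():
    """The TF-IDF intent: detection in 5% of cells beats detection in 80%."""
    n = 200
    E = np.array([[int(0.05 * n)] * 5, [int(0.80 * n)] * 5])
    weights = IcfWeights(
        W=dict(DEFAULT_CONDITION_WEIGHTS), N={c: n for c in CONDITIONS},
        E=E, conditions=CONDITIONS,
    )
    icf, _ = inverse_cell_frequency(weights)
    assert icf[0] > icf[1]


# ---------------------------------------------------------------------------
# GF-ICF product
# ---------------------------------------------------------------------------

def test_unit_icf_is_identity():
    gf = sp.csr_matrix(np.array([[1.0, 2.0], [0.0, 3.0]]))
    out = gf_icf(gf, np.ones(2))
    np.testing.assert_allclose(out.values.toarray(), gf.toarray())


def test_row_scaling_matches_elementwise_oracle(rng):
    gf = sp.csr_matrix(rng.random((3, 2)))
    icf = np.array([0.5, 2.0, 1.5])
    out = gf_icf(gf, icf)
    expected = gf.toarray() * icf[:, None]
    np.testing.assert_allclose(out.values.toarray(), expected, atol=1e-15)


def test_gene_set_mismatch_rejected():
    with pytest.raises(ValueError, match="gene sets differ"):
        gf_icf(sp.eye(3, format="csr"), np.ones(2))


def test_transform_chain_matches_naive_loops(rng):
    """gene_frequency / ICF / gf_icf agree with direct loop evaluation."""
    for _ in range(25):
        n_genes = rng.integers(3, 21)
        n_cells = rng.integers(4, 11)
        counts = rng.poisson(0.8, size=(n_genes, n_cells)).astype(float)
        conds = rng.choice(CONDITIONS, size=n_cells)
        cm = _matrix(counts, conds)
        gf, keep = gene_frequency(cm)
        # oracle: log2(1+c), genes detected in >= 2 cells
        keep_o = [g for g in range(n_genes) if (counts[g] > 0).sum() >= 2]
        assert list(keep) == keep_o
        for gi, g in enumerate(keep_o):
            for c in range(n_cells):
                assert gf[gi, c] == pytest.approx(np.log2(1 + counts[g, c]), abs=1e-12)
        weights = compute_icf_weights(cm, gene_index=keep)
        icf, _ = inverse_cell_frequency(weights, clamp_negative=False)
        for gi, g in enumerate(keep_o):
            total = 0.0
            for cond in CONDITIONS:
                sel = conds == cond
                if sel.sum() == 0:
                    continue
                e = (counts[g][sel] > 0).sum()
                total += DEFAULT_CONDITION_WEIGHTS[cond] * sel.sum() / (1 + e)
            assert icf[gi] == pytest.approx(np.log10(total), abs=1e-12)
        m = gf_icf(gf, np.abs(icf))
        for gi in range(len(keep_o)):
            for c in range(n_cells):
                assert m.values[gi, c] == pytest.approx(
                    gf[gi, c] * abs(icf[gi]), abs=1e-12
                )


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def test_rank_one_matrix_has_single_singular_value(rng):
    row = rng.random(30)
    M = np.outer(np.arange(1, 13, dtype=float), row)
    out = gf_icf(sp.csr_matrix(M), np.ones(12))
    emb = embed_genes(out, n_components=5, perplexity=3, seed=0, tsne_max_iter=250)
    d = emb.singular_values
    assert (d[1:] <= 1e-8 * d[0]).all()


def test_duplicated_gene_rows_have_zero_cosine_distance(rng):
    M = rng.random((10, 20))
    M[7] = M[2]
    out = gf_icf(sp.csr_matrix(M), np.ones(10))
    emb = embed_genes(out, n_components=5, perplexity=3, seed=0, tsne_max_iter=250)
    assert emb.cosine_distances[2, 7] == pytest.approx(0.0, abs=1e-9)


def test_orthogonal_gene_blocks_stay_separated(rng):
    block = np.zeros((40, 30))
    block[:20, :15] = rng.random((20, 15)) + 0.5
    block[20:, 15:] = rng.random((20, 15)) + 0.5
    out = gf_icf(sp.csr_matrix(block), np.ones(40))
    emb = embed_genes(out, n_components=4, perplexity=10, seed=0, tsne_max_iter=500)
    D = emb.cosine_distances
    within = (D[:20, :20].mean() + D[20:, 20:].mean()) / 2
    between = D[:20, 20:].mean()
    assert within < between
    Z = emb.coords2d
    from sklearn.metrics import silhouette_score

    labels = np.array([0] * 20 + [1] * 20)
    assert silhouette_score(Z, labels) > 0


def test_component_count_validated(rng):
    out = gf_icf(sp.csr_matrix(rng.random((5, 4))), np.ones(5))
    with pytest.raises(ValueError, match="n_components"):
        embed_genes(out, n_components=10)


# ---------------------------------------------------------------------------
# Density clustering
# ---------------------------------------------------------------------------

def test_five_planted_blobs_recovered(rng):
    centres = np.array([[0, 0], [50, 0], [0, 50], [50, 50], [25, 95]])
    Z = np.vstack([rng.normal(c, 1.0, size=(100, 2)) for c in centres])
    part = cluster_genes(Z, min_cluster_size=20)
    truth = np.repeat(np.arange(5), 100)
    assert part.n_modules == 5
    assert adjusted_mutual_information(part.labels, truth) >= 0.9


def test_sparse_uniform_scatter_is_mostly_noise(rng):
    Z = rng.uniform(0, 1000, size=(150, 2))
    part = cluster_genes(Z, min_cluster_size=20)
    assert (part.labels == NOISE_LABEL).mean() > 0.5
    assert (part.probabilities[part.labels == NOISE_LABEL] == 0).all()


def test_blob_centre_probability_at_least_peripheral(rng):
    centre = np.array([10.0, 10.0])
    cloud = rng.normal(centre, 1.0, size=(80, 2))
    cloud[0] = centre          # central gene
    cloud[1] = centre + 4.0    # peripheral gene
    other = rng.normal([60.0, 60.0], 1.0, size=(40, 2))
    part = cluster_genes(np.vstack([cloud, other]), min_cluster_size=15)
    assert part.labels[0] != NOISE_LABEL
    assert part.probabilities[0] >= part.probabilities[1]


def test_min_cluster_size_validated(rng):
    with pytest.raises(ValueError):
        cluster_genes(rng.random((30, 2)), min_cluster_size=1)


def test_each_gene_has_at_most_one_module(small_normalised):
    res = discover_modules(small_normalised, seed=0, min_cluster_size=10)
    part = res.partition
    assert part.labels.ndim == 1  # one label per gene: exclusivity by shape
    assert ((part.probabilities >= 0) & (part.probabilities <= 1)).all()
    assert (part.probabilities[part.labels == NOISE_LABEL] == 0).all()


# ---------------------------------------------------------------------------
# AMI
# ---------------------------------------------------------------------------

def test_identical_and_relabelled_partitions_score_one(rng):
    a = rng.integers(0, 6, size=300)
    assert adjusted_mutual_information(a, a) == pytest.approx(1.0)
    relabel = (a + 2) % 6
    assert adjusted_mutual_information(a, relabel) == pytest.approx(1.0)


def test_independent_partitions_score_near_zero():
    vals = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=1000)
        b = rng.integers(0, 10, size=1000)
        vals.append(adjusted_mutual_information(a, b))
    assert np.abs(np.mean(vals)) < 0.01
    assert np.max(np.abs(vals)) < 0.05


def test_all_noise_partitions_share_no_structure():
    a = np.full(100, NOISE_LABEL)
    assert adjusted_mutual_information(a, a.copy()) == 0.0


def test_universe_mismatch_rejected():
    with pytest.raises(ValueError):
        adjusted_mutual_information(np.zeros(5), np.zeros(6))


# ---------------------------------------------------------------------------
# Robustness machinery
# ---------------------------------------------------------------------------

def test_identical_subsets_agree_perfectly(small_normalised):
    rb = robustness(
        small_normalised, n_subsets=2, subset_fraction=1.0, seed=0,
        min_cluster_size=10,
    )
    assert rb.pairwise_ami == pytest.approx([1.0])


def test_subset_fraction_validated(small_normalised):
    with pytest.raises(ValueError):
        robustness(small_normalised, n_subsets=2, subset_fraction=1.5)


def test_partition_expansion_marks_unseen_genes_noise():
    from thymod.gficf import GeneModulePartition

    part = GeneModulePartition(
        labels=np.array([1, 1, 2]),
        probabilities=np.ones(3),
        gene_index=np.array([0, 2, 4]),
    )
    full = partition_on_universe(part, 6)
    assert list(full) == [1, NOISE_LABEL, 1, NOISE_LABEL, 2, NOISE_LABEL]
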