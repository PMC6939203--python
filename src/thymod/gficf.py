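"""Gene co-expression module discovery via the weighted GF-ICF transform.

The transform adapts TF-IDF to sparse single-cell counts so that rarely
detected (tissue-restricted) genes are up-weighted and broadly expressed
genes attenuated:

* gene frequency ``G_f[x, c] = log2(1 + C[x, c])`` on the normalised count
  matrix C, restricted to genes detected in at least two cells;
* inverse cell frequency ``ICF_x = log10( sum_y W_y * N_y / (1 + E_{y,x}) )``
  where the sum runs over the five sort conditions y, ``W_y`` is the
  condition's expected contribution to the total mTEC population
  (TSPAN8+ 0.07, TSPAN8- 0.93, GP2+ 0.02, GP2- 0.98, unselected 1.00),
  ``N_y`` is the number of cells in condition y, and ``E_{y,x}`` the number
  of those cells expressing gene x — a weighted average of the per-condition
  inverse detection frequencies (a gene detected in 25% of a condition's
  cells has per-condition inverse frequency 4);
* ``GF_ICF = G_f * ICF`` (each gene row scaled by its ICF).

Genes are then embedded by truncated SVD (first 50 left singular vectors),
pairwise cosine distances, and a 2-D t-SNE on the precomputed distances;
density-based hierarchical clustering (HDBSCAN) of the 2-D coordinates
yields mutually exclusive gene modules with membership probabilities, genes
in no dense region being declared noise. Partition robustness is quantified
by re-running the whole chain on random cell subsets and scoring all
pairwise partition agreements with adjusted mutual information (noise kept
as its own cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import TruncatedSVD
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_mutual_info_score, pairwise_distances

from .containers import CONDITIONS, CountMatrix

#: Expected contribution of each sort condition to the total mTEC
#: population; the ICF weights W_y.
DEFAULT_CONDITION_WEIGHTS = {
    "TSPAN8+": 0.07,
    "TSPAN8-": 0.93,
    "GP2+": 0.02,
    "GP2-": 0.98,
    "unselected": 1.00,
}

NOISE_LABEL = -1


@dataclass
class IcfWeights:
    """Condition weights with per-condition detection counts.

    ``W`` maps condition to weight, ``N`` condition to cell count, and
    ``E`` is the genes x conditions matrix of expressing-cell counts.
    """

    W: dict
    N: dict
    E: np.ndarray
    conditions: tuple
    gene_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.W.values()):
            raise ValueError("weights must be non-negative")
        for j, cond in enumerate(self.conditions):
            if self.E[:, j].min() < 0 or self.E[:, j].max() > self.N[cond]:
                raise ValueError(f"E out of range for condition {cond!r}")


@dataclass
class GfIcfMatrix:
    values: sp.csr_matrix  # genes x cells
    icf: np.ndarray
    gf: sp.csr_matrix
    gene_index: np.ndarray  # indices into the original gene universe
    clamped: np.ndarray  # genes whose raw ICF was negative and clamped


@dataclass
class GeneEmbedding:
    singular_values: np.ndarray
    left_vectors: np.ndarray  # genes x n_components (U)
    cosine_distances: np.ndarray
    coords2d: np.ndarray
    seed: int
    perplexity: float


@dataclass
class GeneModulePartition:
    """Per-gene module label (noise = -1) and membership probability."""

    labels: np.ndarray
    probabilities: np.ndarray
    gene_index: np.ndarray | None = None

    @property
    def n_modules(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE_LABEL])))


@dataclass
class RobustnessResult:
    n_subsets: int
    subset_fraction: float
    pairwise_ami: np.ndarray
    partitions: list = field(default_factory=list)

    @property
    def mean_ami(self) -> float:
        return float(np.mean(self.pairwise_ami))


# ---------------------------------------------------------------------------
# The transform
# ---------------------------------------------------------------------------

def gene_frequency(
    C: CountMatrix | sp.spmatrix, min_cells: int = 2
) -> tuple[sp.csr_matrix, np.ndarray]:
    """``G_f = log2(1 + C)``, keeping genes detected in >= ``min_cells`` cells.

    Returns the gene-frequency matrix and the indices of the retained genes
    (genes detected in fewer cells are dropped from the co-clustering, as
    single-cell detections carry no co-expression signal).
    """
    counts = C.counts if isinstance(C, CountMatrix) else sp.csr_matrix(C)
    detected_in = np.asarray((counts > 0).sum(axis=1)).ravel()
    keep = np.flatnonzero(detected_in >= min_cells)
    gf = counts[keep].copy().tocsr()
    gf.data = np.log2(1.0 + gf.data)
    return gf, keep


def compute_icf_weights(
    C: CountMatrix,
    weights: dict | None = None,
    gene_index: np.ndarray | None = None,
    renormalise: bool = False,
) -> IcfWeights:
    """Tabulate N_y and E_{y,x} from a count matrix, attaching weights W_y.

    ``gene_index`` restricts the tabulation to a subset of genes (typically
    the genes retained by :func:`gene_frequency`). With ``renormalise`` the
    weights are divided by their sum (the default keeps the raw printed
    contributions, which intentionally do not sum to one).
    """
    W = dict(weights or DEFAULT_CONDITION_WEIGHTS)
    if renormalise:
        total = sum(W.values())
        W = {k: v / total for k, v in W.items()}
    detected = (C.counts > 0).astype(np.int64)
    if gene_index is not None:
        detected = detected[gene_index]
    conditions = tuple(c for c in CONDITIONS if c in set(C.cell_meta["condition"]))
    cond_arr = C.cell_meta["condition"].to_numpy()
    N = {}
    E = np.zeros((detected.shape[0], len(conditions)), dtype=np.int64)
    for j, cond in enumerate(conditions):
        sel = np.flatnonzero(cond_arr == cond)
        N[cond] = len(sel)
        E[:, j] = np.asarray(detected[:, sel].sum(axis=1)).ravel()
    return IcfWeights(W=W, N=N, E=E, conditions=conditions, gene_index=gene_index)


def inverse_cell_frequency(
    weights: IcfWeights, clamp_negative: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """``ICF_x = log10( sum_y W_y * N_y / (1 + E_{y,x}) )``.

    Conditions with ``N_y = 0`` are omitted from the sum. Genes detected in
    nearly every cell can make the sum fall below 1, producing a negative
    ICF; by default such entries are clamped to 0 (a negative weight would
    invert the intent of the transform) and reported in the returned
    boolean mask. Pass ``clamp_negative=False`` to keep the raw values.
    """
    if weights.E.min() < 0:
        raise ValueError("negative expressing-cell counts")
    total = np.zeros(weights.E.shape[0])
    for j, cond in enumerate(weights.conditions):
        n_y = weights.N[cond]
        if n_y == 0:
            continue
        total += weights.W[cond] * n_y / (1.0 + weights.E[:, j])
    icf = np.log10(total)
    clamped = icf < 0
    if clamp_negative:
        icf = np.where(clamped, 0.0, icf)
    return icf, clamped


def per_condition_inverse_frequency(n_cells: int, n_expressing: int,
                                    regularised: bool = False) -> float:
    """Inverse detection frequency of a gene within one condition subset.

    The plain ratio ``N_y / E_{y,x}`` (a gene detected in 25% of a subset
    has inverse cell frequency 4); with ``regularised=True`` the
    add-one-regularised term ``N_y / (1 + E_{y,x})`` that enters the
    weighted ICF sum is returned instead.
    """
    if regularised:
        return n_cells / (1.0 + n_expressing)
    if n_expressing == 0:
        raise ValueError("gene not expressed in the subset; use regularised=True")
    return n_cells / n_expressing


def gf_icf(
    gf: sp.spmatrix,
    icf: np.ndarray,
    gene_index: np.ndarray | None = None,
    clamped: np.ndarray | None = None,
) -> GfIcfMatrix:
    """Scale each gene row of ``gf`` by its ICF: ``GF_ICF = G_f * ICF``."""
    gf = sp.csr_matrix(gf)
    icf = np.asarray(icf, dtype=float)
    if gf.shape[0] != len(icf):
        raise ValueError(
            f"gene sets differ: {gf.shape[0]} gf rows vs {len(icf)} ICF entries"
        )
    values = sp.diags(icf) @ gf
    return GfIcfMatrix(
        values=values.tocsr(),
        icf=icf,
        gf=gf,
        gene_index=gene_index if gene_index is not None else np.arange(gf.shape[0]),
        clamped=clamped if clamped is not None else np.zeros(len(icf), dtype=bool),
    )


# ---------------------------------------------------------------------------
# Embedding and clustering
# ---------------------------------------------------------------------------

def embed_genes(
    m: GfIcfMatrix,
    n_components: int = 50,
    perplexity: float = 50.0,
    seed: int = 0,
    tsne_max_iter: int = 1000,
    weight_by_singular_values: bool = True,
) -> GeneEmbedding:
    """Truncated SVD -> cosine distances in the reduced space -> 2-D t-SNE.

    The first ``n_components`` left singular vectors of GF_ICF summarise
    each gene's expression context; pairwise cosine distances between genes
    in the reduced space are fed to a seeded t-SNE (precomputed-distance
    mode). By default the components are weighted by their singular values
    (cosine on the rows of U·Σ, i.e. on the rank-``n_components``
    reconstruction of each gene's GF_ICF row): on data whose effective rank
    falls short of ``n_components``, unweighted cosine on U gives the
    residual pure-noise components equal influence and erases the gene
    neighbourhood structure, whereas the weighted form degrades gracefully.
    Pass ``weight_by_singular_values=False`` for plain cosine on U. The
    perplexity is reduced automatically when fewer than ``3 * perplexity``
    genes are embedded (recorded in the result).
    """
    n_genes, n_cells = m.values.shape
    if n_components > min(n_genes, n_cells):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells)="
            f"{min(n_genes, n_cells)}"
        )
    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    us = svd.fit_transform(m.values)  # U * diag(d)
    d = svd.singular_values_
    U = us / np.where(d > 0, d, 1.0)
    D = pairwise_distances(us if weight_by_singular_values else U, metric="cosine")
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    perp = min(perplexity, (n_genes - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perp,
        random_state=seed,
        max_iter=tsne_max_iter,
    )
    Z = tsne.fit_transform(D)
    return GeneEmbedding(
        singular_values=d,
        left_vectors=U,
        cosine_distances=D,
        coords2d=Z,
        seed=seed,
        perplexity=perp,
    )


def cluster_genes(
    emb: GeneEmbedding | np.ndarray,
    min_cluster_size: int = 20,
    coherence_threshold: float | None = 0.9,
) -> GeneModulePartition:
    """HDBSCAN density clustering of the 2-D gene coordinates.

    Genes in no dense region receive the noise label (-1) and membership
    probability 0; clustered genes carry HDBSCAN's soft membership
    probability. Module ids are relabelled to 1..M.

    A co-expression module must be internally coherent, not merely dense on
    the 2-D map: when a :class:`GeneEmbedding` is supplied, candidate
    clusters whose median within-cluster cosine distance exceeds
    ``coherence_threshold`` times the global median pairwise distance are
    rejected as background and returned to noise. (A large diffuse
    population of mutually unrelated genes can form a contiguous region of
    the map whose internal distances are indistinguishable from the overall
    background — such a region is not a module.) Pass
    ``coherence_threshold=None``, or a bare coordinate array, to skip the
    filter.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    is_embedding = isinstance(emb, GeneEmbedding)
    Z = emb.coords2d if is_embedding else np.asarray(emb)
    clusterer = HDBSCAN(min_cluster_size=min_cluster_size, copy=True)
    clusterer.fit(Z)
    raw = clusterer.labels_.copy()
    if is_embedding and coherence_threshold is not None and (raw >= 0).any():
        D = emb.cosine_distances
        global_median = np.median(D[np.triu_indices(len(D), k=1)])
        for c in np.unique(raw[raw >= 0]):
            members = raw == c
            sub = D[np.ix_(members, members)]
            within = np.median(sub[np.triu_indices(int(members.sum()), k=1)])
            if within > coherence_threshold * global_median:
                raw[members] = -1
    labels = np.full_like(raw, NOISE_LABEL)
    for new, old in enumerate(np.unique(raw[raw >= 0]), start=1):
        labels[raw == old] = new
    probs = np.where(labels == NOISE_LABEL, 0.0, clusterer.probabilities_)
    return GeneModulePartition(labels=labels, probabilities=probs)


def adjusted_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """AMI between two gene-module partitions, noise as its own cluster.

    Uses the permutation-model expected mutual information and the
    arithmetic mean of the two entropies as normaliser:
    ``AMI = (MI - E[MI]) / (mean(H(a), H(b)) - E[MI])``. Noise labels are
    mapped to one dedicated cluster before the computation, so agreement on
    which genes are unassignable counts as agreement.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions cover different gene universes")
    # Degenerate case: two partitions that assigned *no* gene to any module
    # are constant labelings, for which the AMI normaliser is 0/0. The
    # statistic quantifies reproducibility of discovered structure, and two
    # runs that discovered nothing share none — defined here as 0 (the
    # identical-constant-labeling convention would return 1 and reward
    # finding nothing).
    if set(np.unique(a)) == {NOISE_LABEL} and set(np.unique(b)) == {NOISE_LABEL}:
        return 0.0
    # noise (-1) is a valid shared label otherwise; sklearn treats every
    # distinct value as a cluster, which is exactly the noise-as-a-cluster
    # convention.
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


# ---------------------------------------------------------------------------
# Pipeline and robustness
# ---------------------------------------------------------------------------

@dataclass
class ModulePipelineResult:
    partition: GeneModulePartition
    embedding: GeneEmbedding
    gf_icf: GfIcfMatrix
    weights: IcfWeights


def discover_modules(
    C: CountMatrix,
    condition_weights: dict | None = None,
    n_components: int = 50,
    perplexity: float = 50.0,
    min_cluster_size: int = 20,
    seed: int = 0,
    min_cells: int = 2,
) -> ModulePipelineResult:
    """Full chain: G_f -> ICF -> GF_ICF -> SVD/cosine/t-SNE -> HDBSCAN.

    The returned partition carries ``gene_index`` mapping its rows back to
    the input gene universe (genes detected in fewer than ``min_cells``
    cells are excluded before the transform).
    """
    gf, keep = gene_frequency(C, min_cells=min_cells)
    weights = compute_icf_weights(C, weights=condition_weights, gene_index=keep)
    icf, clamped = inverse_cell_frequency(weights)
    m = gf_icf(gf, icf, gene_index=keep, clamped=clamped)
    emb = embed_genes(m, n_components=n_components, perplexity=perplexity, seed=seed)
    part = cluster_genes(emb, min_cluster_size=min_cluster_size)
    part.gene_index = keep
    return ModulePipelineResult(partition=part, embedding=emb, gf_icf=m, weights=weights)


def partition_on_universe(
    part: GeneModulePartition, n_genes: int
) -> np.ndarray:
    """Expand a partition to the full gene universe, unseen genes as noise."""
    full = np.full(n_genes, NOISE_LABEL, dtype=int)
    idx = part.gene_index if part.gene_index is not None else np.arange(len(part.labels))
    full[idx] = part.labels
    return full


def robustness(
    C: CountMatrix,
    n_subsets: int = 100,
    subset_fraction: float = 0.8,
    seed: int = 0,
    condition_weights: dict | None = None,
    **pipeline_kwargs,
) -> RobustnessResult:
    """Partition stability under cell subsampling.

    For each of ``n_subsets`` random subsets of ``subset_fraction`` of the
    cells (drawn without replacement), the condition counts N_y and
    expressing-cell counts E_{y,x} are recomputed and the full
    transform-and-cluster chain re-run; all pairwise AMIs between the
    resulting gene partitions (expanded to the common gene universe, noise
    as a cluster) are returned. The chain seed is shared across subsets so
    that identical subsets yield identical partitions.
    """
    if not 0.0 < subset_fraction <= 1.0:
        raise ValueError("subset_fraction must lie in (0, 1]")
    n_take = max(1, int(round(subset_fraction * C.n_cells)))
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_subsets):
        idx = np.sort(rng.choice(C.n_cells, size=n_take, replace=False))
        sub = C.subset_cells(idx)
        res = discover_modules(
            sub, condition_weights=condition_weights, seed=seed, **pipeline_kwargs
        )
        partitions.append(partition_on_universe(res.partition, C.n_genes))
    amis = []
    for i in range(n_subsets):
        for j in range(i + 1, n_subsets):
            amis.append(adjusted_mutual_information(partitions[i], partitions[j]))
    return RobustnessResult(
        n_subsets=n_subsets,
        subset_fraction=subset_fraction,
        pairwise_ami=np.array(amis),
        partitions=partitions,
    )
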