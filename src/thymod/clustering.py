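"""Cell subpopulation discovery: SNN graph, Louvain communities, and
condition enrichment.

Cells are embedded (principal components of the normalised matrix, batch
corrected), joined into a shared-nearest-neighbour graph whose edge weights
are the Jaccard overlap of the two cells' k-NN sets, and partitioned with
the Louvain modularity algorithm. Sorted-condition enrichment or depletion
of each cluster is tested per mouse against the proportion expected from
the unselected cells, with a two-sided Wilcoxon signed-rank test across
mice.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.neighbors import NearestNeighbors


@dataclass
class SnnGraph:
    """Shared-nearest-neighbour graph over cells."""

    graph: nx.Graph
    k: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class CellClusterPartition:
    labels: np.ndarray  # per-cell cluster id, 1..K
    modularity: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass
class EnrichmentResult:
    cluster: int
    condition: str
    direction: str  # enriched | depleted | none
    p_value: float | None
    n_mice: int
    testable: bool


def build_snn_graph(embedding: np.ndarray, k: int = 10) -> SnnGraph:
    """SNN graph: edge weight = Jaccard index of two cells' k-NN sets.

    Each cell's neighbourhood is its k nearest neighbours (excluding
    itself); an undirected edge joins two cells sharing at least one
    neighbour, weighted |A ∩ B| / |A ∪ B|.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row[1:]) for row in idx]  # drop self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    # candidate pairs: cells co-occurring in someone's neighbourhood, plus
    # mutual neighbour pairs
    inverted: dict[int, list[int]] = {}
    for i, s in enumerate(neigh):
        for j in s:
            inverted.setdefault(j, []).append(i)
    pairs = set()
    for members in inverted.values():
        members = sorted(members)
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                pairs.add((a, b))
    for i, s in enumerate(neigh):
        for j in s:
            pairs.add((min(i, j), max(i, j)))
    for a, b in pairs:
        inter = len(neigh[a] & neigh[b])
        if inter == 0:
            continue
        union = len(neigh[a] | neigh[b])
        g.add_edge(a, b, weight=inter / union)
    return SnnGraph(graph=g, k=k)


def louvain(snn: SnnGraph, seed: int = 0, resolution: float = 1.0) -> CellClusterPartition:
    """Louvain community detection on the SNN graph.

    Returns 1-based cluster labels and the weighted modularity of the final
    partition. Node visit order is shuffled by ``seed``.
    """
    g = snn.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for cid, members in enumerate(communities, start=1):
        for node in members:
            labels[node] = cid
    q = nx.community.modularity(g, communities, weight="weight", resolution=resolution)
    return CellClusterPartition(labels=labels, modularity=float(q), seed=seed)


def subcluster(
    embedding: np.ndarray,
    partition: CellClusterPartition,
    cluster: int,
    k: int = 10,
    seed: int = 0,
) -> CellClusterPartition:
    """Recursively re-cluster the cells of one cluster (e.g. to split a
    heterogeneous satellite cluster into sub-clusters).

    The returned partition keeps all other labels and replaces ``cluster``
    with new labels appended after the current maximum.
    """
    sel = partition.labels == cluster
    if sel.sum() < 3:
        raise ValueError("cluster too small to subdivide")
    sub = louvain(build_snn_graph(embedding[sel], k=min(k, int(sel.sum()) - 1)), seed=seed)
    labels = partition.labels.copy()
    offset = labels.max()
    labels[sel] = offset + sub.labels
    return CellClusterPartition(labels=labels, modularity=partition.modularity, seed=seed)


def condition_enrichment(
    partition: CellClusterPartition,
    cell_meta: pd.DataFrame,
    reference_condition: str = "unselected",
) -> list[EnrichmentResult]:
    """Per-cluster condition enrichment/depletion vs the unselected baseline.

    For every cluster and every non-reference condition, each mouse
    contributes a paired observation: the proportion of its
    condition-sorted cells found in the cluster versus the proportion of
    its unselected cells found there (the expected value absent sorting
    effects). A two-sided Wilcoxon signed-rank test across mice yields the
    p-value; direction is the sign of the median paired difference. Mice
    lacking cells of either the tested or the reference condition are
    excluded; with fewer than two contributing mice, or all differences
    zero, the result is flagged untestable.
    """
    labels = partition.labels
    conditions = cell_meta["condition"].to_numpy()
    mice = cell_meta["mouse_id"].to_numpy()
    results = []
    for cluster in np.unique(labels):
        in_cluster = labels == cluster
        for cond in pd.unique(conditions):
            if cond == reference_condition:
                continue
            obs, exp = [], []
            for mouse in pd.unique(mice):
                m = mice == mouse
                n_cond = int((m & (conditions == cond)).sum())
                n_ref = int((m & (conditions == reference_condition)).sum())
                if n_cond == 0 or n_ref == 0:
                    continue
                obs.append((m & (conditions == cond) & in_cluster).sum() / n_cond)
                exp.append((m & (conditions == reference_condition) & in_cluster).sum() / n_ref)
            diffs = np.array(obs) - np.array(exp)
            if len(diffs) < 2 or np.all(diffs == 0):
                results.append(
                    EnrichmentResult(int(cluster), cond, "none", None, len(diffs), False)
                )
                continue
            method = "exact" if len(diffs) <= 25 else "approx"
            stat = wilcoxon(diffs, alternative="two-sided", method=method,
                            zero_method="wilcox")
            med = np.median(diffs)
            direction = "enriched" if med > 0 else ("depleted" if med < 0 else "none")
            results.append(
                EnrichmentResult(
                    int(cluster), cond, direction, float(stat.pvalue), len(diffs), True
                )
            )
    return results


def cluster_cells(
    embedding: np.ndarray, k: int = 10, seed: int = 0
) -> CellClusterPartition:
    """Convenience: SNN graph + Louvain in one call."""
    return louvain(build_snn_graph(embedding, k=k), seed=seed)
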