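"""Cross-mouse reproducibility of pairwise TRG co-expression.

For every unordered pair of tissue-restricted genes, the co-expression
frequency ``f(G^X, G^Y)`` is the fraction of a single mouse's cells in
which both genes are detected (raw count >= 1). Comparing the per-mouse
frequency vectors across all mouse pairs with a Pearson correlation
quantifies how reproducibly the same gene pairs co-occur in different
animals; a restricted variant computes the frequencies only within a
chosen set of cell clusters (the AIRE+ mature analogue of restricting to
clusters 3-6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import CountMatrix


@dataclass
class CoexpressionFrequencies:
    gene_pairs: np.ndarray  # (n_pairs, 2) indices into the gene set
    gene_ids: np.ndarray  # ids of the gene set
    per_mouse: dict  # mouse_id -> (n_pairs,) frequencies
    pooled: np.ndarray
    cell_filter: str
    cells_per_mouse: dict


@dataclass
class CorrelationSummary:
    pairwise_r: dict  # (mouse_a, mouse_b) -> r
    vs_pooled_r: dict  # mouse -> r against the pooled meta-experiment

    @property
    def mean_r(self) -> float:
        return float(np.mean(list(self.pairwise_r.values())))

    @property
    def mean_r_including_pooled(self) -> float:
        vals = list(self.pairwise_r.values()) + list(self.vs_pooled_r.values())
        return float(np.mean(vals))


def coexpression_frequencies(
    C: CountMatrix,
    gene_ids: np.ndarray,
    cell_clusters: np.ndarray | None = None,
    clusters: tuple | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> CoexpressionFrequencies:
    """Per-mouse pairwise co-detection frequencies over a gene set.

    ``gene_ids`` selects the (TRG) genes; detection is raw count >= 1. When
    ``clusters`` is given, cells are first restricted to those whose entry
    in ``cell_clusters`` is in the tuple. The full pair set is quadratic in
    the gene set; ``max_pairs`` caps it by a seeded uniform subsample of
    pairs (the same pairs for every mouse).
    """
    id_to_row = {g: i for i, g in enumerate(C.gene_ids)}
    rows = np.array([id_to_row[g] for g in gene_ids if g in id_to_row])
    if len(rows) < 2:
        raise ValueError("need at least 2 genes from the matrix")
    cell_sel = np.ones(C.n_cells, dtype=bool)
    filter_desc = "all cells"
    if clusters is not None:
        if cell_clusters is None:
            raise ValueError("clusters requested but no cell_clusters given")
        cell_sel = np.isin(np.asarray(cell_clusters), clusters)
        filter_desc = f"clusters {sorted(clusters)}"
    det = (C.counts[rows] > 0).astype(np.int64).toarray()[:, cell_sel]
    mice = C.cell_meta["mouse_id"].to_numpy()[cell_sel]

    n_set = len(rows)
    pairs = np.array(list(combinations(range(n_set), 2)))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = pairs[rng.choice(len(pairs), size=max_pairs, replace=False)]

    def freqs(block: np.ndarray) -> np.ndarray:
        co = (block[pairs[:, 0]] * block[pairs[:, 1]]).sum(axis=1)
        return co / block.shape[1]

    per_mouse = {}
    cells_per_mouse = {}
    for mouse in pd.unique(mice):
        sel = mice == mouse
        if sel.sum() == 0:
            warnings.warn(f"mouse {mouse!r} has no cells after filtering; excluded")
            continue
        per_mouse[mouse] = freqs(det[:, sel])
        cells_per_mouse[mouse] = int(sel.sum())
    if det.shape[1] == 0:
        raise ValueError("no cells left after filtering")
    pooled = freqs(det)
    gene_id_arr = C.gene_ids[rows]
    return CoexpressionFrequencies(
        gene_pairs=pairs,
        gene_ids=gene_id_arr,
        per_mouse=per_mouse,
        pooled=pooled,
        cell_filter=filter_desc,
        cells_per_mouse=cells_per_mouse,
    )


def cross_mouse_correlation(
    freqs: CoexpressionFrequencies,
    drop_all_zero_pairs: bool = True,
) -> CorrelationSummary:
    """Pearson correlation of co-expression frequencies between mouse pairs.

    Pairs with zero frequency in every mouse carry no signal and are
    dropped by default before correlating. Mouse pairs where either vector
    has zero variance are flagged with a warning and excluded from the
    mean. Mouse-versus-pooled correlations are reported separately.
    """
    mice = list(freqs.per_mouse)
    if len(mice) < 2:
        if len(mice) == 1:
            return CorrelationSummary(
                pairwise_r={(mice[0], mice[0]): 1.0}, vs_pooled_r={}
            )
        raise ValueError("need at least one mouse")
    mat = np.stack([freqs.per_mouse[m] for m in mice])
    keep = np.ones(mat.shape[1], dtype=bool)
    if drop_all_zero_pairs:
        keep = mat.sum(axis=0) > 0
    mat = mat[:, keep]
    pooled = freqs.pooled[keep]
    if mat.shape[1] < 3:
        raise ValueError("fewer than 3 informative gene pairs")
    pairwise = {}
    for i, j in combinations(range(len(mice)), 2):
        a, b = mat[i], mat[j]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(
                f"zero-variance frequency vector for pair ({mice[i]}, {mice[j]}); "
                "correlation undefined, excluded"
            )
            continue
        pairwise[(mice[i], mice[j])] = float(np.corrcoef(a, b)[0, 1])
    vs_pooled = {}
    for i, m in enumerate(mice):
        if mat[i].std() == 0 or pooled.std() == 0:
            continue
        vs_pooled[m] = float(np.corrcoef(mat[i], pooled)[0, 1])
    return CorrelationSummary(pairwise_r=pairwise, vs_pooled_r=vs_pooled)
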