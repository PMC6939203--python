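"""Module composition statistics: Monte Carlo enrichment, chromosome
preference, genomic distance ECDFs, and arbitrary gene-set distributions.

The common null model resamples gene sets of matched size uniformly without
replacement from the clustered gene universe, with empirical p-values using
the add-one rule ``p = (1 + #{null >= obs}) / (n_perm + 1)`` (never zero),
Benjamini-Hochberg adjusted across the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .containers import TRG_CATEGORIES
from .gficf import NOISE_LABEL, GeneModulePartition


@dataclass
class McEnrichmentResult:
    module: int
    statistic: float  # observed count of set members in the module
    proportion: float
    expected: float  # null mean
    null_samples: np.ndarray
    p_empirical: float  # two-sided
    p_enriched: float
    p_depleted: float
    p_adjusted: float
    direction: str  # enriched | depleted | ns


@dataclass
class DistanceEcdf:
    distances: np.ndarray  # sorted, bp
    source: str
    ks_statistic: float | None = None
    ks_p: float | None = None

    def ecdf(self, at: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.distances, at, side="right") / len(self.distances)


def _module_sizes(labels: np.ndarray) -> dict[int, int]:
    mods = np.unique(labels[labels != NOISE_LABEL])
    return {int(m): int((labels == m).sum()) for m in mods}


def _mc_set_counts(
    member_mask: np.ndarray, sizes: list[int], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null counts of set members in resampled modules of the given sizes.

    Vectorised over permutations: each permutation shuffles the membership
    mask once and slices it into the module sizes (equivalent to sampling
    each module without replacement from the universe).
    """
    n = len(member_mask)
    out = np.empty((n_perm, len(sizes)), dtype=np.int64)
    for p in range(n_perm):
        perm = rng.permutation(n)
        shuffled = member_mask[perm]
        start = 0
        for j, s in enumerate(sizes):
            out[p, j] = shuffled[start:start + s].sum()
            start += s
    return out


def _empirical_p(null: np.ndarray, obs: float) -> tuple[float, float, float]:
    n_perm = len(null)
    p_enr = (1 + int((null >= obs).sum())) / (n_perm + 1)
    p_dep = (1 + int((null <= obs).sum())) / (n_perm + 1)
    p_two = min(1.0, 2.0 * min(p_enr, p_dep))
    return p_two, p_enr, p_dep


def geneset_module_distribution(
    partition: GeneModulePartition | np.ndarray,
    member_mask: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    mc_method: str = "fdr_bh",
) -> list[McEnrichmentResult]:
    """Monte Carlo enrichment/depletion of a gene set in every module.

    ``member_mask`` is a boolean vector over the clustered universe (genes
    with a module label or noise). For each module of size s, the null is
    the count of set members among s genes sampled uniformly without
    replacement from the universe, ``n_perm`` times; one-sided empirical
    p-values are doubled and capped at 1 for the two-sided call and
    BH-adjusted across modules.
    """
    labels = partition.labels if isinstance(partition, GeneModulePartition) else np.asarray(partition)
    member_mask = np.asarray(member_mask, dtype=bool)
    if len(member_mask) != len(labels):
        raise ValueError("membership mask and partition cover different universes")
    if member_mask.sum() == 0:
        raise ValueError("gene set has empty intersection with the universe")
    sizes = _module_sizes(labels)
    if any(s > len(labels) for s in sizes.values()):
        raise ValueError("module larger than the gene universe")
    rng = np.random.default_rng(seed)
    mods = list(sizes)
    null = _mc_set_counts(member_mask, [sizes[m] for m in mods], n_perm, rng)
    results = []
    p_two_all = []
    for j, m in enumerate(mods):
        obs = int(member_mask[labels == m].sum())
        p_two, p_enr, p_dep = _empirical_p(null[:, j], obs)
        p_two_all.append(p_two)
        results.append(
            McEnrichmentResult(
                module=m,
                statistic=float(obs),
                proportion=obs / sizes[m],
                expected=float(null[:, j].mean()),
                null_samples=null[:, j],
                p_empirical=p_two,
                p_enriched=p_enr,
                p_depleted=p_dep,
                p_adjusted=np.nan,
                direction="ns",
            )
        )
    adjusted = multipletests(p_two_all, method=mc_method)[1]
    for res, p_adj in zip(results, adjusted):
        res.p_adjusted = float(p_adj)
        if p_adj < alpha:
            res.direction = "enriched" if res.statistic > res.expected else "depleted"
    return results


def trg_enrichment(
    partition: GeneModulePartition | np.ndarray,
    categories: np.ndarray | pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
    **kwargs,
) -> list[McEnrichmentResult]:
    """TRG enrichment/depletion per module.

    TRGs are the union of the AIRE-dependent, AIRE-enhanced and
    AIRE-independent-TRG categories; otherwise identical to
    :func:`geneset_module_distribution`.
    """
    is_trg = pd.Series(categories).isin(TRG_CATEGORIES).to_numpy()
    return geneset_module_distribution(partition, is_trg, n_perm=n_perm, seed=seed, **kwargs)


def chromosome_enrichment(
    partition: GeneModulePartition | np.ndarray,
    chromosomes: np.ndarray | pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.01,
    mc_method: str = "fdr_bh",
) -> pd.DataFrame:
    """One-sided Monte Carlo chromosome enrichment per module x chromosome.

    For every module and chromosome, the observed percentage of the
    module's genes on that chromosome is compared with the percentages in
    resampled modules of matched size; the one-sided (enrichment)
    empirical p is BH-adjusted across all module x chromosome cells and
    flagged significant at adjusted p < ``alpha``.
    """
    labels = partition.labels if isinstance(partition, GeneModulePartition) else np.asarray(partition)
    chromosomes = pd.Series(chromosomes).reset_index(drop=True)
    if len(chromosomes) != len(labels):
        raise ValueError("chromosome vector and partition cover different universes")
    if chromosomes.isna().any():
        raise ValueError("unknown (missing) chromosome labels")
    chrom_values = sorted(chromosomes.unique())
    chrom_codes = chromosomes.map({c: i for i, c in enumerate(chrom_values)}).to_numpy()
    sizes = _module_sizes(labels)
    mods = list(sizes)
    rng = np.random.default_rng(seed)
    n = len(labels)
    n_chrom = len(chrom_values)
    null = np.empty((n_perm, len(mods), n_chrom), dtype=np.int64)
    for p in range(n_perm):
        perm_codes = chrom_codes[rng.permutation(n)]
        start = 0
        for j, m in enumerate(mods):
            s = sizes[m]
            null[p, j] = np.bincount(perm_codes[start:start + s], minlength=n_chrom)
            start += s
    rows = []
    for j, m in enumerate(mods):
        obs_counts = np.bincount(chrom_codes[labels == m], minlength=n_chrom)
        for ci, chrom in enumerate(chrom_values):
            p_enr = (1 + int((null[:, j, ci] >= obs_counts[ci]).sum())) / (n_perm + 1)
            rows.append(
                {
                    "module": m,
                    "chromosome": chrom,
                    "observed_pct": 100.0 * obs_counts[ci] / sizes[m],
                    "expected_pct": 100.0 * null[:, j, ci].mean() / sizes[m],
                    "p_empirical": p_enr,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_empirical"], method=mc_method)[1]
    table["significant"] = table["p_adjusted"] < alpha
    return table


def pairwise_distance_ecdf(
    gene_meta: pd.DataFrame,
    partition: GeneModulePartition | np.ndarray | None = None,
    aire_mask: np.ndarray | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> dict[str, DistanceEcdf]:
    """Same-chromosome pairwise genomic distance ECDFs with KS comparisons.

    Distances are |start_i - start_j| between gene start coordinates on the
    same chromosome, computed for (a) all genes, (b) AIRE-regulated genes
    only (``aire_mask``), and (c) pairs of genes sharing a module. The
    two-sample Kolmogorov-Smirnov statistic and p-value of (b) vs (a) and
    (c) vs (a) are stored on the respective results.
    """
    chroms = gene_meta["chromosome"].to_numpy()
    pos = gene_meta["position_bp"].to_numpy(dtype=float)

    def distances(mask: np.ndarray, same_module: np.ndarray | None = None) -> np.ndarray:
        out = []
        for c in np.unique(chroms[mask]):
            sel = np.flatnonzero(mask & (chroms == c))
            if len(sel) < 2:
                continue
            p = pos[sel]
            d = np.abs(p[:, None] - p[None, :])
            iu = np.triu_indices(len(sel), k=1)
            dd = d[iu]
            if same_module is not None:
                lab = same_module[sel]
                pair_ok = (lab[iu[0]] == lab[iu[1]]) & (lab[iu[0]] != NOISE_LABEL)
                dd = dd[pair_ok]
            out.append(dd)
        if not out:
            raise ValueError("fewer than 2 genes on every chromosome for this subset")
        d_all = np.concatenate(out)
        if max_pairs is not None and len(d_all) > max_pairs:
            rng = np.random.default_rng(seed)
            d_all = rng.choice(d_all, size=max_pairs, replace=False)
        return np.sort(d_all)

    everyone = np.ones(len(gene_meta), dtype=bool)
    results = {"all_pairs": DistanceEcdf(distances(everyone), "all_pairs")}
    if aire_mask is not None:
        d = DistanceEcdf(distances(np.asarray(aire_mask, dtype=bool)), "aire_regulated_pairs")
        ks = ks_2samp(d.distances, results["all_pairs"].distances)
        d.ks_statistic, d.ks_p = float(ks.statistic), float(ks.pvalue)
        results["aire_regulated_pairs"] = d
    if partition is not None:
        labels = partition.labels if isinstance(partition, GeneModulePartition) else np.asarray(partition)
        d = DistanceEcdf(distances(everyone, same_module=labels), "within_module_pairs")
        ks = ks_2samp(d.distances, results["all_pairs"].distances)
        d.ks_statistic, d.ks_p = float(ks.statistic), float(ks.pvalue)
        results["within_module_pairs"] = d
    return results
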