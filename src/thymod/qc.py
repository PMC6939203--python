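"""Cell quality filtering, normalisation, and batch-aware embedding.

Low-quality libraries are removed by median-absolute-deviation rules
applied per batch: cells with total counts or detected features more than
one MAD below the batch median, or a mitochondrial read fraction more than
three MADs above it, are dropped. MADs use the 1.4826 normal-consistency
constant (configurable). Surviving cells are scaled so every cell total
equals the median pre-normalisation total.

Batch correction is deliberately a pluggable embedding contract: the
built-in default is PCA followed by per-batch mean-centring in PC space,
and an externally computed corrected embedding of matching cell order is
accepted wherever an embedding is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .containers import CountMatrix

MAD_CONSTANT = 1.4826


@dataclass
class QcReport:
    """Per-batch thresholds and per-cell pass/fail bookkeeping."""

    n_cells_in: int
    n_cells_kept: int
    thresholds: dict  # batch -> {"reads_min", "features_min", "mito_max"}
    flags: pd.DataFrame  # cell_id, batch, kept, reason

    def to_json_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_kept": self.n_cells_kept,
            "thresholds": self.thresholds,
            "n_failed_by_reason": self.flags.loc[~self.flags.kept, "reason"]
            .value_counts()
            .to_dict(),
        }


def _mad(x: np.ndarray, constant: float = MAD_CONSTANT) -> float:
    med = np.median(x)
    return constant * float(np.median(np.abs(x - med)))


def filter_cells(
    raw: CountMatrix,
    n_mads_reads: float = 1.0,
    n_mads_features: float = 1.0,
    n_mads_mito: float = 3.0,
    per_batch: bool = True,
    min_batch_size: int = 10,
    mad_constant: float = MAD_CONSTANT,
) -> tuple[CountMatrix, QcReport]:
    """Remove low-quality cells by the three MAD rules.

    A cell fails when its total counts fall below ``median - n_mads_reads *
    MAD``, its detected feature count below ``median - n_mads_features *
    MAD``, or its mitochondrial fraction above ``median + n_mads_mito *
    MAD``, thresholds computed within each batch (or pooled with
    ``per_batch=False``). Batches with fewer than ``min_batch_size`` cells
    are passed through unfiltered with a warning.
    """
    totals = np.asarray(raw.counts.sum(axis=0)).ravel()
    features = np.asarray((raw.counts > 0).sum(axis=0)).ravel()
    mito = raw.mito_fraction()
    batches = (
        raw.cell_meta["batch"].to_numpy()
        if per_batch and "batch" in raw.cell_meta
        else np.zeros(raw.n_cells, dtype=int)
    )
    keep = np.ones(raw.n_cells, dtype=bool)
    reasons = np.array([""] * raw.n_cells, dtype=object)
    thresholds = {}
    for batch in pd.unique(batches):
        sel = batches == batch
        if sel.sum() < min_batch_size:
            warnings.warn(
                f"batch {batch!r} has only {int(sel.sum())} cells; "
                "passed through unfiltered"
            )
            thresholds[str(batch)] = None
            continue
        reads_min = np.median(totals[sel]) - n_mads_reads * _mad(totals[sel], mad_constant)
        feats_min = np.median(features[sel]) - n_mads_features * _mad(features[sel], mad_constant)
        mito_max = np.median(mito[sel]) + n_mads_mito * _mad(mito[sel], mad_constant)
        thresholds[str(batch)] = {
            "reads_min": float(reads_min),
            "features_min": float(feats_min),
            "mito_max": float(mito_max),
        }
        fail_reads = totals < reads_min
        fail_feats = features < feats_min
        fail_mito = mito > mito_max
        for name, fail in (
            ("low_reads", fail_reads), ("low_features", fail_feats),
            ("high_mito", fail_mito),
        ):
            hit = sel & fail
            keep[hit] = False
            reasons[hit] = np.where(
                reasons[hit] == "", name, reasons[hit] + "+" + name
            )
    flags = pd.DataFrame(
        {
            "cell_id": raw.cell_ids,
            "batch": batches,
            "kept": keep,
            "reason": reasons,
        }
    )
    report = QcReport(
        n_cells_in=raw.n_cells,
        n_cells_kept=int(keep.sum()),
        thresholds=thresholds,
        flags=flags,
    )
    return raw.subset_cells(keep), report


def normalise(filtered: CountMatrix) -> CountMatrix:
    """Scale every cell to the median pre-normalisation cell total.

    The size factor of a cell is its total divided by the median total;
    dividing by it equalises column sums while conserving within-cell
    relative proportions exactly.
    """
    totals = np.asarray(filtered.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = filtered.cell_ids[totals == 0]
        raise ValueError(f"cells with zero total counts: {list(bad[:5])}")
    size_factors = totals / np.median(totals)
    scaled = filtered.counts @ sp.diags(1.0 / size_factors)
    return CountMatrix(scaled, filtered.gene_meta.copy(), filtered.cell_meta.copy())


def correct_batches(
    normalised: CountMatrix,
    n_components: int = 50,
    external_embedding: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cells x components embedding with per-batch mean-centring.

    The default is PCA of log2(1 + C) followed by subtraction of each
    batch's mean in PC space — a linear stand-in honouring the pluggable
    contract under which a mutual-nearest-neighbours (or any other)
    correction computed elsewhere can be passed via ``external_embedding``
    (cell order must match; only the row count is checkable here).
    """
    if external_embedding is not None:
        emb = np.asarray(external_embedding, dtype=float)
        if emb.shape[0] != normalised.n_cells:
            raise ValueError(
                f"external embedding has {emb.shape[0]} rows for "
                f"{normalised.n_cells} cells"
            )
        return emb
    X = np.log2(1.0 + normalised.counts.T.toarray())
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, random_state=seed)
    emb = pca.fit_transform(X)
    if "batch" in normalised.cell_meta:
        batches = normalised.cell_meta["batch"].to_numpy()
        if len(pd.unique(batches)) > 1:
            for batch in pd.unique(batches):
                sel = batches == batch
                emb[sel] -= emb[sel].mean(axis=0)
    return emb
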