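"""Core data containers and on-disk formats.

The central object is :class:`CountMatrix`, a sparse gene-by-cell UMI count
matrix with linked per-gene and per-cell metadata tables. It is written to
disk as Matrix Market (``matrix.mtx``) plus two TSV tables (``genes.tsv``,
``cells.tsv``), and can also be read from a 10x-style directory
(``matrix.mtx`` + ``genes.tsv``/``features.tsv`` + ``barcodes.tsv``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

#: The five FACS sort conditions of the mTEC study design.
CONDITIONS = ("TSPAN8+", "TSPAN8-", "GP2+", "GP2-", "unselected")

#: Gene expression categories; the first three together constitute the
#: tissue-restricted genes (TRGs).
GENE_CATEGORIES = (
    "AIRE-dependent",
    "AIRE-enhanced",
    "AIRE-independent TRG",
    "housekeeping",
    "other",
    "unclassified",
)

TRG_CATEGORIES = frozenset(GENE_CATEGORIES[:3])


@dataclass
class CountMatrix:
    """Sparse gene-by-cell counts with aligned metadata.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` sparse matrix of non-negative values. Raw
        matrices hold integer UMI counts; normalised matrices hold reals.
    gene_meta
        DataFrame with one row per gene. Expected columns: ``gene_id``,
        ``chromosome``, ``position_bp``, ``category``; extra columns (e.g.
        gene-set memberships) are carried along untouched.
    cell_meta
        DataFrame with one row per cell. Expected columns: ``cell_id``,
        ``mouse_id``, ``condition``, ``batch``; ``mito_fraction`` is
        optional (treated as zero when absent).
    """

    counts: sp.spmatrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if self.counts.shape[0] != len(self.gene_meta):
            raise ValueError(
                f"gene_meta has {len(self.gene_meta)} rows for "
                f"{self.counts.shape[0]} genes"
            )
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows for "
                f"{self.counts.shape[1]} cells"
            )
        if "condition" in self.cell_meta:
            bad = set(self.cell_meta["condition"]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown conditions: {sorted(bad)}")
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_meta["cell_id"].to_numpy()

    def mito_fraction(self) -> np.ndarray:
        """Per-cell mitochondrial read fraction (zeros when not annotated)."""
        if "mito_fraction" in self.cell_meta:
            return self.cell_meta["mito_fraction"].to_numpy(float)
        return np.zeros(self.n_cells)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the cells in ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[:, index],
            gene_meta=self.gene_meta.copy(),
            cell_meta=self.cell_meta.iloc[index].reset_index(drop=True),
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the genes in ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[index],
            gene_meta=self.gene_meta.iloc[index].reset_index(drop=True),
            cell_meta=self.cell_meta.copy(),
        )

    def detected(self) -> sp.csr_matrix:
        """Boolean sparse matrix of detection (count > 0)."""
        return (self.counts > 0).tocsr()

    def is_trg(self) -> np.ndarray:
        """Boolean mask of tissue-restricted genes (the three AIRE categories)."""
        return self.gene_meta["category"].isin(TRG_CATEGORIES).to_numpy()

    # ---- IO -------------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        """Write as matrix.mtx + genes.tsv + cells.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(out / "matrix.mtx"), self.counts)
        self.gene_meta.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.cell_meta.to_csv(out / "cells.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "CountMatrix":
        """Read a directory written by :meth:`write` or a 10x-style directory.

        A 10x-style directory holds ``matrix.mtx``, a gene table
        (``genes.tsv`` or ``features.tsv``, headerless, id + name columns)
        and ``barcodes.tsv``.
        """
        d = Path(in_dir)
        counts = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")))
        barcodes = d / "barcodes.tsv"
        if barcodes.exists():
            genes_path = d / "genes.tsv"
            if not genes_path.exists():
                genes_path = d / "features.tsv"
            gtab = pd.read_csv(genes_path, sep="\t", header=None)
            gene_meta = pd.DataFrame({"gene_id": gtab.iloc[:, 0]})
            cells = pd.read_csv(barcodes, sep="\t", header=None)
            cell_meta = pd.DataFrame({"cell_id": cells.iloc[:, 0]})
        else:
            gene_meta = pd.read_csv(d / "genes.tsv", sep="\t")
            cell_meta = pd.read_csv(d / "cells.tsv", sep="\t")
        return cls(counts=counts, gene_meta=gene_meta, cell_meta=cell_meta)
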