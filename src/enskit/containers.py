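"""Core in-memory containers shared by all pipeline stages.

Counts are stored genes-as-rows (Matrix Market convention for 10x
depositions); exported tables are cells-as-rows. Mitochondrial genes are
recognised by name prefix (mouse nomenclature ``mt-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MITO_PREFIX = "mt-"

#: sex-specific genes excluded from variable-gene selection
SEX_GENES = ("Xist", "Tsix", "Ddx3y", "Uty", "Kdm5d", "Eif2s3y", "Gm13305", "Gm8730")
#: immediate early genes optionally excluded from variable-gene selection
IEG_GENES = ("Fos", "Jun", "Junb", "Egr1")


@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with identifiers.

    Parameters
    ----------
    X
        Sparse genes x cells matrix of non-negative integer counts.
    genes, cells
        Unique gene / cell identifiers matching the matrix dimensions.
    """

    X: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell identifiers must be unique")

    # ---------------------------------------------------------------- shape
    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    # ------------------------------------------------------------- per-cell
    def umis_per_cell(self) -> np.ndarray:
        """Total UMI count (library size) per cell."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with non-zero counts per cell."""
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        """Per-cell fraction of UMIs from genes whose name starts with *prefix*.

        Returns 0 for cells with zero total counts; the caller decides how
        to treat such cells.
        """
        mito = self.genes.str.lower().str.startswith(prefix.lower())
        total = self.umis_per_cell().astype(float)
        if not mito.any():
            return np.zeros(self.n_cells)
        mito_counts = np.asarray(self.X[np.flatnonzero(mito), :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)
        return frac

    def mito_genes(self, prefix: str = MITO_PREFIX) -> pd.Index:
        return self.genes[self.genes.str.lower().str.startswith(prefix.lower())]

    def cell_metadata(self) -> pd.DataFrame:
        """Standard per-cell QC metadata table (cells as rows)."""
        return pd.DataFrame(
            {
                "total_umis": self.umis_per_cell(),
                "n_genes": self.genes_per_cell(),
                "mito_fraction": self.mito_fraction(),
            },
            index=self.cells,
        )

    # ------------------------------------------------------------ subsetting
    def subset_cells(self, keep) -> "CountMatrix":
        """Subset to cells given by boolean mask, integer positions or names."""
        idx = self._resolve(keep, self.cells)
        return CountMatrix(self.X[:, idx], self.genes, self.cells[idx])

    def subset_genes(self, keep) -> "CountMatrix":
        idx = self._resolve(keep, self.genes)
        return CountMatrix(self.X[idx, :], self.genes[idx], self.cells)

    @staticmethod
    def _resolve(keep, index: pd.Index) -> np.ndarray:
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if keep.shape[0] != len(index):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(keep)
        if keep.dtype.kind in "iu":
            return keep
        return index.get_indexer(keep)

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector across cells for one gene (zeros if absent)."""
        if gene not in self.genes:
            return np.zeros(self.n_cells)
        i = self.genes.get_loc(gene)
        return np.asarray(self.X[i, :].todense()).ravel()

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.X.copy(), self.genes.copy(), self.cells.copy())


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of normalised expression values."""

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    method: str = "log_cpm"
    hvgs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("normalised matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not present")
        return self.values[self.genes.get_loc(gene), :]

    def hvg_submatrix(self) -> "NormalizedMatrix":
        """Restrict to the highly variable genes (for embedding)."""
        idx = self.genes.get_indexer(self.hvgs)
        return NormalizedMatrix(
            self.values[idx, :], self.genes[idx], self.cells, self.method, list(self.hvgs)
        )
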