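"""Count-matrix container and readers/writers for 10x-style MTX triplets and
dense delimited tables.

The genes-by-cells orientation follows the 10x convention (rows = genes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells.

    `values` may be dense or scipy-sparse; `dense()` gives an ndarray view.
    Gene and cell identifiers must be unique.
    """

    values: object  # (n_genes, n_cells) ndarray or sparse
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError(
                f"dimension mismatch: values {self.values.shape}, "
                f"{len(self.gene_ids)} gene ids, {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene IDs are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell IDs are not unique")
        dmin = self.values.min() if n_genes and n_cells else 0
        if dmin < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values.tocsc()[:, idx] if sp.issparse(self.values) else self.values[:, idx]
        return CountMatrix(vals, self.gene_ids, [self.cell_ids[i] for i in idx])

    def subset_genes(self, gene_list) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_list])
        vals = self.values.tocsr()[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return CountMatrix(vals, list(gene_list), self.cell_ids)


def read_mtx_dir(path: str) -> CountMatrix:
    """Read an MTX triplet directory (matrix.mtx, genes.tsv, barcodes.tsv)."""
    mat = mmread(os.path.join(path, "matrix.mtx")).tocsr()
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)
    return CountMatrix(mat, genes.iloc[:, 0].tolist(), barcodes.iloc[:, 0].tolist())


def write_mtx_dir(counts: CountMatrix, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    vals = counts.values if sp.issparse(counts.values) else sp.csr_matrix(counts.values)
    mmwrite(os.path.join(path, "matrix.mtx"), vals.astype(int))
    pd.Series(counts.gene_ids).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_dense(path: str, sep: str | None = None) -> CountMatrix:
    """Read a dense genes-by-cells table (first column = gene IDs)."""
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(df.to_numpy(), df.index.tolist(), df.columns.tolist())


def write_dense(counts: CountMatrix, path: str, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    pd.DataFrame(counts.dense(), index=counts.gene_ids, columns=counts.cell_ids).to_csv(
        path, sep=sep
    )
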