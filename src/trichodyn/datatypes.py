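"""Shared in-memory containers for the hair-regeneration time-course pipeline.

The universal input is a sparse gene x cell integer count matrix
(:class:`CountMatrix`) together with a per-cell metadata table (a pandas
DataFrame with the columns listed in :data:`CELLMETA_COLUMNS`).  Result
objects produced by the analysis stages live in the modules that compute
them; only the containers every stage shares are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Treatment arms of the two-arm design (vehicle vs drug-treated).
GROUPS = ("vehicle", "treated")

#: Sampling days of the regeneration time course: baseline before
#: treatment, priming response, pigmentation onset, anagen accumulation.
DEFAULT_DAYS = (0, 3, 9, 15)

#: Required columns of a cell-metadata table.
CELLMETA_COLUMNS = ("cell_id", "group", "day", "cell_type")

#: Case-insensitive gene-name prefix marking mouse mitochondrial genes.
MITO_PREFIX = "mt-"


def infer_mito_flag(gene_names) -> np.ndarray:
    """Flag mitochondrial genes by the mouse ``mt-`` naming convention."""
    return np.array(
        [str(g).lower().startswith(MITO_PREFIX) for g in gene_names], dtype=bool
    )


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer UMI counts.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` sparse matrix of raw counts.
    gene_names
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    mito_flag
        Boolean per gene; inferred from the ``mt-`` prefix when omitted.
    """

    counts: sp.spmatrix
    gene_names: np.ndarray
    cell_ids: np.ndarray
    mito_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise ValueError("counts must be integral")
        if self.mito_flag is None:
            self.mito_flag = infer_mito_flag(self.gene_names)
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        if self.mito_flag.shape[0] != self.n_genes:
            raise ValueError("mito_flag length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Row indices of ``genes``; raises on unknown names."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_names,
            self.cell_ids[idx],
            self.mito_flag,
        )


def validate_cellmeta(meta: pd.DataFrame, require=CELLMETA_COLUMNS) -> pd.DataFrame:
    """Check the presence of the required metadata columns; returns ``meta``."""
    missing = [c for c in require if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValueError("cell metadata contains duplicate cell_id entries")
    return meta
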