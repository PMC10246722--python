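"""Quality control, log-normalization and marker-based cell-type annotation.

QC follows the study's cell-level thresholds: 500-5,000 detected genes per
cell (closed interval) and at most 20% mitochondrial counts.  Cell identity
is assigned by scoring each cell against a table of cell-type marker genes
(mean of across-cell z-scored marker expression, argmax over types), which
replaces graph clustering for data where identity is either ground-truthed
(synthetic) or user-supplied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix

__all__ = [
    "DEFAULT_MARKERS",
    "qc_filter",
    "normalize_log",
    "annotate_by_markers",
    "read_marker_table",
]

#: The study's 15 mouse-skin cell types and their canonical markers:
#: epidermal keratinocytes (BC basal, MC mitotic basal, SC spinous,
#: GC granular), hair-follicle keratinocytes (UHF upper HF, HFB bulge,
#: GL germ layer, SG sebaceous gland), vascular (EC endothelial,
#: SM smooth muscle), FB fibroblast, and immune cells (Mac1/Mac2
#: macrophages, LC Langerhans, TC T cell).
DEFAULT_MARKERS = {
    "BC": ["Krt14"],
    "MC": ["Mki67"],
    "SC": ["Krt1"],
    "GC": ["Flg2"],
    "UHF": ["Krt79"],
    "HFB": ["Lhx2", "Cd34"],
    "GL": ["Cdh3", "Lef1"],
    "SG": ["Scd1"],
    "EC": ["Pecam1"],
    "SM": ["Acta2"],
    "FB": ["Pdgfra"],
    "Mac1": ["Cd68"],
    "Mac2": ["Cd163"],
    "LC": ["Cd207"],
    "TC": ["Cd3g"],
}


def qc_filter(matrix: CountMatrix, meta: pd.DataFrame | None = None, *,
              min_genes: int = 500, max_genes: int = 5000,
              max_mito: float = 0.20, doublet_mask=None):
    """Filter cells on detected-gene count and mitochondrial proportion.

    A cell is retained iff ``min_genes <= n_genes_detected <= max_genes``
    (both bounds inclusive) and ``mito_pct <= max_mito``.  An optional
    boolean ``doublet_mask`` (True = doublet, from an external caller)
    removes additional cells.  Returns ``(filtered CountMatrix, cell
    metadata with QC covariates, report dict)``; removing every cell is
    reported as a warning, not an error.
    """
    counts = matrix.counts.tocsc()
    n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    libsize = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito_counts = np.asarray(counts[matrix.mito_flag].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        mito_pct = np.where(libsize > 0, mito_counts / np.maximum(libsize, 1), 0.0)

    low = n_detected < min_genes
    high = n_detected > max_genes
    mito_fail = mito_pct > max_mito
    keep = ~(low | high | mito_fail)
    if doublet_mask is not None:
        doublet_mask = np.asarray(doublet_mask, dtype=bool)
        keep &= ~doublet_mask
    report = {
        "n_input": matrix.n_cells,
        "n_retained": int(keep.sum()),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_high_mito": int(mito_fail.sum()),
        "removed_doublets": int(doublet_mask.sum()) if doublet_mask is not None else 0,
        "thresholds": {
            "min_genes": min_genes, "max_genes": max_genes, "max_mito": max_mito,
            "bounds": "closed interval on genes; mito <= max_mito",
        },
        "note": "cells failing several criteria are counted under each",
    }
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    filtered = matrix.subset_cells(keep)
    qc_cols = pd.DataFrame({
        "cell_id": matrix.cell_ids[keep],
        "n_genes_detected": n_detected[keep],
        "mito_pct": mito_pct[keep],
    })
    if meta is not None:
        out_meta = meta.merge(qc_cols, on="cell_id", how="right")
    else:
        out_meta = qc_cols
    out_meta = out_meta.reset_index(drop=True)
    return filtered, out_meta, report


def normalize_log(matrix: CountMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size log-normalization: ``ln(count * scale / libsize + 1)``.

    Zeros map to zero, so sparsity is preserved.  Cells with zero library
    size are rejected (their normalization is undefined).
    """
    libsize = matrix.library_sizes().astype(float)
    zero = libsize == 0
    if zero.any() and matrix.n_genes > 0:
        bad = list(matrix.cell_ids[zero][:5])
        raise ValueError(f"zero library size for cells {bad}; filter them first")
    out = matrix.counts.tocsc().astype(np.float64)
    if out.nnz:
        sf = scale / libsize
        out.data *= np.repeat(sf, np.diff(out.indptr))
        np.log1p(out.data, out=out.data)
    return out.tocsr()


def read_marker_table(path) -> dict:
    """Read a two-column TSV (cell_type, gene) into a marker dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "gene"])
    table: dict = {}
    for r in df.itertuples():
        table.setdefault(str(r.cell_type), []).append(str(r.gene))
    return table


def annotate_by_markers(lognorm, gene_names, markers: dict, cell_ids=None):
    """Assign each cell the marker-defined type with the highest score.

    Each type's score for a cell is the mean, over that type's resolvable
    markers, of the marker's across-cell z-scored expression.  The label is
    the argmax; ties break deterministically by marker-table order, and the
    confidence ``margin`` is top score minus runner-up.  Types with no
    marker in the gene universe are dropped with a warning.

    Returns a DataFrame (cell_id, cell_type, margin, low_confidence).
    """
    gene_names = np.asarray(gene_names, dtype=object)
    lookup = {g: i for i, g in enumerate(gene_names)}
    resolved, dropped = {}, []
    for ct, genes in markers.items():
        found = [g for g in genes if g in lookup]
        if found:
            resolved[ct] = found
        else:
            dropped.append(ct)
    if dropped:
        warnings.warn(f"cell types with no resolvable markers dropped: {dropped}",
                      stacklevel=2)
    if not resolved:
        raise ValueError("no cell type has a resolvable marker gene")

    marker_genes = sorted({g for gs in resolved.values() for g in gs},
                          key=lambda g: lookup[g])
    idx = np.array([lookup[g] for g in marker_genes])
    X = lognorm[idx]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / sd, 0.0)
    row_of = {g: i for i, g in enumerate(marker_genes)}
    types = list(resolved)
    scores = np.stack([
        Z[[row_of[g] for g in resolved[ct]]].mean(axis=0) for ct in types
    ])  # (n_types, n_cells)
    best = np.argmax(scores, axis=0)  # first max wins: table-order tie-break
    top = scores[best, np.arange(scores.shape[1])]
    runner = np.partition(scores, -2, axis=0)[-2] if len(types) > 1 else np.full_like(top, -np.inf)
    margin = top - runner if len(types) > 1 else np.zeros_like(top)
    if cell_ids is None:
        cell_ids = np.arange(scores.shape[1])
    return pd.DataFrame({
        "cell_id": np.asarray(cell_ids, dtype=object),
        "cell_type": [types[b] for b in best],
        "margin": margin,
        "low_confidence": margin <= 1e-12,
    })
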