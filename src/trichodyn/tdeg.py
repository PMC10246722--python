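"""Time-dependent differentially expressed genes (TDEGs) and kinetic modules.

The procedure mirrors the customized time-ordering analysis of the hair
regeneration time course:

1. for every pair of sampling days within a treatment arm and cell type,
   call per-gene differential expression with a two-sided Wilcoxon
   rank-sum test and the Seurat-style natural-log fold change;
2. BH-adjust within each (cell type, arm, day-pair) family and keep genes
   with ``|avg_logFC| > 0.25`` and ``p_val_adj < 0.05`` in at least one
   pair (the TDEG set);
3. fit each TDEG's expression as a natural-cubic-spline function of the
   continuous day coordinate and evaluate on a dense grid;
4. Ward-cluster (ward.D2 convention: unsquared Euclidean input) the
   row-standardized curves into four kinetic modules;
5. label each module's mean curve with its canonical kinetic shape
   (decreasing / bell / valley / increasing) by maximum-correlation
   bipartite matching and renumber modules 1-4 accordingly, so module ids
   are comparable across cell types;
6. intersect module membership across cell types to find high-frequency
   shared TDEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .synthgen import MODULE_SHAPES, kinetic_curve

__all__ = [
    "de_test",
    "bh_adjust",
    "find_time_degs",
    "natural_spline_basis",
    "smooth_time_curves",
    "SmoothedCurves",
    "ModuleAssignment",
    "cluster_kinetic_modules",
    "label_module_shapes",
    "shared_tdeg_genes",
]


# ---------------------------------------------------------------------------
# differential expression engine
# ---------------------------------------------------------------------------

def _avg_logfc(a: np.ndarray, b: np.ndarray) -> float:
    """Seurat-style natural-log fold change on log-normalized values:
    ``ln[(mean(expm1 a) + 1) / (mean(expm1 b) + 1)]``."""
    return float(np.log((np.expm1(a).mean() + 1.0) / (np.expm1(b).mean() + 1.0)))


def de_test(expr_a, expr_b):
    """Two-sided Wilcoxon rank-sum test plus average log fold change.

    The p-value is exact (full enumeration of the rank-sum distribution)
    when both groups have at most 8 observations and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections is used.  Returns ``(p_val, avg_logFC)``.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue), _avg_logfc(a, b)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p-values for gene x cell blocks,
    sharing the method selection of :func:`de_test`."""
    nA, nB = A.shape[1], B.shape[1]
    if nA <= 8 and nB <= 8:
        return np.array([de_test(A[i], B[i])[0] for i in range(A.shape[0])])
    res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic",
                             use_continuity=True, axis=1)
    return np.asarray(res.pvalue, dtype=float)


def find_time_degs(lognorm, meta: pd.DataFrame, gene_names, *,
                   cell_type=None, group="treated", days=None,
                   lfc_min: float = 0.25, padj_max: float = 0.05,
                   pairs: str = "all", min_cells: int = 3):
    """Union-over-day-pairs TDEG calling for one (cell type, arm).

    For every configured day pair a per-gene rank-sum test is run and BH
    adjustment applied within that (cell type, arm, pair) family; a gene
    is a TDEG iff ``|avg_logFC| > lfc_min`` **and** ``p_val_adj < padj_max``
    (strict inequalities) in at least one pair.  ``pairs`` is ``"all"``
    (all unordered pairs) or ``"consecutive"``.  Day points with fewer
    than ``min_cells`` cells are skipped and recorded in the report.

    Returns ``(tdeg_genes, records DataFrame, report dict)``.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    mask = meta["group"].to_numpy() == group
    if cell_type is not None:
        mask &= meta["cell_type"].to_numpy() == cell_type
    sub_meta = meta.loc[mask]
    day_values = sorted(set(sub_meta["day"])) if days is None else sorted(days)
    if pairs == "all":
        day_pairs = [(a, b) for i, a in enumerate(day_values)
                     for b in day_values[i + 1:]]
    elif pairs == "consecutive":
        day_pairs = list(zip(day_values, day_values[1:]))
    else:
        raise ValueError(f"pairs must be 'all' or 'consecutive', got {pairs!r}")

    X = lognorm[:, np.flatnonzero(mask)]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    day_arr = sub_meta["day"].to_numpy()
    usable = {d: np.flatnonzero(day_arr == d) for d in day_values}
    n_usable = sum(len(v) >= min_cells for v in usable.values())
    if n_usable < 2:
        raise ValueError(
            f"need >= 2 time points with >= {min_cells} cells for "
            f"cell_type={cell_type!r}, group={group!r}"
        )

    frames, skipped = [], []
    for da, db in day_pairs:
        ia, ib = usable[da], usable[db]
        if len(ia) < min_cells or len(ib) < min_cells:
            skipped.append((da, db))
            continue
        A, B = X[:, ia], X[:, ib]
        pvals = _rank_sum_matrix(A, B)
        ea, eb = np.expm1(A).mean(axis=1), np.expm1(B).mean(axis=1)
        lfc = np.log((ea + 1.0) / (eb + 1.0))
        frames.append(pd.DataFrame({
            "gene": gene_names,
            "cell_type": cell_type if cell_type is not None else "all",
            "group": group,
            "dayA": da,
            "dayB": db,
            "avg_logFC": lfc,
            "p_val": pvals,
            "p_val_adj": bh_adjust(pvals),
        }))
    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["gene", "cell_type", "group", "dayA",
                                          "dayB", "avg_logFC", "p_val",
                                          "p_val_adj"]))
    hit = records[(records["avg_logFC"].abs() > lfc_min)
                  & (records["p_val_adj"] < padj_max)]
    hit_set = set(hit["gene"])
    tdeg_genes = [g for g in gene_names if g in hit_set]
    report = {
        "cell_type": cell_type, "group": group,
        "n_pairs_tested": len(frames), "skipped_pairs": skipped,
        "n_tdegs": len(tdeg_genes),
        "thresholds": {"lfc_min": lfc_min, "padj_max": padj_max,
                       "inequalities": "strict"},
    }
    return tdeg_genes, records, report


# ---------------------------------------------------------------------------
# spline smoothing along the time axis
# ---------------------------------------------------------------------------

def natural_spline_basis(x, df: int, *, knots=None):
    """Natural cubic spline regression basis with ``df`` columns.

    Truncated-power construction of the ns() basis: boundary knots at
    min/max of ``x``, ``df - 1`` interior knots at quantiles; the basis is
    linear beyond the boundary knots and, together with an intercept,
    reproduces affine functions exactly.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None].copy()
    if knots is None:
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(np.unique(x), qs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("spline knots must be distinct; reduce df")
    K = knots.size  # df + 1 knots -> df basis columns

    def d(k):
        num = (np.clip(x - knots[k], 0, None) ** 3
               - np.clip(x - knots[-1], 0, None) ** 3)
        return num / (knots[-1] - knots[k])

    d_last = d(K - 2)
    cols = [x] + [d(k) - d_last for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass
class SmoothedCurves:
    """Spline-fitted expression curves for a gene set on a dense time grid.

    ``values`` is genes x grid (raw fit); ``standardized`` the per-gene
    mean-0/sd-1 copy used for clustering (constant genes are zeroed and
    listed in ``constant_genes``).
    """

    genes: list
    grid: np.ndarray
    values: np.ndarray
    standardized: np.ndarray
    constant_genes: list = field(default_factory=list)
    axis_name: str = "day"


def smooth_time_curves(lognorm, time, genes, gene_names, *,
                       df: int = 3, n_grid: int = 100,
                       axis_name: str = "day") -> SmoothedCurves:
    """Fit per-gene natural-cubic-spline curves of expression vs ``time``.

    ``time`` is the continuous per-cell coordinate (sampling day, or
    pseudotime when reused by the trajectory stage).  Each gene is
    regressed by least squares on an intercept plus a ``df``-column
    natural spline basis and evaluated on ``n_grid`` equally spaced points
    spanning the observed time range.
    """
    time = np.asarray(time, dtype=float)
    distinct = np.unique(time)
    if distinct.size < 3:
        raise ValueError("need >= 3 distinct time values for spline smoothing")
    if df >= distinct.size:
        raise ValueError(
            f"df={df} must be < number of distinct time values ({distinct.size})"
        )
    gene_names = np.asarray(gene_names, dtype=object)
    lookup = {g: i for i, g in enumerate(gene_names)}
    genes = list(genes)
    idx = np.array([lookup[g] for g in genes], dtype=int)
    Y = lognorm[idx]
    Y = Y.toarray() if sp.issparse(Y) else np.asarray(Y, dtype=float)

    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(distinct, qs)
    basis = natural_spline_basis(time, df, knots=knots)
    design = np.column_stack([np.ones(time.size), basis])
    coef, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    grid = np.linspace(distinct[0], distinct[-1], n_grid)
    gbasis = np.column_stack(
        [np.ones(n_grid), natural_spline_basis(grid, df, knots=knots)]
    )
    values = (gbasis @ coef).T  # genes x grid

    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    const = sd.ravel() < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = np.where(const[:, None], 0.0, (values - mean) / sd)
    return SmoothedCurves(
        genes=genes, grid=grid, values=values, standardized=standardized,
        constant_genes=[g for g, c in zip(genes, const) if c],
        axis_name=axis_name,
    )


# ---------------------------------------------------------------------------
# kinetic-module clustering and shape labelling
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """Gene -> kinetic module partition for one (cell type, arm).

    ``module_of`` holds module ids per gene; after
    :func:`label_module_shapes` the ids are renumbered by canonical shape
    (1 decreasing, 2 bell, 3 valley, 4 increasing) so they are comparable
    across cell types, and ``shape_of_module`` maps id -> shape label.
    """

    cell_type: str
    group: str
    genes: list
    module_of: np.ndarray
    grid: np.ndarray
    mean_curves: dict
    shape_of_module: dict = field(default_factory=dict)
    shape_correlations: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "cell_type": self.cell_type,
            "group": self.group,
            "module": self.module_of,
            "shape": [self.shape_of_module.get(int(m), "") for m in self.module_of],
        })


def cluster_kinetic_modules(curves: SmoothedCurves, k: int = 4, *,
                            cell_type: str = "all",
                            group: str = "treated") -> ModuleAssignment:
    """Ward-cluster standardized curves into ``k`` kinetic modules.

    Agglomerative hierarchical clustering with Euclidean distance and Ward
    variance-minimization linkage on unsquared distances (the hclust
    ward.D2 convention), tree cut into ``k`` flat clusters.  Deterministic
    for a given gene order; raw cluster ids are arbitrary until
    :func:`label_module_shapes` renumbers them by shape.
    """
    n = len(curves.genes)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be between 1 and the number of genes ({n})")
    if k == 1 or n == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(curves.standardized, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust").astype(int)
    mean_curves = {
        int(m): curves.standardized[labels == m].mean(axis=0)
        for m in np.unique(labels)
    }
    return ModuleAssignment(
        cell_type=cell_type, group=group, genes=list(curves.genes),
        module_of=labels, grid=curves.grid.copy(), mean_curves=mean_curves,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def canonical_shape_curves(grid: np.ndarray, group: str = "treated",
                           amplitude: float = 4.0) -> dict:
    """Standardized canonical template curves on ``grid`` for the four
    kinetic shapes."""
    day_max = float(grid[-1]) if grid[-1] > 0 else 1.0
    plateau = day_max / 5.0
    return {
        MODULE_SHAPES[m]: _standardize(
            kinetic_curve(m, grid, group, amplitude, day_max=day_max,
                          plateau_day=plateau)
        )
        for m in (1, 2, 3, 4)
    }


def label_module_shapes(assignment: ModuleAssignment, *,
                        amplitude: float = 4.0) -> ModuleAssignment:
    """Match module mean curves to the four canonical kinetic shapes.

    Computes the Pearson correlation of every module mean curve with every
    canonical template and solves the 4x4 maximum-total-correlation
    bipartite matching, so the shape assignment is bijective.  Modules are
    renumbered to the canonical ordering (1 decreasing, 2 bell, 3 valley,
    4 increasing) in place of the arbitrary tree-cut labels.
    """
    raw_ids = sorted(assignment.mean_curves)
    if len(raw_ids) != 4:
        raise ValueError(
            f"shape labelling requires exactly 4 modules, got {len(raw_ids)}"
        )
    templates = canonical_shape_curves(assignment.grid, assignment.group,
                                       amplitude)
    shape_names = list(MODULE_SHAPES.values())  # canonical order
    corr = np.zeros((4, 4))
    for i, m in enumerate(raw_ids):
        mc = assignment.mean_curves[m]
        if not np.all(np.isfinite(mc)):
            raise ValueError(f"module {m} mean curve contains non-finite values")
        mcs = _standardize(mc)
        for j, s in enumerate(shape_names):
            t = templates[s]
            corr[i, j] = float(np.mean(mcs * t)) if mcs.any() and t.any() else 0.0
    rows, cols = linear_sum_assignment(-corr)
    new_id_of_raw = {raw_ids[i]: int(cols[np.flatnonzero(rows == i)[0]]) + 1
                     for i in range(4)}
    new_labels = np.array([new_id_of_raw[int(m)] for m in assignment.module_of])
    new_means = {new_id_of_raw[m]: assignment.mean_curves[m] for m in raw_ids}
    return ModuleAssignment(
        cell_type=assignment.cell_type, group=assignment.group,
        genes=assignment.genes, module_of=new_labels, grid=assignment.grid,
        mean_curves=new_means,
        shape_of_module={i + 1: s for i, s in enumerate(shape_names)},
        shape_correlations=corr,
    )


def shared_tdeg_genes(assignments, module_id: int, min_cell_types: int):
    """High-frequency TDEGs: genes assigned to ``module_id`` in at least
    ``min_cell_types`` cell types (inclusive threshold).

    ``assignments`` maps cell type -> shape-renumbered
    :class:`ModuleAssignment`.  Returns a DataFrame (gene, n_cell_types)
    sorted by count descending, then gene name.
    """
    if module_id not in MODULE_SHAPES:
        raise ValueError(f"unknown module id: {module_id!r} (expected 1-4)")
    counts: dict = {}
    for asg in assignments.values():
        for g, m in zip(asg.genes, asg.module_of):
            if int(m) == module_id:
                counts[g] = counts.get(g, 0) + 1
    rows = [(g, c) for g, c in counts.items() if c >= min_cell_types]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["gene", "n_cell_types"])
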