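"""Per-cell gene-set AUC scoring and weighted-KS gene-set enrichment.

``aucell_score`` reimplements ranking-based recovery-curve scoring: per
cell, all genes are ranked by expression (descending, average ranks for
ties), the recovery curve counts how many set members appear within the
top ``maxRank = ceil(top_fraction * G)`` positions, and the score is the
normalized area under that curve — 1 when the set occupies the very top
of the ranking, 0 when no member appears within ``maxRank``.

``gsea_enrichment`` implements the classical weighted Kolmogorov-Smirnov
enrichment statistic: hits advance the running sum proportionally to
``|metric|^p`` (normalized over set hits), misses decrement it by
``1/(G - m)``; ES is the maximal deviation from zero, NES normalizes by
the sign-matched permutation null, and FDR follows the sign-matched
NES-ratio convention across tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .tdeg import de_test

__all__ = [
    "GeneSet",
    "read_gmt",
    "aucell_score",
    "score_gene_sets",
    "EnrichmentResult",
    "gsea_enrichment",
    "gsea_batch",
    "score_contrast",
]


@dataclass
class GeneSet:
    """A named set of genes (e.g. cell cycle, BMP pathway, Foxc1 targets)."""

    name: str
    genes: list
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen, uniq = set(), []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        self.genes = uniq


def read_gmt(path) -> list:
    """Read GMT gene sets (name, description, members...; tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(name=parts[0], description=parts[1],
                                genes=[g for g in parts[2:] if g]))
    return sets


# ---------------------------------------------------------------------------
# recovery-curve AUC scoring
# ---------------------------------------------------------------------------

def aucell_score(expr, gene_names, gene_set: GeneSet, *,
                 top_fraction: float = 0.05, cell_ids=None,
                 tie_rng=None) -> pd.Series:
    """Per-cell recovery-curve AUC of one gene set, in [0, 1].

    ``expr`` is genes x cells (log-normalized or raw — the score is rank
    based, hence invariant to per-cell monotone transforms).  Ties get
    average ranks by default (deterministic); pass a numpy Generator as
    ``tie_rng`` for randomized tie-breaking sensitivity checks.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    G = gene_names.size
    lookup = {g: i for i, g in enumerate(gene_names)}
    members = [g for g in gene_set.genes if g in lookup]
    missing = [g for g in gene_set.genes if g not in lookup]
    if not members:
        raise ValueError(
            f"no member of gene set {gene_set.name!r} found in the gene "
            f"universe; missing: {missing}"
        )
    X = expr.toarray() if sp.issparse(expr) else np.asarray(expr, dtype=float)
    if tie_rng is not None:
        X = X + tie_rng.uniform(0, 1e-9, size=X.shape)
    ranks = stats.rankdata(-X, axis=0, method="average")  # genes x cells
    max_rank = int(np.ceil(top_fraction * G))
    m = len(members)
    k = min(m, max_rank)
    r = np.ceil(ranks[[lookup[g] for g in members]]).astype(int)  # m x cells
    contrib = np.clip(max_rank - r + 1, 0, None)
    raw = contrib.sum(axis=0).astype(float)
    denom = k * (k + 1) / 2 + (max_rank - k) * k
    scores = np.clip(raw / denom, 0.0, 1.0)
    index = (np.asarray(cell_ids, dtype=object) if cell_ids is not None
             else np.arange(scores.size))
    return pd.Series(scores, index=index, name=gene_set.name)


def score_gene_sets(expr, gene_names, gene_sets, *, top_fraction: float = 0.05,
                    cell_ids=None) -> pd.DataFrame:
    """Cells x gene-sets AUC score matrix."""
    cols = {}
    for gs in gene_sets:
        cols[gs.name] = aucell_score(expr, gene_names, gs,
                                     top_fraction=top_fraction,
                                     cell_ids=cell_ids)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# weighted-KS enrichment
# ---------------------------------------------------------------------------

def _running_es(metric_sorted: np.ndarray, hit_mask: np.ndarray,
                p: float) -> float:
    """Signed enrichment score: maximal deviation of the running sum."""
    G = metric_sorted.size
    m = int(hit_mask.sum())
    w = np.abs(metric_sorted) ** p
    nr = w[hit_mask].sum()
    steps = np.where(
        hit_mask,
        (w / nr) if nr > 0 else (1.0 / m),
        -1.0 / (G - m),
    )
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class EnrichmentResult:
    """Weighted-KS enrichment of one gene set against a ranked list."""

    name: str
    es: float
    nes: float
    p_val: float
    fdr: float
    n_perm: int
    seed: int | None
    null_es: np.ndarray = field(repr=False, default=None)  # type: ignore


def gsea_enrichment(metric: pd.Series, gene_set: GeneSet, *, p: float = 1.0,
                    n_perm: int = 1000, seed: int = 0) -> EnrichmentResult:
    """Enrichment of ``gene_set`` in a signed gene ranking.

    ``metric`` maps gene -> ranking statistic (e.g. the between-arm
    avg_logFC); genes are sorted descending.  The null distribution comes
    from ``n_perm`` random gene-label assignments of the set positions,
    NES = ES / mean(|null ES| of the matching sign), and the nominal p is
    the sign-matched permutation tail fraction with +1 smoothing (floor
    ``1/(n_perm + 1)``).  The single-set FDR equals the nominal p; use
    :func:`gsea_batch` for the cross-set NES-ratio FDR.
    """
    metric = metric.astype(float)
    if not np.all(np.isfinite(metric.to_numpy())):
        raise ValueError("ranking metric must be finite for all genes")
    order = np.argsort(-metric.to_numpy(), kind="stable")
    genes_sorted = metric.index.to_numpy()[order]
    metric_sorted = metric.to_numpy()[order]
    G = genes_sorted.size
    members = set(gene_set.genes) & set(genes_sorted)
    m = len(members)
    if m == 0:
        raise ValueError(f"no member of {gene_set.name!r} in the ranking")
    if m == G:
        raise ValueError("gene set equals the whole universe")
    hit = np.isin(genes_sorted, list(members))
    es = _running_es(metric_sorted, hit, p)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pos = rng.choice(G, size=m, replace=False)
        mask = np.zeros(G, dtype=bool)
        mask[pos] = True
        null[b] = _running_es(metric_sorted, mask, p)
    same = null[null >= 0] if es >= 0 else null[null < 0]
    denom = np.abs(same).mean() if same.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    n_same = same.size
    p_val = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + n_same)
    return EnrichmentResult(name=gene_set.name, es=es, nes=nes, p_val=p_val,
                            fdr=p_val, n_perm=n_perm, seed=seed, null_es=null)


def gsea_batch(metric: pd.Series, gene_sets, *, p: float = 1.0,
               n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Enrichment of several gene sets with sign-matched NES-ratio FDR.

    For a set with NES* >= 0, FDR is the fraction of all pooled null NES
    >= NES* divided by the fraction of observed NES >= NES* (clipped to
    [0, 1]); symmetrically for negative NES*.  With a single set FDR is
    the nominal p.
    """
    results = [
        gsea_enrichment(metric, gs, p=p, n_perm=n_perm, seed=seed + i)
        for i, gs in enumerate(gene_sets)
    ]
    if len(results) > 1:
        null_nes = []
        for r in results:
            pos, neg = r.null_es[r.null_es >= 0], r.null_es[r.null_es < 0]
            mp = pos.mean() if pos.size else 1.0
            mn = np.abs(neg).mean() if neg.size else 1.0
            null_nes.append(np.where(r.null_es >= 0, r.null_es / mp,
                                     r.null_es / mn))
        null_nes = np.concatenate(null_nes)
        obs = np.array([r.nes for r in results])
        for r in results:
            if r.nes >= 0:
                num = np.mean(null_nes >= r.nes)
                den = np.mean(obs >= r.nes)
            else:
                num = np.mean(null_nes <= r.nes)
                den = np.mean(obs <= r.nes)
            r.fdr = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
    return pd.DataFrame([{
        "gene_set": r.name, "ES": r.es, "NES": r.nes, "p_val": r.p_val,
        "FDR": r.fdr, "n_perm": r.n_perm,
    } for r in results])


def score_contrast(scores: pd.Series, meta: pd.DataFrame, *,
                   strata=("cell_type",), group_col: str = "group",
                   arms=("vehicle", "treated")) -> pd.DataFrame:
    """Stratified summaries of per-cell set scores with a between-arm test.

    ``scores`` is indexed by cell_id.  Per (stratum, arm): n, median, IQR;
    per stratum: a rank-sum p-value between the two arms (using the same
    test engine as differential expression), omitted and flagged when an
    arm has fewer than two cells.
    """
    df = meta.copy()
    df["_score"] = scores.loc[df["cell_id"]].to_numpy()
    strata = list(strata)
    rows = []
    keys = df.groupby(strata, sort=True).groups if strata else {(): df.index}
    for key, idx in keys.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = df.loc[idx]
        vals = {arm: sub.loc[sub[group_col] == arm, "_score"].to_numpy()
                for arm in arms}
        testable = all(v.size >= 2 for v in vals.values())
        p = de_test(vals[arms[1]], vals[arms[0]])[0] if testable else np.nan
        for arm in arms:
            v = vals[arm]
            row = dict(zip(strata, key))
            row.update({
                "group": arm, "n": v.size,
                "median": float(np.median(v)) if v.size else np.nan,
                "iqr": float(np.subtract(*np.percentile(v, [75, 25])))
                        if v.size else np.nan,
                "p_between_arms": p,
                "tested": testable,
            })
            rows.append(row)
    return pd.DataFrame(rows)
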