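"""Ligand-receptor crosstalk scoring and the arm-vs-arm event-count contrast.

Within one treatment arm, an interaction between a sender and receiver
cell type through a ligand-receptor pair is scored as the product of
Tukey trimeans of ligand expression in the sender population and receptor
expression in the receiver population.  Significance comes from shuffling
cell-type labels within the arm (preserving the arm's expression
distribution) and counting permuted scores at least as large as the
observed one.  The treatment contrast counts, per (sender, receiver),
significant pairs in the treated arm minus the vehicle arm.

This is a deliberately transparent replacement for mass-action
communication models: it keeps the testable contract the analysis needs —
per-pair, per-arm significance and the differential event count — without
multi-subunit receptor or pathway aggregation machinery (complex database
entries must be pre-split; unresolvable genes are skipped with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LRPair",
    "read_lr_pairs",
    "trimean",
    "lr_score_test",
    "score_arm",
    "interaction_delta",
]


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor gene pair with an optional pathway tag."""

    ligand: str
    receptor: str
    pathway: str = ""


def read_lr_pairs(path) -> list:
    """Read a ligand-receptor pair table (TSV: ligand, receptor[, pathway])."""
    df = pd.read_csv(path, sep="\t")
    low = {c.lower(): c for c in df.columns}
    if "ligand" not in low or "receptor" not in low:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["ligand", "receptor", "pathway"])
        low = {c: c for c in df.columns}
    pairs = []
    for _, r in df.iterrows():
        pw = ""
        if "pathway" in low and pd.notna(r[low["pathway"]]):
            pw = str(r[low["pathway"]])
        pairs.append(LRPair(str(r[low["ligand"]]), str(r[low["receptor"]]), pw))
    return pairs


def trimean(values) -> float:
    """Tukey trimean (Q1 + 2 Q2 + Q3) / 4 with linear-interpolation
    (type-7) quantiles."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("trimean of an empty sample is undefined")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float((q1 + 2 * q2 + q3) / 4.0)


@dataclass
class LRResult:
    """Scored ligand-receptor interaction for one arm and type pair."""

    arm: str
    sender: str
    receiver: str
    ligand: str
    receptor: str
    score: float
    p_val: float
    significant: bool


def _dense_rows(lognorm, idx):
    X = lognorm[idx]
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def lr_score_test(lognorm, meta: pd.DataFrame, gene_names, pair: LRPair,
                  sender: str, receiver: str, *, arm: str = "treated",
                  n_perm: int = 100, alpha: float = 0.05, seed: int = 0,
                  label_col: str = "cell_type") -> LRResult:
    """Permutation test of one pair between one sender and receiver type.

    ``score = trimean(ligand | sender) * trimean(receptor | receiver)``;
    the null shuffles cell-type labels within the arm, and
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.  Significant iff
    ``p < alpha`` and ``score > 0``.
    """
    table = score_arm(lognorm, meta, gene_names, [pair], arm=arm,
                      senders=[sender], receivers=[receiver], n_perm=n_perm,
                      alpha=alpha, seed=seed, label_col=label_col)
    if table.empty:
        raise ValueError(
            f"pair {pair.ligand}->{pair.receptor} unresolvable or "
            f"{sender!r}/{receiver!r} empty in arm {arm!r}"
        )
    r = table.iloc[0]
    return LRResult(arm=arm, sender=sender, receiver=receiver,
                    ligand=pair.ligand, receptor=pair.receptor,
                    score=float(r["score"]), p_val=float(r["p_val"]),
                    significant=bool(r["significant"]))


def score_arm(lognorm, meta: pd.DataFrame, gene_names, pairs, *,
              arm: str, senders=None, receivers=None, n_perm: int = 100,
              alpha: float = 0.05, seed: int = 0,
              label_col: str = "cell_type") -> pd.DataFrame:
    """Score every (sender, receiver, pair) combination within one arm.

    One set of ``n_perm`` label shuffles is shared by all combinations, so
    the per-arm table is internally consistent and cheap to compute.
    Pairs with a gene missing from the universe are skipped with a warning.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    lookup = {g: i for i, g in enumerate(gene_names)}
    usable, skipped = [], []
    for p in pairs:
        if p.ligand in lookup and p.receptor in lookup:
            usable.append(p)
        else:
            skipped.append((p.ligand, p.receptor))
    if skipped:
        warnings.warn(f"skipped pairs with unresolvable genes: {skipped[:10]}"
                      + ("..." if len(skipped) > 10 else ""), stacklevel=2)
    mask = meta["group"].to_numpy() == arm
    labels = meta.loc[mask, label_col].to_numpy()
    types = sorted(pd.unique(labels))
    senders = types if senders is None else list(senders)
    receivers = types if receivers is None else list(receivers)
    genes = sorted({p.ligand for p in usable} | {p.receptor for p in usable},
                   key=lambda g: lookup[g])
    if not usable or not types:
        return pd.DataFrame(columns=["arm", "sender", "receiver", "ligand",
                                     "receptor", "pathway", "score", "p_val",
                                     "significant"])
    X = _dense_rows(lognorm[:, np.flatnonzero(mask)],
                    np.array([lookup[g] for g in genes]))
    row_of = {g: i for i, g in enumerate(genes)}

    def trimeans_by_type(lab):
        out = {}
        for t in types:
            cols = np.flatnonzero(lab == t)
            if cols.size:
                q1, q2, q3 = np.quantile(X[:, cols], [0.25, 0.5, 0.75], axis=1)
                out[t] = (q1 + 2 * q2 + q3) / 4.0
        return out

    obs_tm = trimeans_by_type(labels)
    rng = np.random.default_rng(seed)
    null_tm = []
    for _ in range(n_perm):
        null_tm.append(trimeans_by_type(rng.permutation(labels)))

    rows = []
    for s in senders:
        for r in receivers:
            if s not in obs_tm or r not in obs_tm:
                continue
            for p in usable:
                li, ri = row_of[p.ligand], row_of[p.receptor]
                score = float(obs_tm[s][li] * obs_tm[r][ri])
                exceed = sum(
                    1 for tm in null_tm
                    if s in tm and r in tm and tm[s][li] * tm[r][ri] >= score
                )
                pv = (1 + exceed) / (n_perm + 1)
                rows.append({
                    "arm": arm, "sender": s, "receiver": r,
                    "ligand": p.ligand, "receptor": p.receptor,
                    "pathway": p.pathway, "score": score, "p_val": pv,
                    "significant": bool(pv < alpha and score > 0),
                })
    return pd.DataFrame(rows)


def interaction_delta(results_vehicle: pd.DataFrame,
                      results_treated: pd.DataFrame):
    """Differential event counts: treated minus vehicle significant pairs.

    Both tables must cover the same (sender, receiver, ligand, receptor)
    universe.  Returns ``(delta DataFrame, union DataFrame)`` where delta
    has one row per (sender, receiver) with n_vehicle, n_treated and the
    signed difference, and the union table carries per-arm significance
    flags per pair for Sankey-style export.
    """
    key = ["sender", "receiver", "ligand", "receptor"]
    uv = set(map(tuple, results_vehicle[key].itertuples(index=False)))
    ut = set(map(tuple, results_treated[key].itertuples(index=False)))
    if uv != ut:
        raise ValueError("vehicle and treated arms cover different "
                         "pair/cell-type universes")
    v = results_vehicle[key + ["score", "p_val", "significant"]].rename(
        columns={"score": "score_vehicle", "p_val": "p_vehicle",
                 "significant": "sig_vehicle"})
    t = results_treated[key + ["score", "p_val", "significant"]].rename(
        columns={"score": "score_treated", "p_val": "p_treated",
                 "significant": "sig_treated"})
    union = v.merge(t, on=key, how="inner").sort_values(key).reset_index(drop=True)
    grp = union.groupby(["sender", "receiver"], sort=True)
    delta = grp.agg(
        n_vehicle=("sig_vehicle", "sum"),
        n_treated=("sig_treated", "sum"),
    ).reset_index()
    delta["n_vehicle"] = delta["n_vehicle"].astype(int)
    delta["n_treated"] = delta["n_treated"].astype(int)
    delta["delta"] = delta["n_treated"] - delta["n_vehicle"]
    return delta, union
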