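"""Shared fixtures: small simulated datasets and independent oracles."""

import itertools

import numpy as np
import pytest

import trichodyn as td


@pytest.fixture(scope="session")
def sim_small():
    """Compact two-arm, four-day dataset with planted modules and markers."""
    cfg = td.SimConfig(
        n_genes=800, n_cell_types=2, cells_per_condition=25,
        genes_per_module={1: 30, 2: 30, 3: 30, 4: 30},
        markers_per_type=5, seed=11,
    )
    matrix, meta, truth = td.simulate_dataset(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def lognorm_small(sim_small):
    _, matrix, _, _ = sim_small
    return td.normalize_log(matrix)


def wilcoxon_enum_p(a, b):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled ranks to group A (tie-free inputs only)."""
    pooled = np.concatenate([a, b])
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    n, n_a = len(pooled), len(a)
    obs = sum(ranks[v] for v in a)
    mean = n_a * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def bh_definitional(p):
    """Step-up BH computed straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return np.minimum(q, 1.0)


def aucell_bruteforce(expr_col, gene_names, members, top_fraction):
    """Recovery-curve AUC by materializing R(x) for x = 1..maxRank."""
    from scipy.stats import rankdata

    G = len(gene_names)
    ranks = rankdata(-np.asarray(expr_col, dtype=float), method="average")
    rank_of = dict(zip(gene_names, ranks))
    max_rank = int(np.ceil(top_fraction * G))
    present = [g for g in members if g in rank_of]
    k = min(len(present), max_rank)
    raw = 0
    for x in range(1, max_rank + 1):
        raw += sum(1 for g in present if rank_of[g] <= x)
    denom = sum(min(x, k) for x in range(1, max_rank + 1))
    return min(raw / denom, 1.0)


def gsea_es_bruteforce(metric_sorted, hit_mask, p=1.0):
    """ES by materializing the full running-sum vector step by step."""
    G = len(metric_sorted)
    m = int(np.sum(hit_mask))
    weights = np.abs(metric_sorted) ** p
    nr = weights[hit_mask].sum()
    running, best = 0.0, 0.0
    for i in range(G):
        if hit_mask[i]:
            running += weights[i] / nr if nr > 0 else 1.0 / m
        else:
            running -= 1.0 / (G - m)
        if abs(running) > abs(best):
            best = running
    return best
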