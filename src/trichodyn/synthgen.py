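"""Ground-truthed synthetic time-course scRNA-seq data.

Emulates the study design the downstream analysis assumes: two treatment
arms (vehicle / treated) sampled at four days (0, 3, 9, 15), several cell
types, negative-binomial counts, planted gene programs following the four
kinetic shapes observed during hair regeneration (continuously decreasing,
bell-shaped, valley/cosine-shaped, gradually increasing with a vehicle-arm
plateau), log-normal library-size variation, a calibrated mitochondrial
gene block, and injected cell-type marker genes.

Kinetic templates
-----------------
Each planted gene's expected expression is its baseline multiplied by a
smooth template ``m(day)`` with ``m(0) = 1``:

* module 1 (*decreasing*): exponential decay, ``m = a**(-t/T)``, reaching
  ``1/a`` at the final day.
* module 2 (*bell*): log-scale Gaussian bump centred mid-course,
  ``m = a**b(t)`` with ``b(0) = b(T) = 0`` and ``b = 1`` at the centre.
* module 3 (*valley*): the reflected bump, ``m = a**(-b(t))`` — a sharp
  early-to-mid dip recovering to baseline.
* module 4 (*increasing*): saturating exponential rise to ``a`` in the
  treated arm; in the vehicle arm the rise is frozen at its day-3 value
  (plateau), so the treated endpoint dominates the vehicle endpoint.

``a`` is the per-module, per-arm amplitude (fold change, > 0) and ``T``
the final day.  The day axis is continuous so templates and downstream
spline fits share one coordinate system.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import DEFAULT_DAYS, GROUPS, CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "MODULE_SHAPES",
    "kinetic_template",
    "kinetic_curve",
    "simulate_dataset",
    "simulate_trajectory_dataset",
    "write_fixture",
    "read_fixture",
    "marker_table_from_truth",
]

#: Canonical shape label of each kinetic module.
MODULE_SHAPES = {1: "decreasing", 2: "bell", 3: "valley", 4: "increasing"}

_DEFAULT_AMPLITUDE = {
    1: {"vehicle": 3.0, "treated": 4.0},
    2: {"vehicle": 3.0, "treated": 3.5},
    3: {"vehicle": 3.0, "treated": 3.5},
    4: {"vehicle": 2.5, "treated": 4.0},
}


@dataclass
class SimConfig:
    """Configuration of a synthetic two-arm, four-day experiment.

    ``amplitude`` maps module id -> {group: fold change}; scalar values are
    broadcast over both arms.  ``nb_dispersion`` is the negative-binomial
    size parameter theta (variance = mu + mu^2/theta).
    ``libsize_lognormal`` gives the (log-mean, log-sd) of the per-cell
    library-size factor; ``mito_fraction`` the (mean, sd) of the per-cell
    mitochondrial proportion.
    """

    n_genes: int = 2000
    n_cell_types: int = 3
    cells_per_condition: int = 50
    days: tuple = DEFAULT_DAYS
    groups: tuple = GROUPS
    genes_per_module: dict = field(default_factory=lambda: {1: 50, 2: 50, 3: 50, 4: 50})
    amplitude: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in _DEFAULT_AMPLITUDE.items()
    })
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple = (0.0, 0.3)
    mito_fraction: tuple = (0.05, 0.02)
    n_mito_genes: int = 13
    markers_per_type: int = 5
    marker_boost: float = 8.0
    mean_library_size: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        self.days = tuple(int(d) for d in self.days)
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        amp = {}
        for m in (1, 2, 3, 4):
            a = self.amplitude.get(m, _DEFAULT_AMPLITUDE[m])
            if np.isscalar(a):
                a = {g: float(a) for g in self.groups}
            amp[m] = {g: float(a[g]) for g in self.groups}
            if any(v <= 0 for v in amp[m].values()):
                raise ValueError(f"amplitudes must be > 0 (module {m})")
        self.amplitude = amp
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (theta) must be > 0")
        n_planted = (
            sum(self.genes_per_module.values())
            + self.markers_per_type * self.n_cell_types
            + self.n_mito_genes
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``gene_module`` maps gene -> kinetic module id (1-4) or None;
    ``gene_marker_type`` maps gene -> boosted cell type or None;
    ``cell_labels`` maps cell -> (cell_type, day, group); ``mu`` is the
    dense gene x cell matrix of expected counts.
    """

    gene_module: dict
    gene_marker_type: dict
    cell_labels: dict
    mu: np.ndarray | None = None


def _bump(day, day_max: float):
    """Gaussian bump normalised to 0 at day 0 and day_max, 1 at mid-course."""
    c = day_max / 2.0
    sigma = day_max / 5.0
    g = np.exp(-((np.asarray(day, dtype=float) - c) ** 2) / (2 * sigma**2))
    g0 = np.exp(-(c**2) / (2 * sigma**2))
    return (g - g0) / (1.0 - g0)


def kinetic_curve(module_id, day, group="treated", amplitude=4.0, *,
                  day_max=DEFAULT_DAYS[-1], plateau_day=DEFAULT_DAYS[1]):
    """Evaluate a kinetic template on a continuous day axis (vectorised).

    Unlike :func:`kinetic_template` this does not restrict ``day`` to the
    configured sampling days; it is the form used for planting expression
    programs and for canonical shape matching on dense grids.
    """
    if module_id not in MODULE_SHAPES:
        raise ValueError(f"unknown kinetic module id: {module_id!r} (expected 1-4)")
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group!r} (expected one of {GROUPS})")
    a = float(amplitude)
    if a <= 0:
        raise ValueError("amplitude must be > 0")
    t = np.asarray(day, dtype=float)
    if module_id == 1:
        out = a ** (-t / day_max)
    elif module_id == 2:
        out = a ** _bump(t, day_max)
    elif module_id == 3:
        out = a ** (-_bump(t, day_max))
    else:  # module 4: saturating rise; vehicle arm plateaus after plateau_day
        t_eff = np.minimum(t, plateau_day) if group == "vehicle" else t
        r = 3.0 / day_max
        s = -np.expm1(-r * t_eff) / -np.expm1(-r * day_max)
        out = a**s
    return out if out.ndim else float(out)


def kinetic_template(module_id: int, day, group: str, amplitude: float, *,
                     days=DEFAULT_DAYS):
    """Expression multiplier m(day) of kinetic module ``module_id``.

    ``day`` must be one of the configured sampling days; ``m(day 0) = 1``
    exactly for every module, group and amplitude.
    """
    days = tuple(days)
    if day not in days:
        raise ValueError(f"unknown day: {day!r} (configured days: {days})")
    if float(amplitude) < 1:
        raise ValueError("amplitude must be >= 1")
    return kinetic_curve(
        module_id, day, group, amplitude, day_max=days[-1], plateau_day=days[1]
    )


def _beta_params(mean: float, sd: float):
    """Moment-matched Beta(a, b) parameters for a proportion in (0, 1)."""
    var = sd**2
    nu = mean * (1 - mean) / var - 1
    if nu <= 0:
        raise ValueError("mito_fraction sd too large for the given mean")
    return mean * nu, (1 - mean) * nu


def simulate_dataset(config: SimConfig):
    """Draw a complete synthetic dataset.

    Returns ``(CountMatrix, cell-metadata DataFrame, SimTruth)``.  Counts
    are negative binomial with mean
    ``mu(g, c) = baseline_g * libsize_c * template(module_g; day_c, group_c)``
    (times the marker boost in a marker gene's own cell type) and size
    theta; the flagged mitochondrial block receives a Dirichlet-weighted
    share of each cell's expected total, calibrated so the per-cell
    mitochondrial proportion has the configured mean.  Identical seeds
    yield bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- gene layout: module blocks, marker blocks, mito block, background
    gene_names, gene_module, gene_marker = [], {}, {}
    for m in sorted(cfg.genes_per_module):
        for i in range(cfg.genes_per_module[m]):
            g = f"Mod{m}g{i:04d}"
            gene_names.append(g)
            gene_module[g] = m
    cell_types = [f"CT{t + 1}" for t in range(cfg.n_cell_types)]
    for ct in cell_types:
        for i in range(cfg.markers_per_type):
            g = f"{ct}mk{i:02d}"
            gene_names.append(g)
            gene_marker[g] = ct
    mito_names = [f"mt-Sim{i:02d}" for i in range(cfg.n_mito_genes)]
    gene_names.extend(mito_names)
    n_bg = cfg.n_genes - len(gene_names)
    gene_names.extend(f"Bg{i:05d}" for i in range(n_bg))
    gene_names = np.array(gene_names, dtype=object)
    mito_flag = np.array([g.startswith("mt-") for g in gene_names], dtype=bool)
    non_mito = ~mito_flag

    # --- per-gene relative baselines, scaled to the target library size
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base[mito_flag] = 0.0
    base = base / base[non_mito].sum() * cfg.mean_library_size
    mito_weights = rng.dirichlet(np.full(cfg.n_mito_genes, 5.0))

    # --- cell layout
    rows = []
    for ct in cell_types:
        for day in cfg.days:
            for group in cfg.groups:
                for i in range(cfg.cells_per_condition):
                    rows.append((ct, day, group))
    n_cells = len(rows)
    meta = pd.DataFrame(rows, columns=["cell_type", "day", "group"])
    meta.insert(0, "cell_id", [f"cell{i:06d}" for i in range(n_cells)])

    logmu, logsd = cfg.libsize_lognormal
    libsize = rng.lognormal(mean=logmu, sigma=logsd, size=n_cells)
    mito_mean, mito_sd = cfg.mito_fraction
    if mito_sd > 0:
        a, b = _beta_params(mito_mean, mito_sd)
        mito_p = rng.beta(a, b, size=n_cells)
    else:
        mito_p = np.full(n_cells, float(mito_mean))

    # --- expected counts
    mu = np.outer(base, libsize)
    module_ids = np.array([gene_module.get(g, 0) for g in gene_names])
    day_arr = meta["day"].to_numpy()
    group_arr = meta["group"].to_numpy()
    for m in (1, 2, 3, 4):
        gmask = module_ids == m
        if not gmask.any():
            continue
        mult = np.empty(n_cells)
        for group in cfg.groups:
            cmask = group_arr == group
            mult[cmask] = kinetic_curve(
                m, day_arr[cmask], group, cfg.amplitude[m][group],
                day_max=cfg.days[-1], plateau_day=cfg.days[1],
            )
        mu[gmask] *= mult[None, :]
    marker_types = np.array([gene_marker.get(g, "") for g in gene_names], dtype=object)
    ct_arr = meta["cell_type"].to_numpy()
    for ct in cell_types:
        gmask = marker_types == ct
        cmask = ct_arr == ct
        mu[np.ix_(gmask, cmask)] *= cfg.marker_boost

    # mito block: share p/(1-p) of the cell's non-mito expected total
    nonmito_total = mu[non_mito].sum(axis=0)
    mito_total = mito_p / (1.0 - mito_p) * nonmito_total
    mu[mito_flag] = np.outer(mito_weights, mito_total)

    # --- NB sampling: counts ~ NB(size=theta, p=theta/(theta+mu))
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    matrix = CountMatrix(sp.csr_matrix(counts), gene_names, meta["cell_id"].to_numpy(),
                         mito_flag)
    truth = SimTruth(
        gene_module={g: gene_module.get(g) for g in gene_names},
        gene_marker_type={g: gene_marker.get(g) for g in gene_names},
        cell_labels={
            r.cell_id: (r.cell_type, int(r.day), r.group)
            for r in meta.itertuples()
        },
        mu=mu,
    )
    return matrix, meta, truth


def simulate_trajectory_dataset(n_cells=500, n_genes=200, n_programs=20,
                                root_label="outerBulge", theta=2.0, depth=2000.0,
                                seed=0):
    """Synthetic single-lineage dataset with a known cell ordering.

    Cells carry a latent differentiation time ``t`` uniform on [0, 1];
    ``n_programs`` genes follow smooth sigmoidal programs of ``t`` (half
    rising, half falling, staggered midpoints) so the leading principal
    components trace the lineage.  The earliest decile of cells is labelled
    ``root_label`` (the quiescent stem-cell compartment), the rest
    ``"progeny"``.  Returns ``(CountMatrix, meta, true_time)`` where
    ``meta`` carries group/day placeholders and the true ordering is the
    oracle for pseudotime recovery checks.
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, size=n_cells))
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base = base / base.sum() * depth
    mu = np.outer(base, np.ones(n_cells))
    mids = np.linspace(0.15, 0.85, n_programs)
    for j in range(n_programs):
        s = 1.0 / (1.0 + np.exp(-(t - mids[j]) / 0.08))
        if j % 2:
            s = 1.0 - s
        mu[j] *= 1.0 + 7.0 * s
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    gene_names = np.array([f"Traj{i:04d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"tc{i:05d}" for i in range(n_cells)], dtype=object)
    labels = np.where(t <= np.quantile(t, 0.1), root_label, "progeny")
    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "group": "treated",
        "day": 0,
        "cell_type": labels,
    })
    matrix = CountMatrix(sp.csr_matrix(counts), gene_names, cell_ids)
    return matrix, meta, t


def marker_table_from_truth(truth: SimTruth) -> dict:
    """Cell type -> marker gene list, recovered from simulation truth."""
    table: dict = {}
    for g, ct in truth.gene_marker_type.items():
        if ct is not None:
            table.setdefault(ct, []).append(g)
    return {ct: sorted(gs) for ct, gs in sorted(table.items())}


# ---------------------------------------------------------------------------
# fixture I/O (10x-style MTX directory + metadata + truth)
# ---------------------------------------------------------------------------

def write_fixture(dataset, directory):
    """Write ``(CountMatrix, meta, SimTruth)`` as plain-text files.

    Emits ``matrix.mtx`` (MatrixMarket integer coordinate), 3-column
    ``features.tsv`` (id, name, type), ``barcodes.tsv``, ``cellmeta.tsv``
    and ``truth.json`` (gene module / marker maps and cell labels; the
    dense expected-count matrix is not serialised).  A round-trip through
    :func:`read_fixture` reproduces the count matrix exactly.
    """
    matrix, meta, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / "matrix.mtx", sp.coo_matrix(matrix.counts).astype(np.int64),
        field="integer",
    )
    pd.DataFrame({
        "id": matrix.gene_names,
        "name": matrix.gene_names,
        "type": "Gene Expression",
    }).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", header=False, index=False
    )
    if meta is not None:
        meta.to_csv(directory / "cellmeta.tsv", sep="\t", index=False)
    payload = {
        "gene_module": {g: m for g, m in truth.gene_module.items() if m is not None},
        "gene_marker_type": {
            g: ct for g, ct in truth.gene_marker_type.items() if ct is not None
        },
        "cell_labels": {c: list(v) for c, v in truth.cell_labels.items()},
    }
    (directory / "truth.json").write_text(json.dumps(payload, indent=1))


def read_fixture(directory):
    """Read a fixture directory written by :func:`write_fixture`.

    Returns ``(CountMatrix, meta, SimTruth)``; ``truth`` is None when no
    ``truth.json`` is present (e.g. real 10x-style input).
    """
    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    name_col = 1 if features.shape[1] > 1 else 0
    gene_names = features[name_col].to_numpy(dtype=object)
    if (directory / "barcodes.tsv").stat().st_size:
        barcodes = pd.read_csv(directory / "barcodes.tsv", header=None)[0].to_numpy(
            dtype=object
        )
    else:
        barcodes = np.array([], dtype=object)
    matrix = CountMatrix(counts, gene_names, barcodes)
    meta_path = directory / "cellmeta.tsv"
    meta = pd.read_csv(meta_path, sep="\t") if meta_path.exists() else None
    if meta is not None and len(meta) == 0:
        meta = meta.astype({"cell_id": object})
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        gm = payload.get("gene_module", {})
        gk = payload.get("gene_marker_type", {})
        truth = SimTruth(
            gene_module={g: gm.get(g) for g in gene_names},
            gene_marker_type={g: gk.get(g) for g in gene_names},
            cell_labels={
                c: tuple(v) for c, v in payload.get("cell_labels", {}).items()
            },
        )
    return matrix, meta, truth
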