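# trichodyn

Time-course single-cell transcriptomic analysis of drug-induced
hair-follicle regeneration.

## The problem

During the telogen–anagen transition, quiescent hair-follicle stem cells
activate and follicle compartments remodel over days. A topical treatment
that accelerates regeneration shifts both the *kinetics* of gene programs
(what rises, falls, peaks or dips between day 0 and day 15) and the
*cell–cell signalling* between follicle and niche populations. `trichodyn`
implements the computational side of such a study as a tested, reusable
pipeline for a two-arm (vehicle vs treated), four-time-point (days 0, 3,
9, 15) scRNA-seq design:

- **QC & annotation** — cell filtering (500–5,000 detected genes, ≤ 20%
  mitochondrial counts), log-normalization, marker-based cell typing;
- **TDEGs & kinetic modules** — per cell type and arm, genes passing
  `|avg_logFC| > 0.25` and BH-adjusted `p < 0.05` in a Wilcoxon rank-sum
  test for at least one day pair; natural-cubic-spline smoothing along
  time; `ward.D2` hierarchical clustering of standardized curves into four
  kinetic modules (decreasing / bell / valley / increasing); cross-cell-type
  shared-gene counting;
- **Pseudotime & wave-DEGs** — root-anchored shortest-path pseudotime,
  negative-binomial spline likelihood-ratio testing (`q < 0.05`,
  expression ratio > 10%), top-1000 wave-DEGs in three peak-ordered waves,
  binned composition along the trajectory;
- **Gene-set scoring** — per-cell recovery-curve AUC activities (e.g.
  cell-cycle, BMP-pathway, quiescence scores) and weighted-KS enrichment
  with ES/NES and permutation FDR;
- **Crosstalk** — trimean-based ligand-receptor scoring with
  label-permutation significance and the treated-minus-vehicle
  differential event count per sender/receiver pair;
- **Simulation** — a ground-truthed negative-binomial generator of the
  same design (planted kinetic programs, marker genes, calibrated
  mitochondrial content) that drives every test.

The statistical core in the field's notation: for a gene with
log-normalized values `x`, the fold change is
`avg_logFC = ln[(mean(e^{x_A}−1)+1)/(mean(e^{x_B}−1)+1)]`; smoothed curves
are least-squares fits on a df = 3 natural spline basis of the continuous
day; modules minimize Ward variance on unsquared Euclidean distances of
standardized curves; the pseudotime test is
`2(ℓ_full − ℓ_null) ~ χ²(3)` under NB2 regression on a pseudotime spline;
the AUC score is `Σ_x R(x) / Σ_x min(x, k)` over the top
`ceil(0.05·G)` ranks; ES is the maximal running-sum deviation with
`|metric|`-weighted hits; an L-R score is
`trimean(ligand|sender) · trimean(receptor|receiver)` with
`p = (1+#{null ≥ obs})/(B+1)`.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
import numpy as np
import trichodyn as td
from sklearn.metrics import adjusted_rand_score

cfg = td.SimConfig(n_genes=813, n_cell_types=1, cells_per_condition=50,
                   genes_per_module={1: 200, 2: 200, 3: 200, 4: 200},
                   markers_per_type=0, seed=42)
matrix, meta, truth = td.simulate_dataset(cfg)
filtered, qc_meta, report = td.qc_filter(matrix, meta)
print(f"QC: {report['n_retained']}/{report['n_input']} cells retained")

lognorm = td.normalize_log(filtered)
genes, records, _ = td.find_time_degs(lognorm, qc_meta, filtered.gene_names,
                                      cell_type="CT1", group="treated")
print(f"TDEGs (treated arm): {len(genes)}")

idx = np.flatnonzero((qc_meta.group == "treated").to_numpy())
curves = td.smooth_time_curves(lognorm[:, idx], qc_meta.day.to_numpy()[idx],
                               genes, filtered.gene_names)
asg = td.label_module_shapes(td.cluster_kinetic_modules(curves, k=4))
for m, shape in asg.shape_of_module.items():
    print(f"  module {m} ({shape}): {int(np.sum(asg.module_of == m))} genes")

pairs = [(truth.gene_module[g], mm) for g, mm in zip(asg.genes, asg.module_of)
         if truth.gene_module[g] is not None]
t, p = zip(*pairs)
print(f"ARI vs planted modules: {adjusted_rand_score(t, p):.3f}")
```

Output:

```
QC: 399/400 cells retained
TDEGs (treated arm): 801
  module 1 (decreasing): 200 genes
  module 2 (bell): 202 genes
  module 3 (valley): 199 genes
  module 4 (increasing): 200 genes
ARI vs planted modules: 0.997
```

One cell narrowly misses the detected-gene floor; 801 of the 813 genes
(including essentially all 800 planted ones) pass the TDEG thresholds in
at least one day pair of the treated arm; Ward clustering of their
smoothed curves recovers the four planted kinetic programs almost exactly
(adjusted Rand index 0.997), and the shape matcher renumbers the clusters
so module 4 is the "increasing" program, as required for cross-cell-type
comparisons.

## Command line

Each stage is also a subcommand operating on a plain-text fixture
directory (MatrixMarket counts + TSV metadata):

```sh
trichodyn simulate --config cfg.yaml --out data/ --seed 7
trichodyn qc --in data/ --out qc/ --min-genes 500 --max-genes 5000 --max-mito 0.20
trichodyn tdeg --in qc/ --out tdeg/ --lfc 0.25 --padj 0.05 --k 4
trichodyn trajectory --in qc/ --out traj/ --root outerBulge --ntop 1000 --k 3
trichodyn score --in qc/ --out scores/ --gmt sets.gmt
trichodyn gsea --in qc/ --out gsea/ --gmt sets.gmt --nperm 1000 --seed 7
trichodyn crosstalk --in qc/ --out lr/ --pairs lr.tsv --nperm 100 --seed 7
```

Outputs are TSV/JSON with a fixed float format: the same seed yields
byte-identical files.

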