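# Methods

This note documents the models, algorithms and numerical choices behind
`trichodyn`, a pipeline for two-arm (vehicle vs drug-treated), four-day
(0, 3, 9, 15) time-course scRNA-seq of mouse skin during induced
hair-follicle regeneration.

## Synthetic data model

The simulator (`synthgen`) is the test bed for every downstream stage and
encodes the statistical structure the analysis assumes.

**Counts.** For gene *g* and cell *c*, counts are negative binomial with
mean

    mu(g, c) = baseline_g · libsize_c · m_g(day_c, group_c) · boost(g, c)

and size (dispersion) parameter θ, so `Var = mu + mu²/θ`. Defaults:
θ = 2 (a typical droplet scRNA-seq over-dispersion), per-gene baselines
log-normal(0, 1) scaled so an average cell carries 5,000 counts,
per-cell library-size factors log-normal(0, 0.3).

**Kinetic templates.** Each planted gene follows one of four smooth
multipliers `m(day)` of the continuous day coordinate, all anchored at
`m(0) = 1` and parameterised by an amplitude `a` (fold change) per module
and arm:

| module | shape | form |
| --- | --- | --- |
| 1 | decreasing | `a^(−t/T)` — exponential decay to `1/a` at the final day `T` |
| 2 | bell | `a^b(t)` with a Gaussian bump `b` (centre `T/2`, width `T/5`), `b(0)=b(T)=0` |
| 3 | valley | `a^(−b(t))` — the reflected bump: an early dip recovering to baseline |
| 4 | increasing | `a^s(t)`, `s` a saturating exponential with `s(T)=1`; the vehicle arm is frozen at its day-3 value (plateau) |

These are the simplest smooth, strictly positive curves realising the four
qualitative kinetics the pipeline is designed to classify: continuous
decrease, a mid-course peak, a dip-and-recovery, and a treatment-dependent
gradual rise that plateaus without treatment. Working on a log-amplitude
scale (`a^f(t)`) keeps every multiplier positive at any amplitude.

**Mitochondrial content.** A block of 13 `mt-`-prefixed genes receives,
per cell, a `p/(1−p)` share of the cell's non-mitochondrial expected
total, with `p` drawn from a moment-matched Beta distribution (default
mean 0.05, sd 0.02), split across the block by fixed Dirichlet weights.
This makes the per-cell mitochondrial proportion equal `p` in expectation,
so QC behaviour is directly controllable.

**Markers.** Each cell type gets `markers_per_type` dedicated genes
boosted 8× in that type only, making marker-based annotation testable
against ground truth.

**What the simulator does not emulate:** doublets, batch effects,
ambient RNA, gene-length effects, UMI saturation, and continuous mixtures
of cell states within a type. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artefact of real droplet data.

## QC, normalization, annotation

Cells are retained when they detect between 500 and 5,000 genes (closed
interval) and carry at most 20% mitochondrial counts; all three thresholds
are parameters, and the report records per-criterion removal counts. A
hook accepts an externally computed doublet mask. Mitochondrial genes are
identified by the case-insensitive `mt-` prefix (mouse convention) when no
explicit flag is supplied.

Normalization is library-size log-normalization,
`ln(count · 10⁴ / libsize + 1)`, preserving sparsity. Variance-stabilising
transforms, integration anchors, graph clustering and UMAP are deliberately
out of scope: cell identity is either ground-truthed (simulation) or
user-supplied, so annotation reduces to scoring each cell against a marker
table (mean of across-cell z-scored marker expression per type, argmax,
deterministic tie-break by table order) with a top-minus-runner-up
confidence margin. The built-in marker panel covers the 15 mouse-skin
types (Krt14⁺ basal cells through Cd3g⁺ T cells).

## Time-dependent DEGs and kinetic modules

For each (cell type, arm), every unordered pair of sampling days is tested
gene-wise with a two-sided Wilcoxon rank-sum test — exact by full
enumeration when both groups have ≤ 8 tie-free observations, otherwise the
normal approximation with tie and continuity corrections — and the
Seurat-convention natural-log fold change
`ln[(mean(expm1 x_A)+1)/(mean(expm1 x_B)+1)]`, under which the 0.25 cutoff
is meaningful. BH adjustment is applied within each (cell type, arm,
day-pair) family; a gene is a TDEG when `|avg_logFC| > 0.25` **and**
`p_val_adj < 0.05` (strict) in at least one pair. Testing all six pairs
(configurable to consecutive-only) maximises sensitivity, with union
semantics over pairs.

TDEG expression is then regressed on an intercept plus a 3-column natural
cubic spline basis of the continuous day coordinate (truncated-power ns()
construction, boundary knots at the day range, interior knots at
quantiles; together with the intercept it reproduces affine trends
exactly), evaluated on a 100-point grid, and row-standardized. Standardized
curves are clustered by agglomerative Ward linkage on unsquared Euclidean
distances (the hclust `ward.D2` convention) and the tree cut into k = 4
modules. Row standardization makes Euclidean distance monotone in
1 − Pearson correlation, so the clustering groups curves by shape, not
level.

Raw tree-cut labels are arbitrary, so each module's mean curve is matched
to the four canonical templates by Pearson correlation with a 4×4
maximum-correlation bipartite assignment (bijective), and modules are
renumbered 1–4 as decreasing / bell / valley / increasing. This makes
module ids comparable across cell types, which the shared-gene analysis
requires: a gene is a high-frequency module-m TDEG when it lands in module
m in at least the configured number of cell types (inclusive threshold).

## Pseudotime and wave-DEGs

Pseudotime is a root-anchored shortest-path ordering: cells are embedded
in `d = 10` principal components of the log-normalized matrix (top-2,000
variable genes by default, or a user gene set such as follicle-subtype
markers), after one round of kNN-neighbourhood averaging (15 neighbours
found in a preliminary 30-PC embedding) that suppresses count noise
without reordering cells. A symmetric 15-NN graph with Euclidean edge
weights is built, and pseudotime is the graph distance from the cell
nearest the root population's centroid, rescaled to [0, 1]; unreachable
cells get pseudotime 1 and are flagged. This replaces tree-embedding
orderings (DDRTree-style) with a transparent algorithm satisfying the same
contract — root population at pseudotime 0, monotone progression along the
lineage — and the substitution is recorded in the result metadata.
Branch assignment is out of scope (single-lineage only).

Pseudotime dependence of a gene is tested by a likelihood-ratio test:
NB2 maximum-likelihood regression (log link, ML dispersion) of raw counts
on an intercept plus a df = 3 natural spline of pseudotime versus an
intercept-only null, with `2Δℓ` referred to χ²(df). Non-convergent fits
fall back to a Gaussian F-test on log1p counts and are flagged. q-values
are BH. Wave-DEGs are the genes with q < 0.05 and expression ratio
(fraction of cells with a nonzero count) > 10%, ranked by q (ties: LRT
statistic, then name) and capped at the top 1,000; their pseudotime curves
are smoothed with the same spline machinery and Ward-clustered into k = 3
waves, renumbered by peak position (early → 1, late → 3). Binned
composition splits [0, 1] into 20 (configurable) half-open bins, the last
closed, and reports label proportions per bin, with empty bins carried as
NaN rather than silent zeros.

## Gene-set scoring and enrichment

Per-cell activity of a gene set is the normalized area under its recovery
curve: genes ranked per cell by expression descending (average ranks on
ties — deterministic; a seeded randomized tie mode exists for sensitivity
checks), `maxRank = ceil(0.05 · G)`, `R(x) = #{members with rank ≤ x}`,
score `= Σ_x R(x) / Σ_x min(x, k)` with `k = min(m, maxRank)`, clipped to
[0, 1]. The score is invariant to any per-cell monotone transform.

Enrichment uses the classical weighted-KS statistic: with the ranking
sorted by a signed metric (default: between-arm avg_logFC), hits advance
the running sum by `|metric|^p` normalized over set hits (p = 1), misses
decrement by `1/(G − m)`; ES is the maximal deviation from zero. The null
is built from gene-label permutations, NES divides ES by the mean |null
ES| of matching sign, the nominal p is the sign-matched tail fraction with
+1 smoothing (floor `1/(n_perm+1)`), and FDR across sets follows the
sign-matched NES-ratio convention (single set: FDR = nominal p). Curated
set collections are user inputs; nothing is bundled.

## Ligand-receptor crosstalk

Within one arm, the interaction of pair (L, R) from sender type S to
receiver type R is scored as
`trimean(L | S) × trimean(R | R)` with Tukey trimeans
`(Q1 + 2·Q2 + Q3)/4` under type-7 quantiles. Significance comes from
shuffling cell-type labels within the arm (preserving the arm's pooled
expression), `p = (1 + #{null ≥ obs})/(n_perm + 1)`; a pair is an "event"
when p < 0.05 and the score is positive. The treatment contrast is, per
(sender, receiver), the number of significant pairs in the treated arm
minus the vehicle arm, with the per-pair union table exported for
Sankey-style plots. This product-of-trimeans score is a deliberate,
documented simplification of mass-action communication models: it keeps
exactly the contract the contrast needs (per-pair, per-arm significance)
with a calibrated permutation null. Multi-subunit receptor complexes must
be pre-split; unresolvable genes are skipped with a warning.

## Numerical and design choices

- **Strictness and boundaries.** DE thresholds are strict inequalities;
  QC gene bounds are inclusive and the mitochondrial bound is ≤ 0.20
  ("no more than 20%" read literally).
- **Determinism.** All randomness flows through `numpy.random.default_rng`
  seeds; CLI tables are written with a fixed float format, so identical
  seeds give byte-identical outputs.
- **Ties.** Annotation and wave/module renumbering break ties by fixed,
  documented orders (marker-table order; peak position; canonical shape
  order). Average ranks make AUC scoring deterministic; clipping at 1
  guards the rare tie configurations that would overshoot.
- **Degenerate inputs.** Constant genes yield flat spline fits and are
  flagged out of standardization; all-zero genes return a null LRT;
  an all-cell QC wipeout is a warning with an empty matrix, not an error.
- **Problem sizes.** The bundled checks run on deliberately compact
  simulations — e.g. 813 genes × 400 cells per seed for module recovery,
  500 cells for pseudotime, 1,000 null genes for LRT calibration, 500
  repetitions for permutation calibration — sizes at which the measured
  properties (ARI, Spearman ρ, type-I error, KS distance) are stable
  across seeds.

## Known limitations

- The LRT's type-I error is mildly anticonservative (≈ 0.05–0.06 at
  nominal 0.05) because dispersion is re-estimated under both hypotheses;
  the calibration check bounds this directly.
- Shape labelling assumes k = 4 modules; other k values keep raw cluster
  ids.
- Pseudotime assumes a single connected lineage; branching topologies are
  flattened onto one axis.
- Annotation is only as good as the marker table; types sharing markers
  are not disambiguated.
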