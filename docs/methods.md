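# Methods

## Relative expression from cycle thresholds

A qPCR cycle threshold (Ct) is the amplification cycle at which
fluorescence crosses the detection threshold; each cycle is one doubling,
so lower Ct means exponentially higher abundance. We define relative
expression on the log2 scale as

    r = max(0, Ct_LOD − Ct),        Ct_LOD = 25 cycles by default,

with undetected wells (and any well at or above the limit of detection)
set to r = 0. This scale is uncentered and is not corrected against
control genes: it is the scale on which the node-size rule
`2^(relative expression)` and the LOD floor are mutually coherent, and
r = 0 means exactly "not detected". An optional ΔCt mode
(`ct_to_relative_expression(..., delta_ct=True)`) subtracts the per-cell
mean control Ct first, for instruments with strong cell-to-cell loading
variation; it is off by default because the LOD floor then interacts with
the shifted scale. No amplification-efficiency correction is applied.

Cell-level QC removes capture sites flagged empty or doublet and any cell
whose control assay (GAPDH or ACTB) reads undetected — the latter is the
proxy for a failed well when image-based flags are unavailable. Filtering
is idempotent and errs rather than silently returning an empty matrix.

## Relational cell–cell networks

The expression matrix is gene-mean-centered and decomposed by SVD; cell
coordinates are conventional PCA scores (left singular vectors scaled by
singular values) on the first three components. Component signs are fixed
by making the largest-magnitude gene loading positive, which makes the
embedding reproducible across LAPACK implementations.

"Normalized Euclidean distance" is interpreted as global min–max
normalization: similarity `s_ij = 1 − d_ij/d_max`, where `d_max` is the
largest pairwise distance in the dataset. This is the reading under which
the published weak/strong cutoffs (0.92 < 0.99) make sense on a bounded
[0, 1] scale with strong edges being the closer pairs. The alternative —
per-component standardization before the distance — changes only the
component weighting and can be obtained by standardizing the input.

Edge selection is per node: candidates at `s ≥ weak_threshold` are ranked
by similarity (ties broken by cell index, for determinism) and the best
`max_edges_per_node` kept; the undirected edge set is the union of the
per-node selections, i.e. an edge exists when either endpoint selected
it. Union rather than intersection preserves the "k best edges per node"
reading as a cap while keeping the graph undirected. Edges at
`s ≥ strong_threshold` are classed strong (drawn solid in DOT output),
the rest weak (dashed). The builder is tested edge-for-edge against a
brute-force O(n²) enumeration.

Layout uses a seeded force-directed (spring/stress) algorithm weighted by
edge similarity. Only determinism given a seed and non-degeneracy are part
of the contract — force-directed layouts are not reproducible bit-for-bit
across libraries, and no analysis result depends on coordinates.

## Co-expression and marker coincidence

Gene correlation over a day range uses Pearson's r on relative expression
(the log2 scale already compresses dynamic range; Spearman is available
behind a flag), average-linkage hierarchical clustering on distance
`1 − r`, and a flat cut (default 2 clusters). Zero-variance genes are
dropped with a warning, since their correlation is undefined.

Marker coincidence on one day builds the 2×2 detection table (detected =
expression strictly above the detection floor, default 0) and reports the
co-detection fraction, Jaccard index, the odds ratio with the
Haldane–Anscombe +0.5 correction applied to all four cells whenever any
count is zero, and Pearson's r among cells detecting at least one gene of
the pair. Pairs are labelled *exclusive* below odds ratio 0.2 and
*coincident* above 5; the cutoffs are package defaults chosen to be
conservative (a factor of five away from independence in either
direction) and are configurable, as the underlying claim is qualitative.
Under planted independent detection (n = 200 cells, detection rate 0.5)
the labels fire in ≈0% of replicates.

## Bulk staging and concordance

Bulk PCA treats timepoints as samples and genes as features,
gene-centered, same SVD backend as the cell embedding. Marker-panel
trajectories z-score each gene across timepoints (genes constant up to
float rounding contribute zeros) and average within panel categories; the
EMT score is the mesenchymal minus the epithelial trajectory.

Pseudobulk concordance computes the per-gene mean relative expression
over one day's cells and reports the squared Pearson correlation with the
matched bulk column over shared genes. Because r is affine-invariant, the
bulk side may be on any log-like scale; a `log2_bulk` option applies
log2(x+1) for linear-scale bulk matrices.

## Synthetic time course

The generator emulates a ~500-cell microfluidic qPCR experiment over a
staged differentiation. Eight populations total 501 cells: day 0
epithelial/pluripotent (120 cells), transitional day 1 and day 2 (90
each), day-3 DE (150) with CDH1 silenced and CDH2/SOX17/GATA6/GATA4/FOXA2
high, a day-3 double-positive intermediate population (8 cells, 5% of the
day-3 pool) co-expressing pluripotency and DE markers, 12 day-3 laggards
that never responded to induction, and residual hESC-like cells at day 5
(18) and day 7 (13). The panel is 46 marker genes — 22 named markers in
six categories plus 24 neutral `FILLER` assays with a flat baseline — and
2 control genes (GAPDH, ACTB; mean Ct ≈ 11, detected in ≥ 99% of cells).
Population sizes per day are the package's own choice of a realistic
split and are fully configurable through `PopulationSpec`.

Per cell and gene, expression is drawn from a normal with the
population's mean and spread truncated at zero (silent genes stay exactly
zero); an independent dropout event zeroes the well; and Ct is emitted as
`Ct_LOD − expression`, so normalization inverts generation exactly for
detected wells. Noise is placed on the log2-expression scale, not on Ct,
because all downstream statistics operate on relative expression, and
dropout is independent per well — the simplest model reproducing the
zero-inflation of single-cell qPCR. Dropout probability is tiered by mean
expression (0.2% for means ≥ 8, 5% for means in [4, 8), 30% below),
mirroring the strong abundance dependence of detection failure in real
chips; the laggard and residual populations provide the double-negative
cells that make SOX17/CDH2 detection genuinely coincident (odds ratio ≫ 1)
rather than merely both-frequent. Residual day-5/7 cells keep the
pluripotency/CDH1 profile with NANOG decaying over time and a low-level
VIM/TGFB1 trace from the TGFβ-rich medium: enough displacement that they
attach to the day-0 region by weak edges instead of merging into it, and
that clustering can recover them as their own populations.

The matched bulk profile is, per day, the mean of the noiseless per-cell
mean profiles plus optional i.i.d. Gaussian noise; a noiseless generation
mode emits each population's exact mean profile, for which pseudobulk
concordance is exactly R² = 1.

What the generator does **not** emulate: amplification-efficiency
variation between assays, continuous (rather than staged) differentiation
pseudotime, correlated dropout across genes within a cell, cell-cycle or
batch structure, and any attempt to match a particular deposited dataset
numerically. Tests passing on this generator therefore demonstrate that
the pipeline recovers planted staged structure under realistic dropout
and noise — not that any particular biological dataset will show it.

## Numerical choices and scales

* Default configuration: LOD Ct 25; 3 singular components; weak/strong
  similarity thresholds 0.92/0.99; 50 best edges per node; detection
  floor 0; default seed 101. All randomized operations take an explicit
  seed.
* Problem sizes in the test suite and acceptance script — 501-cell
  scenarios, 200 random network instances of ≤ 20 cells, 20-seed
  replicate sweeps, 10⁵-value normalization sweeps — keep the full suite
  around ten seconds while leaving no code path untested at realistic
  scale.
* Degenerate inputs: an all-identical embedding yields all-ones
  similarity with a warning; matrices of rank below the requested number
  of components return the available components with a warning; CSV
  writers use round-trip float formatting (`%.17g` out,
  `float_precision="round_trip"` in).

## Known limitations

* The relative-expression definition is one coherent reading of
  LOD-floored qPCR normalization; instruments or studies using a
  control-gene ΔCt convention should enable the ΔCt mode and revisit the
  floor.
* The similarity normalization depends on `d_max` and is therefore
  dataset-global: adding cells can rescale all similarities. This
  matches the bounded-threshold design but means networks from different
  datasets are not directly comparable edge-for-edge.
* The exclusivity labels are descriptive; no multiple-testing control is
  applied across the pair table.
* Graph layout coordinates are for visualization only.
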