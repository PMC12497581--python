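# Methods

This note documents the statistical model behind each stage of `spotsplit`,
the defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the known limitations of the approach.

## Spot deconvolution model

The deconvolution treats each cell type as a *gene module*: a set of genes
that switch on together in spots containing that type. It makes three
assumptions:

1. **Co-detection**: genes of one cell type are detected (count > 0) in the
   same spots, so their binarized profiles correlate strongly.
2. **Module exclusivity across types**: different cell types occupy partly
   disjoint sets of spots, so binarized profiles of different modules are
   uncorrelated or anticorrelated.
3. **Additivity**: a spot's module UMI sum scales with the number of cells of
   that type it contains, so dividing by a one-cell unit estimates the count.

### Binarization and distance

Counts are binarized (1 iff > 0) and gene–gene distances computed as
`d = 1 − r` with `r` the Pearson correlation of binary profiles (equivalently
the phi coefficient of the 2×2 co-detection table), giving `d ∈ [0, 2]`:
`d = 0` for perfectly co-detected genes, `d ≈ 1` for independent genes,
`d = 2` for perfectly complementary genes. Genes detected in fewer than
`min_prevalence` spots (default 3) are excluded because phi is unstable on
near-constant vectors; genes detected in *every* spot are excluded because
phi is undefined on constant vectors. Exclusions are reported, never silent.

### Clustering and the cut height

Modules are obtained by average-linkage agglomerative clustering of the
distance matrix, cutting the dendrogram at a cophenetic height (default 1.5).
The cut height is the method's "resolution": on the `1 − r` scale, 1.5 keeps
positively correlated genes together and splits modules whose binary profiles
are *anticorrelated* (`d > 1.5` requires `r < −0.5`). This default therefore
presumes spatially segregated cell types — niches, layers, compartments — as
found in structured tissue. In mixtures where types co-occur independently
across spots, between-module distances plateau near 1.0 (independence) and a
1.5 cut merges everything into one module; a cut just below the plateau
(0.8–1.0) separates such modules instead. Both the cut height and the linkage
are exposed in `DeconvolutionConfig`; see *Limitations*.

### Presence thresholding

For each module the per-spot UMI sums (zeros included) are fitted with a
negative binomial in the (mean μ, dispersion r) parameterization
(variance μ + μ²/r, Poisson as r → ∞) by the method of moments:
μ̂ = sample mean, r̂ = μ̂²/(v − μ̂), with a Poisson fallback when the sample
variance v ≤ μ̂. Moments were preferred to maximum likelihood because the fit
is closed-form, deterministic and adequate for a percentile threshold; fitting
over all spots (rather than nonzero spots only) makes the threshold adapt to
each module's occupancy. The module is called present where the sum *strictly
exceeds* the fitted 85th-percentile (an integer, the smallest k with
CDF(k) ≥ 0.85). A strict inequality with zeros included means an all-zero or
flat module is present nowhere; such modules are dropped and reported.

### Cell counts and splitting

The one-cell unit of a module is the minimum UMI sum among its *present*
spots (over all spots the minimum would usually be 0 and counts undefined);
the cell count of a present spot is `floor(sum / unit)`, guaranteeing ≥ 1
(`round-half-up` is available as a config option). Counts of a present
(module, spot) pair are divided among its cells gene-by-gene with a seeded
equal-probability multinomial: integral shares, exact conservation. Cells are
placed uniformly at random in the disk of the spot radius. Counts not
assigned to any cell — excluded genes, plus module counts in spots below
threshold — are reported as unassigned mass in the run report.

## Downstream statistics

Putative cells are depth-normalized as `ln(1 + count/total × 10⁴)` (the
conventional single-cell log-normalization; zero-total cells are dropped with
a warning). Cluster markers use the two-sided Wilcoxon rank-sum test of each
cluster against all other cells (exact when sample sizes permit and no ties),
a log₂ fold change of expm1-means with pseudocount 1, and BH correction
across genes within each cluster; default significance thresholds are
|log₂FC| > 1 and q < 0.005. Dot-plot statistics are the percent of expressing
cells and the per-gene z-score of cluster means across clusters. Cluster
annotation replaces database-dependent enrichment with a hypergeometric
upper-tail overrepresentation test of each cluster's top markers against
user-supplied signatures (GMT format), BH-corrected across signatures per
cluster — the result depends only on inputs shipped with the analysis, not on
an external database version.

## Bulk statistics

**Panel normalization.** Two multiplicative lane factors per sample: first
from positive-control probes, then — after applying the first — from
housekeeping probes. Each factor is (mean over samples of the per-sample
geometric mean of the control probes) / (that sample's geometric mean); the
averaging of geometric means is arithmetic by vendor convention
(`center="geometric"` is available). A zero in any control probe is an error
naming the sample, not a silently pseudocounted value: a dead control lane
should fail QC loudly. Note the two-step procedure is idempotent exactly when
the lane effect is a pure per-sample scale (then the housekeeping factors of
the first round are 1); under probe-class-specific distortions a second
normalization is not a no-op.

**Expressed-gene filter.** Endogenous values are log₂(x+1)-transformed; the
threshold is the median of all transformed endogenous values; a gene is
dropped only if every sample is strictly below the threshold. Controls are
never filtered.

**Differential expression.** Counts are scaled by DESeq-style median-of-ratios
size factors (reference genes = nonzero in all samples), log₂(x+1)
transformed, and tested per gene with Welch's t (second group vs first in
sorted label order; a zero-variance gene with equal means gets p = 1), BH
corrected; flagged iff |log₂FC| > 1 and q < 0.001. This stage is deliberately
a transparent normalize + Welch + BH pipeline with the standard thresholds,
not a negative-binomial GLM with dispersion shrinkage: it trades some power
at small counts for a fully auditable computation, and its recovery
characteristics are measured end-to-end against generator truth. The
secretome stage applies the same Welch + BH machinery to log₂(x+1)
concentrations (no size factors — concentrations are already absolute), with
thresholds |log₂FC| > 2 and q < 0.01; all-zero analytes are excluded with a
warning.

**Cross-species comparison.** Human cells × genes counts are aggregated to
per-sample pseudobulk sums; mouse symbols map to human by uppercasing unless
an explicit map entry overrides; unmapped genes are dropped and reported. The
joint (mouse + human) matrix over shared genes is size-factor normalized
together, log₂(x+1) transformed and z-scored per gene across all samples;
R² is the squared Pearson correlation between sample profiles, computed on
the z-scored matrix (`r2_on="log"` switches to the log scale).

## Synthetic generators

`generate_spatial` lays spots on a hexagonal-offset grid (pitch 100 px,
radius 27.5 px — Visium-like), draws a cell count per spot uniformly in a
range, draws each cell's type i.i.d. from the type proportions, and gives
each cell NB(expr_mean, dispersion) counts on its module genes and
NB(background_rate, dispersion) elsewhere. Defaults: 5 types at proportions
(0.8, 0.05, 0.05, 0.05, 0.05) — one dominant population, loosely mirroring an
erythroid-dominated tissue — 500 spots of 2–8 cells, 20 genes per module,
40 background genes, expr_mean 4, dispersion 2, background_rate 0.05. The
truth object records every gene's module, every spot's composition, every
cell's type, and the raw per-cell draws (so downstream conservation can be
asserted exactly). `generate_bulk` mirrors an immunology nCounter panel
scaled to 200 endogenous probes (15 housekeeping, 6 positive controls on a
2ⁿ ladder, 8 near-zero negative controls), with log-normal lane effects
(σ = 0.05) and spiked two-group fold changes; its default dispersion (500)
models near-Poisson technical replicate noise, under which the DE stage
recovers 10/10 spiked genes with zero false discoveries. `generate_secretome`
draws log-normal concentrations (within-group σ = 0.15 on the log₂ scale,
base levels 2⁵–2¹⁰ pg/mL) for a 13-plex panel with 4 samples per group,
shifting chosen analytes by a known log₂ fold change.

What the spatial generator deliberately does **not** emulate: spatial
autocorrelation of cell types (niches, layers), cross-type marker leakage,
per-spot capture-efficiency variation, or doublet-like chimeric profiles.
Passing recovery tests on this generator therefore demonstrates correctness
of the computation under the stated mixture model, not performance on real
tissue — in particular, real tissue's spatial niches are precisely what the
default cut height 1.5 exploits and the i.i.d. generator lacks (below).

## Numerical choices

- NB quantiles are computed from the scipy CDF with an exact integer search
  around `ppf`, so the returned k is exactly the smallest with CDF(k) ≥ q.
- Geometric means are computed in log space; a zero in a control probe is an
  error, not a pseudocount.
- log₂ transforms use pseudocount 1 throughout.
- BH q-values come from statsmodels (`fdr_bh`); the test suite checks them
  against an exhaustive step-up recomputation.
- MatrixMarket files are written 1-based, coordinate-integer, genes as rows,
  entries in column-major order, which makes write → read → write
  byte-stable; positions/locations CSVs are re-read with round-trip float
  parsing for the same reason.
- Module labels `M1, M2, …` are assigned in decreasing module size with
  first-member tie-breaking, so labels are deterministic.
- The output schema of the three deconvolution files (expression triplet,
  locations CSV, clusters CSV, cross-referenced by cell id) is a
  published-convention choice; the upstream description of these outputs does
  not fix a schema.

## Limitations

- **The cut height presumes anticorrelated modules.** With cell types mixed
  i.i.d. across spots (as in the default generator), between-module distances
  sit at ≈ 1.0 and the default 1.5 cut yields a single module; module
  recovery then requires cutting below the independence plateau (≈ 0.9). The
  `scripts/acceptance.py` report computes module ARI at the default
  configuration and makes this behavior visible rather than hiding it.
- **The 85th-percentile rule is occupancy-relative.** Each module's threshold
  adapts to its own sum distribution, so a module whose type occupies nearly
  every spot is called present only in its upper tail (~15% of spots) and its
  cells are undercounted relative to a rare, zero-inflated module. Cell
  counts are therefore most trustworthy for spatially localized populations.
- The Welch-based DE stage is a documented stand-in for count-model DE; at
  very small counts or very few replicates a NB GLM has more power.
- The multinomial splitter conserves counts but assigns genes to cells
  independently; it does not model within-spot cell-to-cell heterogeneity.
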