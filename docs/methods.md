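# Methods

This note documents the models, parameter choices and numerical
conventions behind `metasig`, and what the synthetic validation does and
does not demonstrate.

## Rank-based gene-set scoring

A unit's (cell, spot, or profile) score for a gene set S is built from the
Mann–Whitney U statistic of the set's within-unit expression ranks. Ranks
are assigned in decreasing expression order with mean ranks for ties; any
rank beyond the cap r_max is replaced by r_max + 1, reflecting that the
tail of a transcriptome-wide ranking is uninformative. The score
1 − U′/(n_g·r_max), clipped at 0, is 1 when the whole set occupies the top
ranks and ~0.5 for a random set. Because only within-unit ranks enter, the
score is invariant to library size, to any monotone transform of
expression, and to which other units are present — the property that makes
it safe across datasets with different cellular composition.

*Parameters.* `r_max` (default 1500 ranks): the cap below which ranks
count. The derivation data cannot pin this value; it is exposed
everywhere. Ties: mean ranks, consistent with the U statistic.

## Quality control and normalisation

Cells are kept with strictly more than 200 detected genes (count > 0) and
at most 20% mitochondrial UMIs (genes matching a configurable `MT-`
prefix); genes are kept when detected in at least 3 of the *retained*
cells, making the filter idempotent. Normalisation is
log(1 + 10⁴·count/library), natural log; zeros map to zeros, so sparsity
is preserved. Whether gene filtering should be recomputed after cell
filtering was an open choice; recomputing was chosen for idempotence.

## Archetypal decomposition

Each patient's cells are embedded by PCA (d = 20) of gene-standardised
log expression (zero-variance genes dropped; a fully constant matrix is a
degeneracy error). Principal-convex-hull archetypal analysis then seeks k
archetypes Z = BX (B rows on the simplex over cells) and loadings A (rows
on the simplex over archetypes) minimising ‖X − ABX‖². Optimisation is
alternating projected gradient with per-block adaptive step sizes and
step-halving, so the RSS is non-increasing at every accepted step;
initialisation is furthest-sum seeding (greedy mutually-distant cells,
first seed re-picked). Convergence: relative RSS change < 1e-6 or 200
iterations. Archetypes claimed by fewer than 5 cells (argmax loading,
ties to the lowest index) are dropped and loadings refit.

k is selected per patient as the elbow of the RSS-vs-k curve over
k = 2..10: the curve is rescaled to the unit square and the k of maximum
perpendicular distance to the chord joining its endpoints is taken
(near-linear curves are flagged degenerate and default to k = 2). The
k-sweep uses a lighter iteration budget (60) than the final fit, since
only the RSS profile matters there.

Each archetype's gene footprint is the loading-weighted mean expression,
z-scored per gene across archetypes **with a variance floor**: the median
per-gene spread across archetypes is added to every denominator. Without
the floor, genes expressed in almost no cell — whose between-archetype
differences are pure sampling noise — outrank genuinely
archetype-specific genes and, because low expression is a stable gene
property, the *same* spurious genes recur across patients and contaminate
the frequency analysis. The moderated z is the standard remedy for
small-denominator instability. The archetype's program is its top 200
footprint genes; 200 is exposed (`top_m`) because it directly shapes the
frequency curve.

## Signature derivation

Archetype footprints are scored (as profiles) against two seed gene
lists — a broad single-evidence list and a smaller multi-evidence list —
and the combined score is their mean. Within each patient the archetypes
at or above the 75th score percentile are selected (all kept, with a
warning, when tied). Genes are counted over selected archetypes only; a
flag allows counting over all archetypes.

The inclusion threshold is the knee of the sorted frequency curve: the
point of maximum perpendicular distance to the chord between the curve's
endpoints after rescaling to the unit square. One refinement: when that
maximum lies *below* the chord it sits in the curve's long low-count
tail (the typical shape when a small block of high-frequency genes meets
hundreds of singletons), past the cliff of interest; the curve is then
trimmed at that point and the search repeated until the knee lands on or
above the chord — the cliff top. On plateau-then-cliff curves this
coincides with the single-pass answer. An explicit threshold override
bypasses the knee (the published analysis that this procedure
operationalises used 25 archetypes). The core signature is all genes at
or above the threshold, ordered by decreasing count then lexically.

Cell-type specificity of a core gene is its per-tumour mean expression
share across cell types (uniform where a gene is silent in a tumour),
averaged over tumours and re-normalised. Genes are Ward-clustered
(Euclidean) into 9 clusters; clusters whose mean target-type (epithelial)
share reaches the midpoint between the lowest and highest cluster means
are selected — a homogeneous core keeps everything, a two-population core
splits at the natural gap; an explicit floor can replace the midpoint.
The refined signature is the core ∩ selected clusters, the residual its
complement; refined ∪ residual = core always.

## Staging and pseudobulk differential expression

Scores are discretised into 16 equal-width bins over [min, max]
(half-open, last closed; an all-equal score vector is flagged and staged
mid). Categories are empirical quantiles — bottom 20% low, top 20% high —
with boundary ties resolved toward mid, so the partition is monotone in
score and hits 20/60/20 within one cell for continuous scores.
Equal-width (not quantile) bins were chosen because a bounded score's
"bins" most plainly reads that way, and the categories are separately
quantile-based.

Differential expression aggregates counts to (sample, category)
pseudobulk sums (totals are conserved exactly; each tested category must
appear in ≥2 samples) and applies a per-gene Welch t-test on
log2-CPM(+1) with Benjamini–Hochberg correction. A moderated-variance
model is deliberately out of scope; the Welch test is calibrated at the
pseudobulk sample sizes used here (validated: type-I error 0.05 ± 0.02 at
6 vs 6).

## Bulk survival

A sample's signature score is the mean of per-gene Z scores
(standardised across samples; zero-variance genes dropped with a
warning). Stratification is at the within-cancer-type median (strictly
above → high). The Cox model uses lifelines, with tumour type as
stratification (separate baseline hazards) by default and dummy coding
behind a flag; purity, stage, age and the continuous score are
covariates; Wald p-values are BH-adjusted across the coefficient family.
Simulated survival times are continuous, so tie-handling variants of the
partial likelihood coincide. Kaplan–Meier curves and the log-rank test
come from the same library; in the no-censoring case the product-limit
estimator equals the empirical survival exactly, which the tests assert.
Tumour-vs-normal comparisons are one-sided rank-sum tests per cancer
type, BH-adjusted; the stage association is the point-biserial
correlation between score and an above/below-stage-III indicator.

## Spatial region testing

Spots are normalised and scored exactly like cells; region labels enter
only the test. The focal-vs-rest comparison is a one-sided rank-sum
test: exact (tie-aware, full enumeration of relabellings via the
permutation distribution) when the smaller group has ≤8 spots and the
enumeration is feasible (≤2·10⁵ combinations), otherwise the normal
approximation with tie correction. One-sided because the scientific
claim is directional (the invasive edge scores higher). All-constant
scores return p = 1.

## Switch timing

Expression is binarised at 0.2 (values equal to the cutoff are "on" —
the boundary convention is documented because the method this
operationalises leaves it unstated). Each gene's state is regressed on
pseudotime by IRLS logistic regression (max 100 iterations, tolerance
1e-8) with step-halving, so the log-likelihood never decreases. Complete
separation is detected by a diverging slope (|β₁| > 500) and flagged,
with pseudo-R² reported as 1 — a magnitude cap plus an honest flag was
preferred over penalised likelihood to keep the estimator simple. The
switch time t* = −β₀/β₁ is flagged when outside the observed pseudotime
range; genes in a single state are flagged degenerate and not fitted
(≥20 cells required). Fits are ranked by McFadden's pseudo-R², then
|β₁|; the top 50 are laid out on a timeline ordered by t*.

## Synthetic cohorts: what they emulate, and what they do not

Counts are negative-binomial (Gamma–Poisson) with log-normal gene means,
a shared dispersion (0.3), log-normal per-cell depth (σ 0.15) and
per-patient gene-mean heterogeneity (σ 0.25) — without patient
heterogeneity, every patient shares one baseline and spurious
cross-patient gene recurrences arise that no real cohort would show.
Mitochondrial genes (an `MT-` prefix block at ~8% of UMIs with per-cell
variability) and a 2% low-depth debris tail exercise QC. The planted
metastatic program (default 150 genes, log2 effect 2) is expressed by 30%
of epithelial cells with a *continuous* uniform intensity, so scores form
a low-to-high continuum rather than two clean groups; half the program is
epithelial-restricted and half shared with fibroblasts, giving the
specificity refinement a real distinction to find. Default cohort: 12
patients, 4 cancer types, 1500 cells and 2000 genes per patient.

The bulk generator draws exponential survival with hazard
λ₀·exp(β·score), where the score is computed exactly as the downstream
scorer computes it; censoring is an independent exponential calibrated to
the requested rate; covariates are independent of the score except for a
weak planted stage association (logistic effect 0.35, emulating the weak
stage–score correlation such signatures show in practice). The spatial
grid places a tumour-body disc inside an invasive-edge annulus inside
stroma; program-gene means are scaled by 2^edge_effect at the edge and
2^(edge_effect/2) in the body, reproducing the stroma < body < edge
ordering. Pseudotime panels draw on-states from a logistic curve in
pseudotime; "on" observations exceed the 0.2 binarisation cutoff by
construction.

Not simulated: technical batch effects, ambient RNA, doublets, UMI-level
reads, spatial spot bleed-over, realistic gene–gene correlation beyond
the planted structure. Passing the recovery tests therefore shows the
pipeline is correct and calibrated under its stated noise model, not that
real cohorts are this clean; on real data the planted-effect margins
(precision/recall near 1) should be read as upper bounds.

## Validation scale

The test suite and acceptance script run the full derivation at the
default cohort size (18,000 cells) over 20 seeds, Cox recovery at 2000
samples over 20 seeds, DE calibration at 200 genes × 20 seeds, a 30×30
spot slide and 500-cell pseudotime panels — sizes chosen so the complete
validation executes on a single CPU in minutes while keeping every
planted-effect margin measurable.

## Packaged gene lists

The published derivation this package operationalises reported a 286-gene
core split into 177 epithelial-refined and 109 residual genes. The
original supplementary lists are not redistributable, so
`src/metasig/data/` ships synthetic stand-ins that preserve exactly the
cardinalities and the disjoint-union structure; every analysis that needs
a real signature derives one from data instead.
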