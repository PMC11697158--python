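# metasig

Derivation and scoring of a pan-cancer metastatic gene signature from
transcriptomic data.

Metastasis is the dominant cause of cancer death, yet most expression
signatures of metastatic potential are built within a single tumour type.
`metasig` implements, end to end, a pipeline that extracts a *shared*
metastatic expression program from multi-patient single-cell RNA-seq and
then deploys it across every major data modality: per-cell staging, bulk
cohort survival stratification, spatial transcriptomics, and pseudotime
switch ordering. It is aimed at computational biologists who want a tested,
scriptable implementation of this class of analysis with synthetic cohorts
(planted ground truth) for validation.

## The method

**Scoring.** Gene-set activity of a cell, spot or profile is the
Mann–Whitney-U rank score: with within-unit expression ranks capped at
r_max (default 1500),

    U'(u) = Σ_{g∈S} rank(g,u) − n_g(n_g+1)/2,
    score(u) = max(0, 1 − U'(u) / (n_g · r_max)) ∈ [0, 1].

The score depends only on within-unit ranks, so it is invariant to any
monotone transform of expression and to the composition of the rest of the
dataset.

**Derivation.** Per patient: QC (>200 genes/cell, ≥3 cells/gene, ≤20%
mitochondrial UMIs), library-size log-normalisation, 20-dimensional PCA,
and principal-convex-hull archetypal analysis (k chosen by the RSS elbow,
k ≤ 10; archetypes claimed by <5 cells are dropped). Each archetype yields
a gene footprint (loading-weighted mean expression, moderated z across
archetypes) whose top 200 genes form its program. Archetype footprints are
scored against two literature seed gene lists; the top quartile of
archetypes per patient is kept; genes are counted across selected
archetypes; and a knee point on the sorted frequency curve sets the
inclusion threshold for the **core signature**. Finally a per-gene
cell-type specificity share (Ward-clustered into 9 clusters) splits the
core into an epithelial-specific **refined signature** and a
non-epithelial **residual**.

**Downstream.** Cells are staged into 16 equal-width score bins and
bottom-20% / middle-60% / top-20% categories; high-vs-low differential
expression runs on per-sample pseudobulk (Welch t on log2-CPM, BH).
Bulk samples are scored by the mean per-gene Z score, stratified at the
within-cancer-type median, and tested with Kaplan–Meier/log-rank and a
Cox proportional-hazards model (tumour type as strata; purity, stage, age
and the continuous score as covariates; BH across coefficients). Spatial
spots are scored identically and region enrichment (e.g. invasive edge)
is tested with a one-sided rank-sum test, exact for small groups. Along a
pseudotime, genes binarised at 0.2 are fitted with logistic regression;
the switch time is t* = −β₀/β₁ and fits are ranked by McFadden's
pseudo-R².

Every input can be generated by `metasig.simulate` with planted ground
truth: a negative-binomial multi-patient cohort carrying a continuous-
intensity metastatic program (an epithelial-specific half and a
fibroblast-shared half), a bulk cohort whose exponential hazard is
λ·exp(β·score), a spatial grid with stroma / tumour body / invasive edge,
and sigmoidal on/off pseudotime panels.

## Worked example

```python
import numpy as np
import metasig as ms

# a 12-patient, 4-cancer-type cohort with a planted 150-gene program
cfg = ms.SimConfig(seed=1)
matrices, truth = ms.gen_pan_cancer(cfg)
s1, s2 = ms.gen_seed_lists(truth, matrices[0].genes, seed=1)
seeds = [ms.GeneSet("single", s1, "single-evidence"),
         ms.GeneSet("multi", s2, "multi-evidence")]

res = ms.derive_signature(matrices, seeds, seed=1)
core, prog = set(res.core.genes), truth.program_genes
print(f"threshold {res.frequency.threshold}, core {len(core)} genes")
print(f"precision {len(core & prog)/len(core):.3f}, "
      f"recall {len(core & prog)/len(prog):.3f}, "
      f"refined {len(res.refined.genes)} genes")
```

prints

```
threshold 14, core 146 genes
precision 1.000, recall 0.973, refined 74 genes
```

i.e. at a knee-point threshold of 14 selected archetypes the derived core
signature contains 146 genes, every one of them a planted program gene
(precision 1.0), recovering 97% of the planted program; 74 of them are
called epithelial-specific by the refinement. A scored cohort can then be
staged (`ms.assign_stages`), tested (`ms.pseudobulk_de`), or carried to
bulk survival (`ms.signature_zscore`, `ms.cox_fit`, `ms.km_logrank`),
spatial slides (`ms.score_spots`, `ms.region_test`) and pseudotime panels
(`ms.fit_switches`, `ms.rank_switches`).

The same stages are available as a CLI:
`metasig simulate | qc | derive | score | stage | de | survival | spatial | switches`.

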