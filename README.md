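# nephroniche

Niche-based spatial transcriptomics analysis of immune kidney injury.

Checkpoint-inhibitor therapy can injure the kidney in two histologically
distinct ways: acute interstitial nephritis (AIN), an immune-cell–driven
inflammation of the interstitium, and acute tubular necrosis (ATN), a
largely non-immune epithelial injury. Segmented in-situ transcriptomics
(cells with coordinates, decoded transcript spots, a sparse cell × gene
count matrix) makes it possible to contrast the two at the level of
*spatial niches* — small contiguous tiles of ~15 cells whose aggregated
expression is far less sparse than any single cell's.

`nephroniche` implements that analysis end to end, for people who study
tissue immunology with imaging-based spatial transcriptomics:

* **synthetic cohorts** — a ground-truthed generator of 4 AIN + 4 ATN
  biopsies with nephron-like anatomy (tubule bands, glomeruli, vessels,
  fibrosis patches, immune aggregates of seven archetypes), gamma-Poisson
  expression and planted condition effects, so every downstream stage can
  be verified against known truth;
* **cell typing** — counts-per-10k/log1p normalisation and
  marker-centroid label assignment over a 24-type kidney/immune taxonomy,
  with a `LowQ` class below a transcript floor;
* **niche tiling** — a pruned Delaunay graph per sample and greedy
  expression-coherent region growing into contiguous ~15-cell tiles;
* **niche typing** — Leiden clustering of niche profiles (SNN graph on top
  principal components, with agglomeration of transcriptionally
  indistinguishable communities), marker-based annotation of 9 major niche
  types, and finer subclustering of immune niches into 7 subtypes;
* **differential abundance** — pooled-proportion fold changes with
  stratified bootstrap CIs, covarying-neighbourhood association with an
  exact label-permutation null (all 70 assignments of a 4+4 design), and a
  beta-binomial logit regression of niche composition with a
  likelihood-ratio test;
* **niche expression** — Wilcoxon differential expression, a rank-based
  module score in [0, 1] (capped Mann–Whitney statistic), classical
  preranked GSEA, the top-100 fibrotic signature, and area-normalised
  pseudobulk densities paired against urine proteomics;
* **spatial crosstalk** — niche adjacency, adjacency-restricted
  ligand–receptor interaction strength with a positional permutation
  null, fibrosis-adjacency enrichment of immune subniches, transcript
  source attribution (which cell types emit a gene's spots), and module
  score correlations.

The statistic at the core of the compositional analysis is the pooled
fold change f_t = p̂_t(AIN) / p̂_t(ATN) of cell-type proportions; the
module score is 1 − U/(n·r_max) with U the capped Mann–Whitney statistic
of the gene set's within-unit expression ranks; the composition model is
k_s ~ BetaBinomial(n_s, μ_s, φ) with logit μ_s = β₀ + β₁·AIN_s and an
F-referenced likelihood-ratio test on β₁.

## Worked example

```python
from nephroniche import (default_config, generate_cohort, apply_typing,
                         tile_cohort, type_niches, celltype_fold_changes,
                         transcript_attribution)
from nephroniche import catalogs

cohort = generate_cohort(default_config(seed=1))     # 8 samples, 40,000 cells
apply_typing(cohort, catalogs.CELL_TYPE_MARKERS)

qc = cohort.cells["qc_pass"]
folds = celltype_fold_changes(cohort.cells.loc[qc, "type_label"],
                              cohort.cells.loc[qc, "sample_id"],
                              cohort.samples, seed=1)
print(folds.set_index("cell_type").loc["Plasma", "fold"].round(2))   # 28.01

frac = transcript_attribution(cohort.transcripts, cohort.cells, "IFNG",
                              type_subset=catalogs.IMMUNE_CELL_TYPES)
print(round(100 * frac["CD8 T"], 1))                                 # 74.7

niches = tile_cohort(cohort, seed=1)
type_niches(niches, catalogs.NICHE_TYPE_MARKERS,
            catalogs.IMMUNE_SUBTYPE_MARKERS, seed=1)
print(niches.table["cluster"].nunique())                             # 9
```

The first number is the recovered plasma-cell enrichment in AIN (the
generator plants a 27-fold enrichment; pooled estimation over 40,000
cells recovers 28.0). The second is the share of immune-cell IFNG
transcript spots owned by CD8 T cells (planted at 75.1%). The last is the
number of major niche clusters found de novo — the nine planted
archetypes (glomerular, proximal tubule, injured proximal tubule, thick
ascending limb, distal convoluted tubule, collecting duct, immune,
fibrotic, vascular).

Short narrative scripts for each capability live in `examples/`; the
one-command pipeline is also exposed as a thin CLI:

```
nephroniche run --outdir out --seed 1
nephroniche report out
```

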