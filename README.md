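# modulome

Multi-omic module analysis of annual body-weight change: weighted-correlation
module detection over metabolites and metabolite-related transcripts,
module–phenotype association modelling with multiple imputation, weighted
permutation pathway enrichment, and a module-eigengene partial-correlation
network with connectivity permutation tests.

The package is aimed at epidemiologists and systems biologists who have a
cohort with serum metabolomics (and optionally blood transcriptomics)
measured at follow-up, two body-weight measurements, and want joint,
module-level association signals instead of thousands of single-molecule
tests. Because such cohort data are rarely public, the package ships a
first-class synthetic-cohort generator that plants the exact correlation and
effect structure the analysis assumes, so every stage can be validated
against a known ground truth.

## The method

**Phenotype.** Annual percentage body-weight change
`dbw = 100 · ((weight_F4 − weight_S4)/weight_S4) / followup_years`
(positive = gain).

**Preprocessing.** Metabolite concentrations are divided by the per-feature
median of samples measured on the same run day; values more than 4 SD from
the feature mean on the log10 scale are masked; features with >50% missing
cells and then samples with >20% missing cells are dropped; samples fasting
<8 h or with `dbw` outside mean ± 5 SD are excluded.

**Imputation.** Missing cells are multiply imputed by chained equations with
predictive mean matching (donor pool 5, predictors: top-15 correlated
variables plus age, sex and `dbw`); the analysis default is 20 completed
datasets × 10 iterations, and downstream estimates are pooled by Rubin's
rules.

**Modules.** On complete (imputed) data, signed adjacency
`a_ij = ((1 + r_ij)/2)^β` is built from Pearson correlations (soft power β
from the scale-free topology criterion, or the recorded defaults β=13 for
metabolites and β=8 for transcripts), converted to the topological overlap
matrix `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)`, and `1−TOM`
is clustered by average linkage. Branches with ≥5 members become modules;
modules whose eigengenes correlate above 0.75 (dendrogram height 0.25) are
merged. Each module is summarized by its eigengene (ME, first principal
component of the scaled member sub-matrix) and each feature by its module
membership kME = cor(feature, ME). Transcripts enter module detection only
if some metabolite shows a suggestive association (P < 1e-5) with them in
both an age/sex-adjusted model and a model additionally adjusted for body
weight and `dbw`.

**Association.** `ME ~ dbw + age + sex + baseline weight` by OLS with Wald
tests and Bonferroni correction (`0.05 / n_modules`); the same layer provides
single-feature models, subgroup interaction models, sensitivity-adjustment
models and cross-sectional clinical-trait models (logistic for binary
traits, linear for log-transformed continuous traits).

**Enrichment.** For pathway c and module m the statistic
`S_cm = Σ |kME|` over metabolites annotated to c and assigned to m;
significance from 100,000 permutations of the pathway-label vector,
`p = (1 + #{S_perm ≥ S_obs}) / (1 + n_perm)`. Transcript modules are tested
against GMT term sets with one-sided Fisher exact tests (probes collapsed to
genes by largest |kME|).

**Network.** For each ME pair, the partial correlation ζ is the Pearson
correlation of the residuals after regressing both MEs on all other MEs plus
sex, age, body weight and `dbw`; an edge requires a marginal correlation of
matching sign and magnitude ≥ 0.05, and is classed strong (|ζ| > 0.1) or
weak (0.05 < |ζ| ≤ 0.1). Inter-/intra-module connectivity differences
between sample groups (e.g. weight gain vs loss) are tested by permuting the
group flag.

## Worked example

```python
from modulome import CohortSpec, generate_cohort, comodule, association
import numpy as np

spec = CohortSpec(seed=3, mcar_rate=0, censor_rate=0, batch_sd=0)
pheno, metab, transcripts, truth = generate_cohort(spec)

mset, _ = comodule.detect_modules(np.log10(metab.values), power=13)
print(mset.module_sizes.to_dict())
res = association.fit_me_association(mset.eigengenes, pheno)
print(res[["target_id", "effect", "se", "p", "significant"]])
```

prints

```
{1: 15, 2: 15, 3: 15, 4: 15}
  target_id    effect        se             p  significant
0       ME1  0.352456  0.066414  3.014921e-07         True
1       ME2 -0.483069  0.061348  2.332622e-13         True
2       ME3  0.032887  0.071421  6.456910e-01        False
3       ME4  0.098246  0.070745  1.664961e-01        False
```

The generator planted four 15-metabolite modules (within-module correlation
0.7) and standardized effects +0.5 and −0.5 on the first two module latents
(`truth.assoc_effects == {1: 0.5, 2: -0.5}`); module detection recovers the
four blocks exactly, and the association layer flags exactly the two planted
modules, with slopes within sampling error of the planted values (the
eigengene attenuates the latent slope by its correlation ≈0.98 with it) and
the other two modules null.

The same pipeline runs from the shell:

```sh
modulome simulate --out cohort --seed 1
modulome preprocess --metabolites cohort/metabolites.tsv --pheno cohort/phenotype.tsv --out prep
modulome impute --in prep/metabolites_log10.tsv --pheno prep/phenotype.tsv --m 20 --iters 10 --seed 2 --out imp
modulome modules --in imp/imputed_01.tsv --power 13 --out mod
modulome associate --me mod/eigengenes.tsv --pheno prep/phenotype.tsv --out association.tsv
```

or end to end from a single YAML config with per-stage seeds:
`modulome run --config config.yaml`.

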