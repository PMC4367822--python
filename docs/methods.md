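# Methods

This note documents the models and procedures implemented in `modulome`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, the numerical choices, and known limitations.

## Study design being modelled

The analysis targets a prospective cohort design: body weight measured at a
baseline and a follow-up examination several years apart, serum metabolomics
(two platforms, tagged `M` and `N`) and whole-blood transcriptomics (`T`)
measured at follow-up, and the question of which groups of correlated
molecules track the annual percentage weight change

    dbw = 100 · ((weight_f4 − weight_s4) / weight_s4) / followup_years

in percent per year, positive for gain. Molecules are analysed in modules —
clusters of tightly correlated features — because module-level signals are
more stable and more powerful than single-molecule tests, and because the
module eigengene gives a natural single variable per cluster for regression
and network modelling.

## Synthetic cohorts

`synthetic_data.generate_cohort` plants the exact statistical structure the
analysis assumes, via a latent-factor block model rather than explicit
covariance draws (O(n·p) generation, exact control of the within-block
correlation, and a direct match to the single-eigengene module concept):

* module latent `L_m`, unit variance; for an associated module,
  `L_m = a·z(dbw) + sqrt(1 − a²)·η` with standardized slope `a`
  (`assoc_effect`, default 0.5; signs alternate across associated modules);
* metabolite `i` of module `m` on the log10 scale:
  `x_i = sqrt(w)·L_m + sqrt(1 − w)·ε_i`, so every within-module pair has
  population correlation exactly `w` (`within_module_cor`, default 0.7);
  noise features are independent N(0,1); concentrations are `10**x`;
* transcripts mix a module latent with weight `transcript_link_strength`
  (default 0.5) — already on a normalized expression scale, complete;
* run-day batch effects: each (day, feature) cell is multiplied by
  `10**N(0, batch_sd)`; `batch_sd` defaults to 0.2 on the log10 scale, which
  puts the day-median coefficient of variation in the high-tenths range
  typical of multi-day MS batches; samples are assigned to days round-robin;
* missingness: per-feature left-censoring masks the `floor(censor_rate·n)`
  lowest values (rank-based, hence scale-free and exactly testable — a
  deliberate simplification of a concentration threshold), then MCAR masks
  each remaining cell with probability `mcar_rate`. Defaults 0.07 and 0.03:
  a mean per-sample missing fraction near 10%, so the 20% per-sample filter
  removes only a few samples, matching the accounting structure of the
  emulated design (feature-level missingness substantial, sample drops rare).

Cohort size defaults to n=200 with 4 modules × 15 metabolites plus 40 noise
features — the package's reference problem size, chosen so that planted
modules are comfortably recoverable while the full pipeline runs in
seconds. Phenotype defaults: `dbw ~ N(0.3, 1.0)` percent/year, age
`N(61, 9)`, binary sex, baseline weight `N(76, 13)` kg, follow-up ≈7 years.
Age and sex are generated independent of `dbw` so the default configuration
is exactly null for calibration tests; clinical traits and covariate blocks
are likewise independent of the omics unless a test constructs them
otherwise.

What the generator does **not** emulate: real spectra, platform-specific
noise, lipoprotein physics, realistic pathway biochemistry, confounding
between covariates and weight change. Passing tests therefore demonstrate
the statistical machinery (recovery, calibration, exactness of the
permutation and pooling procedures) under the assumed correlation/effect
structure — not robustness to the many ways real cohort data violate it.

## Preprocessing

Fixed order: run-day normalization → outlier masking → missingness filters;
the order is logged and any deviation must be configured explicitly. Run-day
normalization divides each observed cell by the per-(day, feature) median of
observed values; it is idempotent, and the day-median CV (sample SD over
mean of the day medians, ddof=1, computed pre-normalization) is reported per
feature. Outlier masking is a single pass on log10 values, threshold 4 SD
(ddof=1); zero-SD features mask nothing (masking is undefined there), and
nonpositive observed values are a hard error naming the cell. Filters drop
features with >50% missing cells first, then samples with >20% missing
cells recomputed on the surviving features; both orders of magnitude were
reported without an ordering in the emulated design, and the
features-then-samples order is the package's documented choice. Cohort
exclusions drop fasting <8 h first, then `dbw` outside mean ± 5 SD computed
on the remaining samples. Downstream analysis operates on log10 values.

## Multiple imputation

Chained equations with predictive mean matching, written directly in numpy:
for each variable with missing cells, an OLS fit on its predictor set, a
posterior draw (`σ² ~ RSS/χ²_df`, `β* ~ N(β̂, σ²(XᵀX)⁻¹)`, with a 1e-8 ridge
jitter on XᵀX for rank safety), predicted means for missing rows from `β*`
and for observed rows from `β̂`, and each missing cell filled with the
observed value of a donor drawn among the 5 nearest predicted means. PMM
keeps imputations inside the observed support, which respects the
positivity/skew of metabolite data on the log scale. Predictor sets are the
top-15 variables by absolute pairwise correlation plus age, sex and `dbw` —
a pre-selection that keeps the chained models well-posed when features
outnumber the observations informative for any one variable. Defaults m=20
datasets × 10 iterations; the per-iteration mean/SD of imputed values is
recorded as a convergence trace (monitoring only). Variables with fewer
than 10 observed values are refused by name. Observed cells are never
altered; identical seeds give identical datasets (one `SeedSequence` spawned
per dataset).

Pooling follows Rubin's rules: pooled estimate = mean, total variance =
within + (1 + 1/m)·between, t reference with the classical
`(m−1)(1 + W/((1+1/m)B))²` degrees of freedom, replaced by the
Barnard–Rubin small-sample adjustment when the complete-data residual df is
supplied. The pipeline derives the module assignment from the cell-wise
mean of the completed datasets (module detection needs one complete matrix),
then recomputes eigengenes inside each completed dataset under that fixed
assignment and pools the per-dataset association estimates; a single-matrix
(averaged) analysis remains available for speed.

## Module detection

Signed adjacency `a_ij = ((1+r_ij)/2)^β` maps Pearson correlations to [0,1]
so anticorrelated features get low adjacency; "signed" is read as signed
adjacency with the standard topological overlap (the signed-TOM variant of
the dissimilarity is the other defensible reading of the phrase and can be
added behind the same surface). The soft power β is chosen as the smallest
candidate whose connectivity distribution fits a power law with signed
R² ≥ 0.85 (10 equal-width connectivity bins, log–log regression, R² negated
for a rising slope), else the argmax; 0.85 is the common convention. The
powers reported for the original metabolite and transcript networks (13 and
8) are stored as replay defaults, and at desk scale (~100 features) the scan
can be unstable — no candidate may reach the target and the argmax fallback
occasionally picks an extreme power — so the pipeline defaults to the replay
powers and treats the scan as an exploratory tool.

`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
`TOM_ii = 1`, zero denominators (isolated pairs) give overlap 0 with a
warning; dissimilarity `1 − TOM` is clustered by average linkage
(scipy). The exact dynamic-tree-cut variant used originally is not
specified, so the cut is a static threshold at `cut_height_quantile` times
the maximum merge height followed by the minimum-size filter (≥5 members;
smaller branches get label 0, the grey-module convention, and are excluded
from eigengenes and enrichment weights). The default quantile is **0.92**:
in average-linkage trees of block-correlated data the genuine module merges
sit well below 0.9× the root height while unclustered features join just
beneath the root, so a cut at 0.99× the root (a natural first guess) assigns
nearly every noise feature to a module, whereas 0.90–0.92 recovers planted
blocks exactly across seeds and powers 8–13. The parameter is configurable.

Eigengenes are the first principal component of the z-scored (ddof=1) member
sub-matrix, scaled to unit variance and sign-oriented so the mean
correlation with the members is positive (deterministic orientation);
singleton modules use the z-scored feature itself. Modules whose eigengenes
cluster below height 0.25 on `1 − cor(ME)` (average linkage) are merged,
eigengenes recomputed, repeating until stable. Labels are canonical — 1..K
by decreasing size, ties by smallest feature id — so results are invariant
to feature input order. kME is the Pearson correlation of every feature
with every eigengene.

Transcript pre-selection regresses each metabolite on each transcript plus
age and sex (model A) and additionally baseline weight and `dbw` (model B);
a transcript is kept when the same metabolite reaches P < 1e-5 for the
transcript coefficient in both models (the looser any-metabolite-per-model
reading is a flag). Both models are evaluated through the equivalent
partial-correlation t-test, which vectorizes over all pairs. Transcripts
are residualized on technical covariates (RNA integrity, plate, storage
time) beforehand when such columns are supplied.

## Association models

The base model `ME ~ dbw + age + sex + weight_s4` uses closed-form OLS with
a t reference for the Wald statistic (the t-vs-normal difference is
negligible at cohort scale but matters for small synthetic runs, and the
closed form makes 2,000-replicate calibration studies cheap); statsmodels
OLS/Logit drives the interaction, sensitivity and clinical-trait layers and
cross-checks the closed form in tests. Bonferroni thresholds are
`0.05/n_tests` with `n_tests` the number of modules (or features, or
trait×module pairs). Subgroup models fit a single regression with the
subgroup indicator and its interactions with every covariate, reporting
subgroup-specific `dbw` slopes (equal, by construction, to stratified fits)
and the interaction Wald p. Sensitivity models add a named covariate block
and report the change in the `dbw` effect plus the SE inflation ratio, so
collinearity is visible rather than silent. Clinical-trait models are
cross-sectional at follow-up: logistic for binary traits, linear on
natural-log-transformed continuous traits (the transform base is a
documented choice), adjusted for age, sex, body weight and any supplied
medication columns; sex is coded 0/1 with 0 the reference.

## Enrichment

`S_cm` sums |kME| over metabolites annotated to pathway c and assigned to
module m; |kME| (not raw kME) guards the rare negative own-module member,
with a signed variant behind a flag. The null permutes the pathway-label
vector across **all** metabolites (label-0 features keep zero weight but
participate, and super- and sub-pathway labels are permuted as two
independent vectors); the label multiset is held fixed (permutation, not
resampling). `p = (1 + #{S_perm ≥ S_obs})/(1 + n_perm)` — "≥" with +1
smoothing so p > 0 — and the raw strict-greater count is reported alongside.
Implementation permutes the (weight, assignment) pairs against a fixed label
one-hot in chunks, which is equivalent and lets 100,000 permutations run in
seconds at a few hundred features. Fisher term enrichment collapses probes
to genes by largest |kME|, intersects term sets with the universe, and uses
the one-sided (enrichment) exact test.

## Eigengene network and connectivity

ζ for a module pair is the correlation of the residuals of the two
eigengenes after least-squares regression (with intercept) on all other
eigengenes plus sex, age, body weight and `dbw`; this equals the
precision-matrix closed form `−Ω_ab/√(Ω_aa Ω_bb)` of the covariate-augmented
system, which tests verify to 1e-8. Because strongly interrelated modules
can generate spurious negative partial correlations, an edge also requires
the marginal correlation to agree in sign with ζ and exceed 0.05 in
magnitude — the prerequisite was stated without a threshold, so the
magnitude-plus-sign operationalization and its 0.05 default are the
package's documented choice. Edge classes use strict thresholds: strong if
|ζ| > 0.1, weak if 0.05 < |ζ| ≤ 0.1, none otherwise (ζ = 0.05 is "none").
With exactly two modules and no covariates the conditioning set is empty
and ζ reduces to the marginal correlation. A residual variance near zero
(duplicate or collinear eigengenes) is a hard error naming the pair.

Connectivity: inter = correlation of two eigengenes within a sample group,
intra = mean |kME| of a module's members within the group. Group eigengenes
use pooled-sample loadings (the full-sample ME restricted to the group), so
differences reflect changes in correlation structure rather than rotated
components. Significance is two-sided via the absolute difference under
permutation of the group flag, with +1 smoothing; groups below 10 samples
are refused and an imbalance beyond 95/5 warns.

## Problem sizes and numerical choices

Simulation studies in the tests and the acceptance script use deliberately
small configurations — the n=200 reference cohort for module recovery,
n=500 for effect recovery, 2,000 replicates for Wald calibration, 200
replicates of n=150 cohorts with m=5 × 5 iterations for the pooled-coverage
study, 500 null replicates (99 permutations each) and 25 power replicates
(1,000 permutations, n=150/group) for connectivity — sizes at which each
property is statistically decidable in seconds to a minute. Monte-Carlo
assertions use 3-SE bands unless a band is part of the property itself.
Floating-point conventions: sample (ddof=1) SDs throughout; correlations
clipped to [−1, 1]; matrices written with 12 significant digits (lossless
round-trip); every stochastic stage takes an explicit seed and byte-identical
re-runs are part of the test contract.

## Known limitations

* The static quantile cut is a simplification of adaptive dynamic tree cut;
  very unbalanced module sizes or nested module structure may need a
  different `cut_height_quantile`.
* No block-wise approximation: feature counts beyond ~10⁴ are out of scope.
* PMM assumes approximately linear relations on the log scale; censored
  (MNAR) missingness is imputed by the same MCAR-style chained models, so
  left-censored tails are shrunk toward the observed support.
* No shrinkage/glasso partial correlations: the eigengene count must stay
  well below the sample count.
* The clinical-trait layer assumes complete covariates and does not model
  medication changes over time.
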