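# Methods

This note documents the models, defaults, and numerical choices behind
`ardsomics`, in the order the pipeline runs them, followed by what the
synthetic cohort generator does and does not emulate.

## Synthetic cohort generator

The generator (`synthetic_cohort`) produces the study conditions the
analyses assume: 568 subjects with 26.8% 28-day mortality, genotyping for
297 (two ancestry panels, 40% AFR), transcription for 93 subjects at days
0/7/14 with 48 RNA-seq count profiles at baseline, methylation intensity
pairs for 61 subjects pooled across a 450k batch (first 18 subjects) and an
850k batch, and an 11-analyte plasma panel for 240 subjects at days 0 and 7.
Feature counts are scaled to a 1000-gene universe (3000 SNPs, 2000 probes)
so a full run stays interactive; the network stage at this scale holds
~1000 nodes and ~2000 edges rather than the order-10⁴ nodes of a production
PPI release.

Layer models:

* **Genotypes** — per LD block of 10 SNPs, two haplotype-level latent
  Gaussian AR(1) chains (lag correlation `ld_rho` = 0.8) are thresholded at
  the normal quantile of each SNP's MAF (uniform on [0.05, 0.5]); the
  additive dosage is the sum of the two indicators. Thresholding attenuates
  the latent correlation (tetrachoric attenuation): at these defaults the
  realized adjacent-SNP genotype correlation averages ≈ 0.5, which the test
  suite checks against an independent bivariate-normal thresholding oracle
  rather than against the latent value. Causal SNPs (one per planted gene
  window) shift the case-group allele frequency on the odds scale by the
  configured odds ratio (default 1.6). Missing calls are sprinkled at 0.5%,
  below the QC removal threshold.
* **RNA-seq counts** — negative binomial via a Poisson-gamma mixture with
  common dispersion 0.15 and log-normal baseline means. Planted genes gain
  `de_logfc` = 1.5 log2 units in non-survivors, and share a per-subject
  latent factor (weight `dcoexpr_delta` = 1.0) in non-survivors only, which
  is what the differential co-expression edge weights detect.
* **Longitudinal expression** — normalized microarray-style values with a
  subject random intercept. Planted genes follow the clinical pattern the
  longitudinal validation looks for: survivors rise at day 7 and return to
  baseline by day 14; non-survivors are elevated at all three days.
* **Methylation** — per-probe baseline M-values N(0, 2) plus subject noise;
  planted probes (the two probes of each planted gene) gain
  `meth_delta` = 1.2 in non-survivors. M-values are converted to
  methylated/unmethylated intensity pairs through a log-normal total
  intensity with a 15% multiplicative offset for the 850k batch — the
  feature pooled quantile normalization must remove. ~2% of probes sit on
  chrX and a small number of probe/sample detection failures are planted to
  exercise the filters.
* **Proteins** — log-normal concentrations with a subject random intercept
  (day-0/day-7 correlation); the planted day-7 effect raises non-survivors'
  Ang2 by `protein_day7_logfc` = 0.8 log units. Seven analytes are measured
  in ~95% of panel subjects and four in ~45%, so the coverage filter
  (≥ 150 subjects) retains exactly seven at default sizes. Concentrations
  below 0.5 ng/mL are recorded as zero (undetectable).
* **PPI graph** — preferential attachment (m = 2, seeded from a complete
  graph on m nodes) with the planted module densified to edge density 0.7
  by adding random missing pairs over a connectivity backbone.

All effects are planted only on ground-truth-listed features, so setting
every effect size to zero yields an exact null: the test suite verifies
downstream p-value uniformity under that configuration. Every layer draws
from a stage-keyed child generator (CRC32 of `"{seed}:{stage}"`), making
layers independently reproducible and the whole bundle byte-identical under
a fixed seed.

What the generator does **not** emulate: realistic human LD maps or allele
frequency spectra, probe-level annotation (CpG islands, cross-reactive
probes), batch effects beyond the single methylation platform offset,
library-size variation beyond what the NB mixture induces, informative
missingness, or correlated measurement times. Passing tests therefore show
the machinery is correct and calibrated under the assumed data model — not
that the pipeline would recover biology from any particular real cohort.

## Genetic association

QC removes samples then SNPs below 98% call rate, then SNPs with exact
Hardy–Weinberg p < 10⁻⁶ (Wigginton-style conditional enumeration on the
full all-ARDS sample — the cohort has no unaffected controls to restrict
to). PCs come from the SVD of the per-SNP standardized, mean-imputed dosage
matrix, with each component's sign fixed by its largest-magnitude loading.
Per-SNP models are IRLS logistic regressions of death on dosage plus the
first two PCs (age/sex available behind a flag but off by default, since
only the PCs are part of the stated model); separated or non-convergent
fits are excluded from the gene test.

The gene-based test sums per-SNP 1-df chi-squares over a ±50 kb gene window
and simulates the null from MVN(0, R). R is the Pearson correlation of
mean-imputed dosages in the analysis panel itself — a deliberate
substitution for an external reference panel, which would require a
download the package avoids. Non-PSD estimates are repaired by eigenvalue
clipping. The empirical p uses add-one smoothing, (1 + #{null ≥ obs})/(1 + n),
so it is never exactly zero, and the simulation count escalates tenfold
(from 10³ up to a cap, 10⁵ by default in the pipeline, 10⁶ in the API)
until at least 10 exceedances are seen. Per-ancestry gene p-values are
combined by Fisher's method; genes present in a single panel are carried at
their own p (the k = 1 case is an identity).

## Differential analyses

RNA-seq counts are filtered at total count < 6 across samples (a per-sample
variant is exposed by flag) and stabilized as log2(count/sf + 1) with
median-of-ratios size factors — a monotone, size-factor-cancelling stand-in
for a dispersion-fitted VST, chosen so its invariants are testable in closed
form. The two-group test is an empirical-Bayes moderated t: gene variances
are shrunk toward a scaled inverse-chi-square prior whose parameters (d₀,
s₀²) come from matching the digamma/trigamma moments of log s² (the test
suite cross-checks the resulting t statistics against the reference R
implementation to |Δt| < 0.05). When the spread of log s² does not exceed
sampling noise, d₀ = ∞ and the statistic becomes a pooled-variance z.

Methylation uses M = log2((meth + 1)/(unmeth + 1)) — the +1 offset protects
zero intensities; probes are dropped if they fail detection (p > 0.05) in
any retained sample or sit on a sex chromosome, and samples are dropped at
median detection p > 0.05. Full quantile normalization across the pooled
platforms replaces subset quantile normalization, whose probe-category
subsets require annotation files; rank order within samples is preserved
and the operation is idempotent. Probe-wise tests are ordinary equal-
variance t-tests (moderation available by flag), with no covariates by
default. Protein models are per-analyte logistic regressions of death on
concentration with age and sex, fitted at day 0 and day 7 separately to
avoid within-subject correlation; the reported effect is the percent odds
change per ng/mL, 100·(exp(β) − 1).

## Network integration

Node weights z = Φ⁻¹(1 − p) (p clamped to [10⁻¹⁶, 1 − 10⁻¹⁶]); edge weights
the absolute Fisher-z difference of within-group correlations standardized
by √(1/(n₁−3) + 1/(n₀−3)). Genes absent from either the association results
or the expression matrix are dropped from the network.

The greedy search grows one module per seed node, at each step adding the
depth-1 neighbor that maximizes S = (1−λ)Σz_node/√k + λΣz_edge/√max(m,1),
and stops when the best candidate improves S by less than a factor (1 + r)
(implemented as an |S|-scaled margin so the rule is well-defined for
non-positive scores). λ = 0.5, r = 0.1, depth 1, and the top fraction 0.001
are package defaults exposed in `ModuleSearchParams`; the method family
they come from leaves them free. Ties break by higher node weight, then
lexicographic gene id, making the search fully deterministic. Scores are
normalized against 100 random connected modules per observed size (seeded
random growth), and module selection ranks by normalized score (raw-score
ranking by flag). Gene-level methylation evidence is the minimum probe raw
p per gene, with no multiplicity combination — the loosened screening role
of this filter argues for sensitivity.

## Enrichment, longitudinal validation, prediction

Over-representation is the one-sided hypergeometric tail against a
background defaulting to the union of all pathway genes (overridable), with
BH adjustment pooled across the whole collection rather than within source.
The longitudinal validation statistic is
Q = Σ_genes Σ_days n_eff·(meanNS − meanS)² on gene-standardized values,
n_eff the harmonic mean of per-group subject counts at that cell; subjects
with missing days contribute the days they have, and cells with an empty
group are skipped. The null permutes subject group labels (not rows),
preserving within-subject correlation, with 1000 permutations and add-one
smoothing — a permutation realization of the mixed-model variance-component
score test, which is the appropriate form at these sample sizes. Within-
group trajectory patterns are clustered by complete-linkage hierarchical
clustering on per-gene mean day-trajectories, with the cut chosen by mean
silhouette over k ≤ 4 and a single cluster declared when no k reaches 0.25;
labels are canonicalized by each cluster's smallest gene id so output is
order-invariant.

Prediction uses stratified 7:3 splits (largest-remainder per-class
allocation, seeded, both classes guaranteed in both parts). Stepwise
selection alternates score-test entry (p < SLE = 0.25) and Wald-test
removal (p > SLS = 0.25) with candidate-order tie-breaks; because the entry
and stay tests differ, a variable can oscillate, so the search stops if it
revisits a model state. AUC is the tie-corrected Mann–Whitney statistic;
the 90% CI is a subject-level percentile bootstrap (2000 resamples by
default, resamples with a single class redrawn); the "good model" rule is
AUC > 0.70 with CI lower bound > 0.50, both strict. Cutpoints maximize the
Youden index over all midpoints between adjacent distinct scores, breaking
ties toward higher specificity — the use case is a high-specificity rule-in
biomarker. The protein pipeline excludes analytes measured in fewer than
150 subjects, reserves subjects beyond a 190-subject train/test pool as a
validation cohort, and builds day-0 and day-7 models independently.

## Problem sizes and runtime choices

The default pipeline scale (1000 genes, 3000 SNPs, 2000 probes, gene-test
cap 10⁵ simulations, 1000 permutations) completes a full run in well under
a minute on one CPU. The test suite's heavier checks use sizes chosen to
keep the whole suite fast while leaving Monte-Carlo error well inside the
asserted bands: 50 ten-node graphs for the exhaustive-search oracle, 100
seeds for planted-module recovery at strong effects (node z ≈ 4, edge
z ≈ 5), 1000 null datasets × 1000 permutations for trajectory-test
calibration, and 100–200 seeds for the power and null-selection checks.

## Known limitations

* The VST stand-in does not model the mean-dispersion trend; moderated-t
  inputs are therefore slightly heavier-tailed at low counts than under a
  dispersion-fitted transform.
* LD from the analysis panel underestimates correlation for rare variants
  at small n; the gene test is correspondingly slightly anticonservative
  there (not exercised at default MAF ≥ 0.05).
* The parametric variance-component score test is not implemented; only
  its permutation realization is.
* Module search optimality is local: the exhaustive-search agreement rate
  (≥ 0.9 on small graphs) quantifies, rather than eliminates, greedy
  suboptimality.
* The overlap route requires a gene to be measured in all three omics;
  genes missing a layer can never be overlap candidates.
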