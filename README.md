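# ardsomics

Multi-omics integration for discovering biomarkers of 28-day mortality in
acute respiratory distress syndrome (ARDS).

Individually underpowered single-omic studies — a GWAS split across two
ancestry panels, a small RNA-seq cohort, pooled 450k/850k DNA methylation
arrays, and an 11-analyte plasma protein panel — rarely yield
genome-wide-significant hits on their own. This package implements a
systems-biology workflow that integrates them anyway: evidence from every
layer is combined on a protein–protein interaction (PPI) network, candidate
genes are carried into pathway over-representation, validated against
longitudinal expression trajectories, and finally assembled into
mortality-prediction models. Because the analyses are exercised on a bundled
synthetic cohort generator with planted ground truth, every stage is testable
end to end without access to patient data.

It is aimed at computational biologists and biostatisticians who want a
reusable, seeded, and fully tested reference implementation of this class of
integration pipeline.

## The statistics at the core

**Gene-based association.** Per-SNP additive logistic models (death ~ dosage
+ ancestry PCs) after call-rate and exact Hardy–Weinberg QC give p-values
p_i; each gene (±50 kb window) is scored by

    T = Σ_i [Φ⁻¹(1 − p_i/2)]²

and referred to a null generated by drawing z ~ MVN(0, R) with R the local
LD correlation matrix, so correlated SNPs are not double-counted. Ancestry
panels are analysed separately and combined by Fisher's method
(−2Σ ln p ~ χ²_{2k}).

**Edge-weighted dense module search.** On the PPI network, node weights are
z_g = Φ⁻¹(1 − p_g) from the gene-based test and edge weights are the
standardized change in co-expression between non-survivors and survivors,
|atanh r¹ − atanh r⁰| / √(1/(n₁−3) + 1/(n₀−3)). From every seed gene a
module grows greedily, maximizing

    S = (1 − λ)·Σ node_z/√k + λ·Σ edge_z/√max(m, 1)

until the best addition improves S by less than a factor (1 + r). Modules
are ranked by a size-normalized score, the top 0.1% pooled, and the pooled
genes filtered for differential methylation (any probe raw p < 0.05). A
parallel *overlap* route intersects the per-omic gene lists at raw p < 0.05.

**Downstream.** Candidate sets are tested for pathway over-representation
(one-sided hypergeometric with Benjamini–Hochberg q-values); candidate
pathways are validated by a permutation test of group×time expression
patterns over days 0/7/14; and prediction models (logistic, with
score-test/Wald stepwise selection at SLE = SLS = 0.25 for proteins) are
judged by ROC AUC with a 90% bootstrap interval and reduced to Youden-optimal
biomarker cutpoints.

## Worked example

```python
from ardsomics import RunConfig, run_pipeline

cfg = RunConfig(output_dir="demo_run", seed=1)
report = run_pipeline(cfg)
st = report["stages"]
print("network:", st["integrate"]["n_network_nodes"], "nodes,",
      st["integrate"]["n_modules"], "modules")
print("network candidates:", st["integrate"]["network_candidates"])
print("validated pathways:", st["validate_longitudinal"]["n_validated"])
print("transcription AUC:", st["predict"]["transcription"]["auc"])
print("protein day-7 AUC:", st["predict"]["protein"]["day7"]["auc_test"])
```

prints (seed 1):

```
network: 1000 nodes, 1000 modules
network candidates: ['G0167', 'G0198', 'G0258', 'G0454', 'G0533', 'G0616', 'G0892']
validated pathways: 1
transcription AUC: 0.918
protein day-7 AUC: 0.722
```

The default synthetic cohort has 568 subjects (~27% mortality) and a
1000-gene universe with a 10-gene dense module planted in the PPI graph.
All seven recovered network candidates above are planted-module genes; the
pathway seeded with the planted module is the one flagged as enriched and
validated longitudinally (permutation-adjusted p ≈ 0.001); the transcription
model built on the candidate genes separates survivors from non-survivors on
the held-out test set with AUC 0.92; and the day-7 protein model selects the
analyte (Ang2) carrying the planted day-7 effect, AUC 0.72.

The same workflow is available from the shell:

```bash
ardsomics run-all --seed 1 --out demo_run
```

with per-stage subcommands (`simulate`, `assoc`, `integrate`, `enrich`,
`validate-longitudinal`, `predict`) that exchange TSV/GMT/JSON artifacts.

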