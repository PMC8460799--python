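"""Seeded synthetic multi-omic ARDS cohort generator.

Emulates the statistical structure the downstream analyses assume for a
critically-ill cohort followed to 28 days: two ancestry-stratified genotype
panels with block LD, an RNA-seq count matrix with planted differential
expression and differential co-expression, longitudinal microarray-style
expression at days 0/7/14, methylated/unmethylated intensity pairs from two
pooled platform batches, plasma protein concentrations for 11 analytes at
day 0 and day 7, and a scale-free protein-protein interaction graph with an
embedded dense module.  Every effect is planted only on features listed in
the returned ground truth, so an all-zero effect configuration is an exact
null for every downstream test.

Default sizes mirror the study cohort the pipeline emulates: 568 subjects
with 26.8% 28-day mortality, genotyping for 297, transcription for 93 (48
with RNA-seq counts), methylation for 61, and protein panels for 240, with
feature counts scaled down to a ~1000-gene universe so a full pipeline run
stays interactive.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CohortConfig",
    "GenotypePanel",
    "OmicsBundle",
    "GroundTruth",
    "generate_cohort",
    "generate_genotypes",
    "generate_ppi",
    "generate_expression",
    "generate_longitudinal",
    "generate_methylation",
    "generate_proteins",
    "generate_pathways",
    "write_bundle",
    "read_bundle",
    "write_gmt",
]

PROTEIN_NAMES = [
    "eNAMPT", "IL-1b", "IL-1R2", "IL-6", "IL-8", "VEGF",
    "Ang2", "MIF", "S1PR3", "RAGE", "HMGB1",
]
# analytes with high assay coverage in the emulated panel (>= 150 subjects
# at default sizes); the remaining four are sparsely measured
HIGH_COVERAGE_PROTEINS = ["eNAMPT", "IL-1b", "IL-1R2", "IL-8", "Ang2", "MIF", "S1PR3"]

LONGITUDINAL_DAYS = (0, 7, 14)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` are all on additive/log scales so that zero means no
    planted effect anywhere: ``snp_log_or`` (log odds ratio per minor
    allele of each causal SNP), ``de_logfc`` (log2 fold change of planted
    genes, non-survivor vs survivor), ``dcoexpr_delta`` (strength of the
    non-survivor-only shared expression factor inducing differential
    co-expression inside the planted module), ``meth_delta`` (M-value
    group difference for planted probes) and ``protein_day7_logfc``
    (day-7 log fold difference of Ang2 in non-survivors).
    """

    n_subjects_total: int = 568
    n_per_omic: dict = field(default_factory=lambda: {
        "genetics": 297, "rnaseq": 48, "longitudinal": 93,
        "methylation": 61, "protein": 240,
    })
    mortality_rate: float = 0.268
    ancestry_split: float = 0.40  # fraction of AFR-ancestry subjects
    ld_block_size: int = 10
    ld_rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    n_snps: int = 3000
    n_genes: int = 1000
    n_probes: int = 2000
    planted_module_size: int = 10
    effect_sizes: dict = field(default_factory=lambda: {
        "snp_log_or": np.log(1.6),
        "de_logfc": 1.5,
        "dcoexpr_delta": 1.0,
        "meth_delta": 1.2,
        "protein_day7_logfc": 0.8,
    })
    nb_dispersion: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_total < 4:
            raise ConfigurationError("n_subjects_total: need at least 4 subjects")
        for layer, n in self.n_per_omic.items():
            if not 0 < n <= self.n_subjects_total:
                raise ConfigurationError(
                    f"n_per_omic[{layer}]: must be in 1..n_subjects_total, got {n}")
        if not 0.0 < self.mortality_rate < 1.0:
            raise ConfigurationError("mortality_rate: must lie strictly in (0, 1)")
        if not 0.0 <= self.ancestry_split <= 1.0:
            raise ConfigurationError("ancestry_split: must lie in [0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho: must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range: need 0 < min <= max <= 0.5")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_snps:
            raise ConfigurationError("ld_block_size: must be in 1..n_snps")
        if self.planted_module_size < 3:
            raise ConfigurationError("planted_module_size: must be >= 3")
        if self.planted_module_size > self.n_genes:
            raise ConfigurationError("planted_module_size: exceeds n_genes")
        for key, val in self.effect_sizes.items():
            if not np.isfinite(val):
                raise ConfigurationError(f"effect_sizes[{key}]: must be finite")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion: must be positive")


@dataclass
class GenotypePanel:
    """Additively coded genotypes (subjects x SNPs; NaN = missing call)."""

    genotypes: pd.DataFrame
    snp_info: pd.DataFrame  # snp_id, chrom, pos (1-based), a1, a2
    ancestry: str

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class OmicsBundle:
    phenotypes: pd.DataFrame  # subject_id, death_28d, age, sex, ancestry
    genotypes: dict  # ancestry -> GenotypePanel
    rnaseq_counts: pd.DataFrame  # gene x subject, integers
    longitudinal_expr: pd.DataFrame  # subject_id, day, gene, value
    methylation_meth: pd.DataFrame  # probe x subject
    methylation_unmeth: pd.DataFrame
    methylation_platform: pd.Series  # subject -> {450k, 850k}
    methylation_detection_p: pd.DataFrame  # probe x subject
    probe_info: pd.DataFrame  # probe_id, chrom, gene_id
    proteins: pd.DataFrame  # subject_id, protein_name, day, concentration
    ppi_edges: pd.DataFrame  # gene_a, gene_b
    gene_regions: pd.DataFrame  # gene_id, chrom, start, end (1-based inclusive)


@dataclass
class GroundTruth:
    planted_module_genes: list
    causal_snps: dict  # snp_id -> odds ratio
    de_genes: dict  # gene -> log2 fold change
    dm_probes: dict  # probe -> M-value delta
    protein_effects: dict  # protein -> day-7 log fold difference
    seed: int


def _child_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator so each layer is independently reproducible."""
    child = zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(child)


def _gene_ids(n: int) -> list:
    return [f"G{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# phenotypes

def _generate_phenotypes(config: CohortConfig) -> pd.DataFrame:
    rng = _child_rng(config.seed, "phenotypes")
    n = config.n_subjects_total
    subject_id = [f"S{i:04d}" for i in range(n)]
    death = (rng.random(n) < config.mortality_rate).astype(int)
    age = np.clip(rng.normal(53.0, 15.0, n), 18, 95).round(1)
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    ancestry = np.where(rng.random(n) < config.ancestry_split, "AFR", "EUR")
    return pd.DataFrame({
        "subject_id": subject_id, "death_28d": death,
        "age": age, "sex": sex, "ancestry": ancestry,
    })


def _layer_subjects(config: CohortConfig, phenotypes: pd.DataFrame,
                    layer: str) -> list:
    """Deterministic overlapping subject subsets per omic layer."""
    rng = _child_rng(config.seed, f"subset:{layer}")
    n = config.n_per_omic[layer]
    if layer == "rnaseq":
        # RNA-seq subjects are a subset of the transcription cohort
        parent = _layer_subjects(config, phenotypes, "longitudinal")
        n = min(n, len(parent))
        return sorted(rng.choice(parent, size=n, replace=False))
    ids = phenotypes["subject_id"].to_numpy()
    return sorted(rng.choice(ids, size=min(n, ids.size), replace=False))


# ---------------------------------------------------------------------------
# genotypes

def generate_genotypes(config: CohortConfig, phenotypes: pd.DataFrame,
                       truth: GroundTruth, rng: np.random.Generator,
                       subjects: list | None = None) -> dict:
    """Generate the two ancestry-stratified genotype panels.

    Haplotypes are AR(1)-correlated latent Gaussians per LD block,
    thresholded at the normal quantile of each SNP's minor-allele
    frequency; the additive genotype is the sum of the two allele
    indicators, which yields adjacent-SNP genotype correlations close to
    (but attenuated below) ``ld_rho``.  Causal SNPs shift the case-group
    allele frequency on the odds scale by the configured odds ratio.
    A small fraction of calls is set missing (at most 2% per SNP).
    """
    lo, hi = config.maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ConfigurationError("maf_range: need 0 < min <= max <= 0.5")
    if config.ld_block_size > config.n_snps:
        raise ConfigurationError("ld_block_size: exceeds n_snps")
    if subjects is None:
        subjects = _layer_subjects(config, phenotypes, "genetics")
    pheno = phenotypes.set_index("subject_id").loc[subjects]
    snp_info = _snp_info(config)
    panels = {}
    for ancestry in ("AFR", "EUR"):
        ids = pheno.index[pheno["ancestry"] == ancestry].tolist()
        if not ids:
            continue
        dead = pheno.loc[ids, "death_28d"].to_numpy()
        maf = rng.uniform(lo, hi, config.n_snps)
        geno = np.zeros((len(ids), config.n_snps))
        n_blocks = int(np.ceil(config.n_snps / config.ld_block_size))
        for b in range(n_blocks):
            j0 = b * config.ld_block_size
            j1 = min(j0 + config.ld_block_size, config.n_snps)
            width = j1 - j0
            for hap in range(2):
                # AR(1) latent Gaussian along the block
                z = np.empty((len(ids), width))
                z[:, 0] = rng.standard_normal(len(ids))
                for j in range(1, width):
                    z[:, j] = (config.ld_rho * z[:, j - 1]
                               + np.sqrt(1 - config.ld_rho ** 2)
                               * rng.standard_normal(len(ids)))
                # per-SNP, per-outcome allele frequency threshold
                f = np.tile(maf[j0:j1], (len(ids), 1))
                for j_rel, j in enumerate(range(j0, j1)):
                    snp = snp_info["snp_id"].iat[j]
                    if snp in truth.causal_snps:
                        odds = truth.causal_snps[snp] * maf[j] / (1 - maf[j])
                        f_case = odds / (1 + odds)
                        f[:, j_rel] = np.where(dead == 1, f_case, maf[j])
                geno[:, j0:j1] += (z < stats.norm.ppf(f)).astype(float)
        # sprinkle missingness below the QC retention threshold
        miss = rng.random(geno.shape) < 0.005
        geno[miss] = np.nan
        panels[ancestry] = GenotypePanel(
            genotypes=pd.DataFrame(geno, index=ids, columns=snp_info["snp_id"]),
            snp_info=snp_info.copy(),
            ancestry=ancestry,
        )
    return panels


def _snp_info(config: CohortConfig) -> pd.DataFrame:
    """SNPs evenly spaced along one synthetic chromosome."""
    span = config.n_genes * 200_000
    pos = np.linspace(1, span, config.n_snps).astype(int)
    return pd.DataFrame({
        "snp_id": [f"rs{i:06d}" for i in range(config.n_snps)],
        "chrom": "1",
        "pos": pos,
        "a1": "A",
        "a2": "G",
    })


def _gene_regions(config: CohortConfig) -> pd.DataFrame:
    """Genes placed every 200 kb so +/-50 kb windows never overlap."""
    genes = _gene_ids(config.n_genes)
    start = 1 + np.arange(config.n_genes) * 200_000 + 70_000
    return pd.DataFrame({
        "gene_id": genes,
        "chrom": "1",
        "start": start,
        "end": start + 10_000 - 1,
    })


# ---------------------------------------------------------------------------
# PPI graph

def generate_ppi(config: CohortConfig, rng: np.random.Generator,
                 planted_genes: list | None = None) -> pd.DataFrame:
    """Scale-free PPI edge list with an embedded dense planted module.

    The host graph is preferential attachment (m = 2 new edges per node,
    seeded from a complete graph on m nodes, hence m(n-m) + C(m, 2) edges
    before densification).  The planted genes are then densified by adding
    random missing pairs until their induced edge density reaches 0.65.
    """
    if planted_genes is not None and len(planted_genes) > config.n_genes:
        raise ConfigurationError("planted module larger than gene universe")
    genes = _gene_ids(config.n_genes)
    m = 2
    seed_int = int(rng.integers(0, 2 ** 31 - 1))
    g = nx.barabasi_albert_graph(
        config.n_genes, m, seed=seed_int, initial_graph=nx.complete_graph(m))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    if planted_genes:
        planted = list(planted_genes)
        k = len(planted)
        target_edges = int(np.ceil(0.7 * k * (k - 1) / 2))
        # connectivity backbone, then random fill
        for a, b in zip(planted[:-1], planted[1:]):
            g.add_edge(a, b)
        missing = [(planted[i], planted[j]) for i in range(k)
                   for j in range(i + 1, k) if not g.has_edge(planted[i], planted[j])]
        present = k * (k - 1) // 2 - len(missing)
        need = max(0, target_edges - present)
        if need and missing:
            idx = rng.choice(len(missing), size=min(need, len(missing)), replace=False)
            g.add_edges_from(missing[i] for i in sorted(idx))
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])


# ---------------------------------------------------------------------------
# expression

def generate_expression(config: CohortConfig, phenotypes: pd.DataFrame,
                        truth: GroundTruth, rng: np.random.Generator,
                        subjects: list | None = None) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts with planted DE and co-expression.

    Gene baseline means are log-normal; planted genes get ``de_logfc``
    added to their log2 mean in non-survivors, and a per-subject latent
    factor scaled by ``dcoexpr_delta`` is shared across planted genes in
    non-survivors only, creating a group difference in co-expression.
    """
    if subjects is None:
        subjects = _layer_subjects(config, phenotypes, "rnaseq")
    pheno = phenotypes.set_index("subject_id").loc[subjects]
    dead = pheno["death_28d"].to_numpy()
    genes = _gene_ids(config.n_genes)
    base_mean = rng.lognormal(np.log(100.0), 1.0, config.n_genes)
    log2_mu = np.tile(np.log2(base_mean)[:, None], (1, len(subjects)))
    factor = rng.standard_normal(len(subjects))
    for gene, lfc in truth.de_genes.items():
        gi = genes.index(gene)
        log2_mu[gi, dead == 1] += lfc
    delta = config.effect_sizes.get("dcoexpr_delta", 0.0)
    if delta:
        loadings = rng.uniform(0.5, 1.0, len(truth.planted_module_genes))
        for loading, gene in zip(loadings, truth.planted_module_genes):
            gi = genes.index(gene)
            log2_mu[gi, dead == 1] += delta * loading * factor[dead == 1]
    mu = 2.0 ** log2_mu
    # NB as Poisson-gamma mixture with common dispersion
    shape = 1.0 / config.nb_dispersion
    lam = mu * rng.gamma(shape, 1.0 / shape, mu.shape)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                        columns=subjects)


def generate_longitudinal(config: CohortConfig, phenotypes: pd.DataFrame,
                          truth: GroundTruth, rng: np.random.Generator,
                          subjects: list | None = None) -> pd.DataFrame:
    """Microarray-style normalized expression at days 0, 7 and 14.

    Planted genes follow the validated clinical pattern: survivors start
    at baseline, rise at day 7 and return to baseline by day 14;
    non-survivors are elevated at every day.  Other genes are pure noise
    around a subject random intercept.
    """
    if subjects is None:
        subjects = _layer_subjects(config, phenotypes, "longitudinal")
    pheno = phenotypes.set_index("subject_id").loc[subjects]
    dead = pheno["death_28d"].to_numpy()
    genes = _gene_ids(config.n_genes)
    amp = config.effect_sizes.get("de_logfc", 0.0)
    planted = set(truth.planted_module_genes)
    survivor_shape = {0: 0.0, 7: 1.0, 14: 0.0}
    nonsurv_shape = {0: 1.0, 7: 1.3, 14: 1.1}
    n_s, n_g = len(subjects), len(genes)
    subj_icept = rng.normal(0.0, 0.3, n_s)
    rows = []
    planted_mask = np.array([g in planted for g in genes])
    for day in LONGITUDINAL_DAYS:
        vals = (subj_icept[:, None]
                + rng.normal(0.0, 1.0, (n_s, n_g)))
        if amp:
            shape_by_subj = np.where(dead == 1, nonsurv_shape[day], survivor_shape[day])
            vals[:, planted_mask] += amp * shape_by_subj[:, None]
        frame = pd.DataFrame(vals, index=subjects, columns=genes)
        long = frame.reset_index(names="subject_id").melt(
            id_vars="subject_id", var_name="gene", value_name="value")
        long.insert(1, "day", day)
        rows.append(long)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subject_id", "day", "gene"], ignore_index=True)


# ---------------------------------------------------------------------------
# methylation

def generate_methylation(config: CohortConfig, phenotypes: pd.DataFrame,
                         truth: GroundTruth, rng: np.random.Generator,
                         subjects: list | None = None):
    """Methylated/unmethylated intensity pairs for two pooled platforms.

    Each probe has a baseline M-value; planted probes (two per planted
    gene) get ``meth_delta`` added in non-survivors.  M-values are turned
    into intensities via a log-normal total intensity and the logistic
    beta/M relationship.  The first 18 subjects form the 450k batch, the
    rest the 850k batch, with a mild platform intensity offset.
    Returns (meth, unmeth, platform, detection_p, probe_info).
    """
    if subjects is None:
        subjects = _layer_subjects(config, phenotypes, "methylation")
    pheno = phenotypes.set_index("subject_id").loc[subjects]
    dead = pheno["death_28d"].to_numpy()
    probe_info = _probe_info(config)
    n_p, n_s = config.n_probes, len(subjects)
    base_m = rng.normal(0.0, 2.0, n_p)
    m = base_m[:, None] + rng.normal(0.0, 0.5, (n_p, n_s))
    probe_ids = probe_info["probe_id"].tolist()
    for probe, delta in truth.dm_probes.items():
        pi = probe_ids.index(probe)
        m[pi, dead == 1] += delta
    platform = pd.Series(
        ["450k"] * min(18, n_s) + ["850k"] * max(0, n_s - 18), index=subjects)
    total = rng.lognormal(np.log(2000.0), 0.3, (n_p, n_s))
    total[:, (platform == "850k").to_numpy()] *= 1.15  # platform batch offset
    beta = 1.0 / (1.0 + 2.0 ** (-m))
    meth = np.round(total * beta).astype(int)
    unmeth = np.round(total * (1 - beta)).astype(int)
    detection_p = rng.uniform(0.0, 0.01, (n_p, n_s))
    # a handful of failed probe/sample pairs to exercise the detection filter
    n_fail = max(1, n_p // 200)
    fail_rows = rng.choice(n_p, n_fail, replace=False)
    fail_cols = rng.integers(0, n_s, n_fail)
    detection_p[fail_rows, fail_cols] = rng.uniform(0.06, 0.5, n_fail)
    idx = pd.Index(probe_ids, name="probe_id")
    return (
        pd.DataFrame(meth, index=idx, columns=subjects),
        pd.DataFrame(unmeth, index=idx, columns=subjects),
        platform,
        pd.DataFrame(detection_p, index=idx, columns=subjects),
        probe_info,
    )


def _probe_info(config: CohortConfig) -> pd.DataFrame:
    """Probes assigned round-robin to genes; ~2% placed on chrX."""
    genes = _gene_ids(config.n_genes)
    gene_of = [genes[i % config.n_genes] for i in range(config.n_probes)]
    chrom = np.where(np.arange(config.n_probes) % 50 == 49, "X", "1")
    return pd.DataFrame({
        "probe_id": [f"cg{i:06d}" for i in range(config.n_probes)],
        "chrom": chrom,
        "gene_id": gene_of,
    })


# ---------------------------------------------------------------------------
# proteins

def generate_proteins(config: CohortConfig, phenotypes: pd.DataFrame,
                      truth: GroundTruth, rng: np.random.Generator,
                      subjects: list | None = None) -> pd.DataFrame:
    """Log-normal plasma concentrations at day 0 and day 7.

    Subject random intercepts induce realistic day-0/day-7 correlation.
    The planted effect raises non-survivors' day-7 level of the affected
    analyte by the configured log fold difference.  Coverage differs by
    analyte: seven are measured in nearly all panel subjects, four
    sparsely, mimicking heterogeneous assay availability.
    """
    if subjects is None:
        subjects = _layer_subjects(config, phenotypes, "protein")
    pheno = phenotypes.set_index("subject_id").loc[subjects]
    dead = pheno["death_28d"].to_numpy()
    n_s = len(subjects)
    rows = []
    for protein in PROTEIN_NAMES:
        coverage = 0.95 if protein in HIGH_COVERAGE_PROTEINS else 0.45
        measured = rng.random(n_s) < coverage
        base_log = np.log(8.0) + rng.normal(0.0, 0.1)
        subj_icept = rng.normal(0.0, 0.5, n_s)
        effect = truth.protein_effects.get(protein, 0.0)
        for day in (0, 7):
            log_conc = base_log + subj_icept + rng.normal(0.0, 0.4, n_s)
            if day == 7 and effect:
                log_conc = log_conc + effect * dead
            conc = np.exp(log_conc)
            # undetectable levels recorded as zero
            conc[conc < 0.5] = 0.0
            for i, sid in enumerate(subjects):
                if measured[i]:
                    rows.append((sid, protein, day, round(float(conc[i]), 3)))
    return pd.DataFrame(rows, columns=["subject_id", "protein_name", "day", "concentration"])


# ---------------------------------------------------------------------------
# pathways

def generate_pathways(config: CohortConfig, truth: GroundTruth,
                      rng: np.random.Generator, n_pathways: int = 60,
                      size_range: tuple = (10, 80)) -> dict:
    """Random gene-set collection with one set enriched for the module.

    Returns ``{name: (source, gene_list)}`` suitable for ``write_gmt``.
    The first pathway contains the whole planted module plus random
    padding, giving the enrichment stage a true positive.
    """
    genes = np.array(_gene_ids(config.n_genes))
    sources = ["Reactome", "PID", "Wikipathways", "NetPath", "BioCarta"]
    out = {}
    pad = rng.choice(
        [g for g in genes if g not in set(truth.planted_module_genes)],
        size=15, replace=False)
    out["PLANTED_MODULE_PATHWAY"] = (
        "Reactome", sorted(set(truth.planted_module_genes) | set(pad)))
    for i in range(1, n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        out[f"PATHWAY_{i:03d}"] = (sources[i % len(sources)], sorted(members))
    return out


def write_gmt(pathways: dict, path) -> None:
    with open(path, "w") as fh:
        for name, (source, members) in pathways.items():
            fh.write("\t".join([name, source, *members]) + "\n")


# ---------------------------------------------------------------------------
# top-level generation

def generate_cohort(config: CohortConfig):
    """Generate the full bundle and its ground-truth record.

    Deterministic for a fixed ``config.seed``: each layer draws from its
    own stage-keyed generator, so layers are reproducible independently.
    """
    config.validate()
    phenotypes = _generate_phenotypes(config)
    truth = _make_truth(config)
    ppi = generate_ppi(config, _child_rng(config.seed, "ppi"),
                       truth.planted_module_genes)
    panels = generate_genotypes(config, phenotypes, truth,
                                _child_rng(config.seed, "genotypes"))
    counts = generate_expression(config, phenotypes, truth,
                                 _child_rng(config.seed, "rnaseq"))
    longi = generate_longitudinal(config, phenotypes, truth,
                                  _child_rng(config.seed, "longitudinal"))
    meth, unmeth, platform, det_p, probe_info = generate_methylation(
        config, phenotypes, truth, _child_rng(config.seed, "methylation"))
    proteins = generate_proteins(config, phenotypes, truth,
                                 _child_rng(config.seed, "proteins"))
    bundle = OmicsBundle(
        phenotypes=phenotypes,
        genotypes=panels,
        rnaseq_counts=counts,
        longitudinal_expr=longi,
        methylation_meth=meth,
        methylation_unmeth=unmeth,
        methylation_platform=platform,
        methylation_detection_p=det_p,
        probe_info=probe_info,
        proteins=proteins,
        ppi_edges=ppi,
        gene_regions=_gene_regions(config),
    )
    return bundle, truth


def _make_truth(config: CohortConfig) -> GroundTruth:
    rng = _child_rng(config.seed, "truth")
    genes = _gene_ids(config.n_genes)
    planted = sorted(str(g) for g in
                     rng.choice(genes, config.planted_module_size, replace=False))
    eff = config.effect_sizes
    # one causal SNP inside each planted gene's +/-50 kb window
    regions = _gene_regions(config).set_index("gene_id")
    snp_info = _snp_info(config)
    causal = {}
    log_or = eff.get("snp_log_or", 0.0)
    if log_or:
        for gene in planted:
            start, end = regions.loc[gene, ["start", "end"]]
            in_window = snp_info[(snp_info["pos"] >= start - 50_000)
                                 & (snp_info["pos"] <= end + 50_000)]
            if len(in_window):
                snp = in_window["snp_id"].iloc[len(in_window) // 2]
                causal[snp] = float(np.exp(log_or))
    de = {g: eff.get("de_logfc", 0.0) for g in planted} if eff.get("de_logfc", 0.0) else {}
    probe_info = _probe_info(config)
    dm = {}
    if eff.get("meth_delta", 0.0):
        hits = probe_info[probe_info["gene_id"].isin(planted)
                          & (probe_info["chrom"] != "X")]
        dm = {p: eff["meth_delta"] for p in hits["probe_id"]}
    prot = {"Ang2": eff["protein_day7_logfc"]} if eff.get("protein_day7_logfc", 0.0) else {}
    return GroundTruth(
        planted_module_genes=list(planted),
        causal_snps=causal,
        de_genes=de,
        dm_probes=dm,
        protein_effects=prot,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# serialization

def write_bundle(bundle: OmicsBundle, truth: GroundTruth,
                 config: CohortConfig, outdir) -> None:
    """Write the bundle as TSV files plus truth.json and config.yaml."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    for ancestry, panel in bundle.genotypes.items():
        panel.genotypes.to_csv(out / f"genotypes_{ancestry}.tsv", sep="\t",
                               index_label="subject_id", float_format="%.0f")
        panel.snp_info.to_csv(out / f"snp_info_{ancestry}.tsv", sep="\t", index=False)
    bundle.rnaseq_counts.to_csv(out / "rnaseq_counts.tsv", sep="\t",
                                index_label="gene")
    bundle.longitudinal_expr.to_csv(out / "longitudinal_expr.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    bundle.methylation_meth.to_csv(out / "methylation_meth.tsv", sep="\t")
    bundle.methylation_unmeth.to_csv(out / "methylation_unmeth.tsv", sep="\t")
    bundle.methylation_platform.rename("platform").to_csv(
        out / "methylation_platform.tsv", sep="\t", index_label="subject_id")
    bundle.methylation_detection_p.to_csv(out / "methylation_detection_p.tsv",
                                          sep="\t", float_format="%.6g")
    bundle.probe_info.to_csv(out / "probe_info.tsv", sep="\t", index=False)
    bundle.proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
    bundle.ppi_edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    bundle.gene_regions.to_csv(out / "gene_regions.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
    cfg = dataclasses.asdict(config)
    cfg["maf_range"] = list(cfg["maf_range"])
    cfg["effect_sizes"] = {k: float(v) for k, v in cfg["effect_sizes"].items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_bundle(indir):
    """Read back a bundle directory written by :func:`write_bundle`."""
    d = Path(indir)
    phenotypes = pd.read_csv(d / "phenotypes.tsv", sep="\t")
    panels = {}
    for ancestry in ("AFR", "EUR"):
        gpath = d / f"genotypes_{ancestry}.tsv"
        if gpath.exists():
            geno = pd.read_csv(gpath, sep="\t", index_col="subject_id")
            info = pd.read_csv(d / f"snp_info_{ancestry}.tsv", sep="\t",
                               dtype={"chrom": str})
            panels[ancestry] = GenotypePanel(geno, info, ancestry)
    with open(d / "truth.json") as fh:
        truth = GroundTruth(**json.load(fh))
    with open(d / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cfg["maf_range"] = tuple(cfg["maf_range"])
    config = CohortConfig(**cfg)
    bundle = OmicsBundle(
        phenotypes=phenotypes,
        genotypes=panels,
        rnaseq_counts=pd.read_csv(d / "rnaseq_counts.tsv", sep="\t", index_col="gene"),
        longitudinal_expr=pd.read_csv(d / "longitudinal_expr.tsv", sep="\t"),
        methylation_meth=pd.read_csv(d / "methylation_meth.tsv", sep="\t",
                                     index_col="probe_id"),
        methylation_unmeth=pd.read_csv(d / "methylation_unmeth.tsv", sep="\t",
                                       index_col="probe_id"),
        methylation_platform=pd.read_csv(d / "methylation_platform.tsv", sep="\t",
                                         index_col="subject_id")["platform"],
        methylation_detection_p=pd.read_csv(d / "methylation_detection_p.tsv",
                                            sep="\t", index_col="probe_id"),
        probe_info=pd.read_csv(d / "probe_info.tsv", sep="\t", dtype={"chrom": str}),
        proteins=pd.read_csv(d / "proteins.tsv", sep="\t"),
        ppi_edges=pd.read_csv(d / "ppi_edges.tsv", sep="\t"),
        gene_regions=pd.read_csv(d / "gene_regions.tsv", sep="\t",
                                 dtype={"chrom": str}),
    )
    return bundle, truth, config
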