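"""End-to-end orchestration of the multi-omics integration workflow.

Stage order follows the analysis flow: synthetic cohort generation,
single-omic analyses (gene-based GWAS with cross-ancestry meta-analysis,
RNA-seq differential expression, methylation differential analysis,
per-protein logistic models), network and overlap integration, pathway
enrichment, longitudinal gene-set validation, and mortality-prediction
models.  Every stage writes a TSV artifact into the output directory and
contributes counts to a machine-readable run report.  A single global
seed fans out to per-stage child seeds (stage-name hashed) so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    genetic_association as ga,
    longitudinal_gsa as lg,
    molecular_differential as md,
    mortality_prediction as mp,
    network_integration as ni,
    pathway_enrichment as pe,
    synthetic_cohort as sc,
)

__all__ = ["RunConfig", "Thresholds", "run_pipeline", "child_seed"]

logger = logging.getLogger("ardsomics")


@dataclass
class Thresholds:
    fdr: float = 0.05
    raw_p: float = 0.05
    q: float = 0.05
    top_fraction: float = 0.001
    n_perm: int = 1000

    def validate(self) -> None:
        for name in ("fdr", "raw_p", "q", "top_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"threshold {name} must lie in (0, 1], got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")


@dataclass
class RunConfig:
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    search: ni.ModuleSearchParams = field(default_factory=ni.ModuleSearchParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    gmt_path: str | None = None   # None -> generate a synthetic collection
    ppi_path: str | None = None   # None -> use the bundle's synthetic PPI
    output_dir: str = "ardsomics_run"
    seed: int = 0
    n_gene_sims: int = 1000
    max_gene_sims: int = 100_000

    def validate(self) -> None:
        self.cohort.validate()
        self.thresholds.validate()
        for path in (self.gmt_path, self.ppi_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "cohort" in raw:
            c = raw["cohort"]
            if "maf_range" in c:
                c["maf_range"] = tuple(c["maf_range"])
            cfg.cohort = sc.CohortConfig(**c)
        if "search" in raw:
            cfg.search = ni.ModuleSearchParams(**raw["search"])
        if "thresholds" in raw:
            cfg.thresholds = Thresholds(**raw["thresholds"])
        for key in ("gmt_path", "ppi_path", "output_dir", "seed",
                    "n_gene_sims", "max_gene_sims"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["maf_range"] = list(d["cohort"]["maf_range"])
        d["cohort"]["effect_sizes"] = {
            k: float(v) for k, v in d["cohort"]["effect_sizes"].items()}
        return d


def child_seed(seed: int, stage: str) -> int:
    """Stage-keyed child seed (stable hash, below 2**31)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run report (also written to disk).

    Deterministic for a fixed ``config.seed``.  Raises on the first
    failing stage with a stage-named log line.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": config.echo(), "stages": {}}

    def stage(name):
        logger.info("stage:%s starting", name)
        return child_seed(config.seed, name)

    # --- simulate -------------------------------------------------------
    seed0 = stage("simulate")
    cohort_cfg = dataclasses.replace(config.cohort, seed=child_seed(seed0, "cohort"))
    bundle, truth = sc.generate_cohort(cohort_cfg)
    sc.write_bundle(bundle, truth, cohort_cfg, out / "bundle")
    report["stages"]["simulate"] = {
        "n_subjects": int(len(bundle.phenotypes)),
        "mortality_pct": round(100.0 * bundle.phenotypes["death_28d"].mean(), 1),
        "n_planted_genes": len(truth.planted_module_genes),
    }

    # --- genetic association -------------------------------------------
    seed_ga = stage("assoc")
    gene_assoc = ga.gene_association_pipeline(
        bundle.genotypes, bundle.phenotypes, bundle.gene_regions,
        seed=seed_ga, n_sims=config.n_gene_sims, max_sims=config.max_gene_sims)
    gene_assoc.to_csv(out / "gene_association.tsv", sep="\t")
    n_tested = int(len(gene_assoc))
    report["stages"]["assoc"] = {
        "n_genes_tested": n_tested,
        "bonferroni_threshold": ga.bonferroni_threshold(max(n_tested, 1)),
        "n_below_raw_p": int((gene_assoc["p_meta"] < config.thresholds.raw_p).sum())
        if n_tested else 0,
    }

    # --- differential expression ---------------------------------------
    stage("expression")
    counts, removed = md.filter_low_counts(bundle.rnaseq_counts)
    vst = md.vst_normalize(counts)
    groups = bundle.phenotypes.set_index("subject_id")["death_28d"]
    de = md.moderated_t_de(vst, groups)
    de.to_csv(out / "differential_expression.tsv", sep="\t")
    report["stages"]["expression"] = {
        "n_genes_removed_low_count": len(removed),
        "n_genes_tested": int(len(de)),
        "n_fdr_significant": int((de["fdr"] < config.thresholds.fdr).sum()),
    }

    # --- methylation ----------------------------------------------------
    stage("methylation")
    m_vals = md.compute_m_values(bundle.methylation_meth, bundle.methylation_unmeth)
    m_filt, probe_info = md.filter_probes(
        m_vals, bundle.methylation_detection_p, bundle.probe_info)
    m_norm = md.quantile_normalize_pooled(m_filt, bundle.methylation_platform)
    dm = md.probe_differential(m_norm, groups, probe_info=probe_info)
    dm.to_csv(out / "differential_methylation.tsv", sep="\t")
    report["stages"]["methylation"] = {
        "n_probes_tested": int(len(dm)),
        "n_probes_removed": int(len(m_vals) - len(m_filt)),
        "n_fdr_significant": int((dm["fdr"] < config.thresholds.fdr).sum()),
    }

    # --- proteins -------------------------------------------------------
    stage("proteins")
    prot_rows = []
    for day in (0, 7):
        prot_rows.append(md.protein_logistic(bundle.proteins, bundle.phenotypes, day))
    prot = pd.concat(prot_rows, ignore_index=True)
    prot.to_csv(out / "protein_association.tsv", sep="\t", index=False)
    report["stages"]["proteins"] = {
        "n_models": int(len(prot)),
        "n_below_raw_p": int((prot["p"] < config.thresholds.raw_p).sum()),
    }

    # --- integration ----------------------------------------------------
    seed_int = stage("integrate")
    if config.ppi_path:
        ppi = pd.read_csv(config.ppi_path, sep="\t")
        ppi.columns = ["gene_a", "gene_b"] + list(ppi.columns[2:])
    else:
        ppi = bundle.ppi_edges
    gene_p = gene_assoc["p_meta"].to_dict() if len(gene_assoc) else {}
    network = ni.build_network(ppi, gene_p, vst, groups)
    search = dataclasses.replace(config.search, seed=child_seed(seed_int, "norm"))
    modules = ni.dense_module_search(network, search)
    top_genes, top_modules = ni.select_top_modules(
        modules, top_fraction=config.thresholds.top_fraction)
    net_set = ni.methylation_filter(top_genes, dm.reset_index(),
                                    p_max=config.thresholds.raw_p)
    overlap_set = ni.overlap_gene_approach({
        "gwas": gene_p,
        "rnaseq": de["p_raw"].to_dict(),
        "methylation": ni.gene_level_methylation_p(dm.reset_index()).to_dict(),
    }, p_max=config.thresholds.raw_p)
    pd.DataFrame({
        "gene": net_set.genes + overlap_set.genes,
        "provenance": (["network"] * len(net_set.genes)
                       + ["overlap"] * len(overlap_set.genes)),
    }).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    report["stages"]["integrate"] = {
        "n_network_nodes": int(network.graph.number_of_nodes()),
        "n_network_edges": int(network.graph.number_of_edges()),
        "n_modules": len(modules),
        "n_top_modules": len(top_modules),
        "n_top_module_genes": len(top_genes),
        "n_network_candidates": len(net_set.genes),
        "n_overlap_candidates": len(overlap_set.genes),
        "n_candidates_union": len(set(net_set.genes) | set(overlap_set.genes)),
        "top_module_genes": top_genes,
        "network_candidates": net_set.genes,
        "overlap_candidates": overlap_set.genes,
    }

    # --- enrichment -----------------------------------------------------
    seed_enr = stage("enrich")
    if config.gmt_path:
        db = pe.load_gmt(config.gmt_path)
    else:
        pathways = sc.generate_pathways(cohort_cfg, truth,
                                        np.random.default_rng(seed_enr))
        sc.write_gmt(pathways, out / "pathways.gmt")
        db = pe.load_gmt(out / "pathways.gmt")
    enr_net = pe.enrich(net_set.genes, db) if net_set.genes else pd.DataFrame()
    enr_overlap = pe.enrich(overlap_set.genes, db) if overlap_set.genes else pd.DataFrame()
    if len(enr_net):
        enr_net.to_csv(out / "enrichment_network.tsv", sep="\t", index=False)
    if len(enr_overlap):
        enr_overlap.to_csv(out / "enrichment_overlap.tsv", sep="\t", index=False)
    sig_pathways = (enr_net[enr_net["q"] < config.thresholds.q]["pathway"].tolist()
                    if len(enr_net) else [])
    report["stages"]["enrich"] = {
        "n_pathways": len(db.pathways),
        "n_significant_network": len(sig_pathways),
        "n_significant_overlap": int((enr_overlap["q"] < config.thresholds.q).sum())
        if len(enr_overlap) else 0,
        "top_pathways": sig_pathways[:6],
    }

    # --- longitudinal validation ---------------------------------------
    seed_lg = stage("validate-longitudinal")
    validated = {}
    tested = sig_pathways[:6]
    if tested:
        expr_std = lg.standardize_genes(bundle.longitudinal_expr)
        results = lg.run_trajectory_tests(
            expr_std, {p: db.pathways[p] for p in tested}, groups,
            n_perm=config.thresholds.n_perm,
            rng=np.random.default_rng(seed_lg))
        rows = [{"pathway": r.pathway, "Q": r.statistic,
                 "p_perm": r.p_perm, "p_adj": r.p_adj} for r in results]
        pd.DataFrame(rows).to_csv(out / "longitudinal_validation.tsv",
                                  sep="\t", index=False)
        validated = {r.pathway: r.p_adj for r in results}
    report["stages"]["validate_longitudinal"] = {
        "n_pathways_tested": len(tested),
        "n_validated": sum(1 for p in validated.values() if p < 0.05),
        "p_adj": validated,
    }

    # --- prediction -----------------------------------------------------
    seed_pred = stage("predict")
    pred_report: dict = {}
    candidate_genes = net_set.genes or top_genes
    if candidate_genes:
        baseline = (bundle.longitudinal_expr
                    [bundle.longitudinal_expr["day"] == 0]
                    .pivot_table(index="gene", columns="subject_id", values="value"))
        try:
            trans = mp.transcription_model_pipeline(
                baseline, candidate_genes, bundle.phenotypes,
                seed=child_seed(seed_pred, "transcription"), n_boot=500)
            pred_report["transcription"] = {
                "auc": round(trans["roc"].auc, 3),
                "ci90": [round(v, 3) for v in trans["roc"].ci90],
                "good_model": trans["good_model"],
                "n_genes": len(trans["genes"]),
            }
        except ValueError as exc:
            pred_report["transcription"] = {"error": str(exc)}
    try:
        prot_rep = mp.protein_model_pipeline(
            bundle.proteins, bundle.phenotypes,
            seed=child_seed(seed_pred, "protein"), n_boot=500)
        pred_report["protein"] = _protein_report_summary(prot_rep)
    except ValueError as exc:
        pred_report["protein"] = {"error": str(exc)}
    report["stages"]["predict"] = pred_report

    # --- report ---------------------------------------------------------
    report_json = json.dumps(report, indent=1, sort_keys=True, default=_jsonable)
    (out / "report.json").write_text(report_json)
    (out / "report.md").write_text(_render_markdown(report))
    report["report_sha256"] = hashlib.sha256(report_json.encode()).hexdigest()
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def _protein_report_summary(prot_rep: dict) -> dict:
    summary = {
        "proteins_retained": prot_rep["proteins_retained"],
        "n_retained": len(prot_rep["proteins_retained"]),
    }
    for day in (0, 7):
        entry = prot_rep.get(f"day{day}", {})
        day_sum: dict = {"selected": entry.get("selected", [])}
        for key in ("roc_test", "roc_validation"):
            if key in entry:
                day_sum[key.replace("roc_", "auc_")] = round(entry[key].auc, 3)
                day_sum[key.replace("roc_", "ci90_")] = [
                    round(v, 3) for v in entry[key].ci90]
        if "good_model" in entry:
            day_sum["good_model"] = entry["good_model"]
        if "cutpoint" in entry:
            cp = entry["cutpoint"]
            day_sum["cutpoint"] = {
                "protein": entry.get("cutpoint_protein"),
                "threshold": round(cp.threshold, 2),
                "sensitivity": round(cp.sensitivity, 2),
                "specificity": round(cp.specificity, 2),
            }
        summary[f"day{day}"] = day_sum
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _render_markdown(report: dict) -> str:
    lines = ["# ardsomics run report", "",
             f"seed: {report['seed']}", ""]
    for name, stage in report["stages"].items():
        lines.append(f"## {name}")
        for key, val in stage.items():
            if isinstance(val, (list, dict)) and len(str(val)) > 120:
                continue
            lines.append(f"- {key}: {val}")
        lines.append("")
    return "\n".join(lines)
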