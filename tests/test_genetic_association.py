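"""Genotype QC, PCs, SNP/gene association, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from ardsomics._stats import hwe_exact_p
from ardsomics.genetic_association import (
    EmptyPanelError,
    bed_to_regions,
    bonferroni_threshold,
    compute_pcs,
    estimate_ld,
    fisher_meta,
    gene_based_test,
    map_snps_to_genes,
    qc_genotypes,
    read_vcf_genotypes,
    snp_logistic_assoc,
)
from ardsomics.synthetic_cohort import GenotypePanel


def _panel(geno: np.ndarray, ancestry="EUR") -> GenotypePanel:
    n, m = geno.shape
    df = pd.DataFrame(geno, index=[f"s{i}" for i in range(n)],
                      columns=[f"snp{j}" for j in range(m)])
    info = pd.DataFrame({"snp_id": df.columns, "chrom": "1",
                         "pos": 1000 * (np.arange(m) + 1),
                         "a1": "A", "a2": "G"})
    return GenotypePanel(df, info, ancestry)


def _phenotypes(y, ids=None):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(y))]
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "subject_id": ids, "death_28d": y,
        "age": rng.normal(50, 10, len(y)).round(1),
        "sex": np.where(rng.random(len(y)) < 0.5, "M", "F"),
        "ancestry": "EUR",
    })


class TestHweExact:
    def test_equilibrium_counts_retained(self):
        # AA=25, Aa=50, aa=25 sits at the HWE mode: p-value 1
        assert hwe_exact_p(50, 25, 25) == pytest.approx(1.0, abs=1e-9)

    def test_no_heterozygotes_strongly_rejected(self):
        assert hwe_exact_p(0, 50, 50) < 1e-6

    def test_against_full_enumeration(self):
        # independent oracle: enumerate the conditional distribution directly
        import math

        def oracle(het, hom1, hom2):
            n = het + hom1 + hom2
            rare = 2 * min(hom1, hom2) + het
            common = 2 * n - rare
            denom = math.comb(2 * n, rare)
            probs = {}
            for h in range(rare % 2, min(rare, common) + 1, 2):
                hr = (rare - h) // 2
                hc = n - h - hr
                if hr < 0 or hc < 0:
                    continue
                probs[h] = (math.factorial(n)
                            // (math.factorial(hr) * math.factorial(h) * math.factorial(hc))
                            * 2 ** h / denom)
            p_obs = probs[het]
            return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))

        for het, hom1, hom2 in [(10, 5, 5), (3, 10, 2), (7, 0, 3), (20, 40, 40)]:
            assert hwe_exact_p(het, hom1, hom2) == pytest.approx(
                oracle(het, hom1, hom2), rel=1e-9)


class TestQc:
    def test_high_missingness_snp_removed(self, rng):
        # 100 SNPs so single missing calls do not sink any sample first
        geno = rng.binomial(2, 0.4, (100, 100)).astype(float)
        geno[:3, 0] = np.nan  # 3% missing < 98% call rate
        panel = _panel(geno)
        clean, report = qc_genotypes(panel)
        assert "snp0" not in clean.genotypes.columns
        assert report.n_snps_removed_call_rate == 1
        assert report.n_samples_removed_call_rate == 0

    def test_hwe_violating_snp_removed(self, rng):
        geno = np.column_stack([
            np.repeat([0.0, 2.0], 50),               # no hets: HWE p << 1e-6
            rng.binomial(2, 0.3, 100).astype(float),  # fine
        ])
        clean, report = qc_genotypes(_panel(geno))
        assert list(clean.genotypes.columns) == ["snp1"]
        assert report.n_snps_removed_hwe == 1

    def test_qc_idempotent(self, rng):
        geno = rng.binomial(2, 0.3, (80, 20)).astype(float)
        geno[rng.random(geno.shape) < 0.01] = np.nan
        once, _ = qc_genotypes(_panel(geno))
        twice, rep2 = qc_genotypes(once)
        pd.testing.assert_frame_equal(once.genotypes, twice.genotypes)
        assert rep2.n_snps_removed_hwe == 0

    def test_all_removed_raises(self):
        geno = np.repeat([[0.0], [2.0]], 50, axis=0)  # single SNP failing HWE
        with pytest.raises(EmptyPanelError):
            qc_genotypes(_panel(geno))


class TestPcs:
    def test_two_populations_separate_on_pc1(self, rng):
        # divergent allele frequencies between two subpopulations
        freq_a, freq_b = rng.uniform(0.1, 0.3, 200), None
        freq_b = np.clip(freq_a + rng.uniform(0.25, 0.4, 200), 0, 0.95)
        geno = np.vstack([
            rng.binomial(2, freq_a, (60, 200)),
            rng.binomial(2, freq_b, (60, 200)),
        ]).astype(float)
        scores = compute_pcs(_panel(geno), k=2)
        membership = np.repeat([0.0, 1.0], 60)
        r = np.corrcoef(scores["PC1"], membership)[0, 1]
        assert abs(r) > 0.9

    def test_k_components_returned(self, rng):
        geno = rng.binomial(2, 0.4, (3, 10)).astype(float)
        assert compute_pcs(_panel(geno), k=2).shape == (3, 2)

    def test_subject_permutation_equivariance(self, rng):
        geno = rng.binomial(2, 0.3, (40, 60)).astype(float)
        panel = _panel(geno)
        scores = compute_pcs(panel, k=2)
        perm = rng.permutation(40)
        panel_p = GenotypePanel(panel.genotypes.iloc[perm], panel.snp_info, "EUR")
        scores_p = compute_pcs(panel_p, k=2)
        pd.testing.assert_frame_equal(scores.iloc[perm], scores_p)

    def test_orthogonal_and_ordered(self, rng):
        geno = rng.binomial(2, 0.3, (50, 80)).astype(float)
        scores = compute_pcs(_panel(geno), k=3)
        s = scores.to_numpy()
        assert abs(s[:, 0] @ s[:, 1]) < 1e-8
        assert s[:, 0].var() >= s[:, 1].var() >= s[:, 2].var()


class TestSnpLogistic:
    def test_two_by_two_closed_form(self):
        # carriers: 30 of 100 died; non-carriers: 10 of 100 died
        dose = np.repeat([1.0, 0.0], 100)
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
        panel = _panel(dose[:, None])
        res = snp_logistic_assoc(panel, _phenotypes(y.astype(int)))
        expected = np.log(30 * 90 / (70 * 10))
        assert res["beta"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_agreement_with_statsmodels(self, rng):
        geno = rng.binomial(2, 0.3, (300, 20)).astype(float)
        y = rng.integers(0, 2, 300)
        panel = _panel(geno)
        res = snp_logistic_assoc(panel, _phenotypes(y)).set_index("snp_id")
        for j in rng.choice(20, 5, replace=False):
            X = sm.add_constant(geno[:, j])
            ref = sm.Logit(y, X).fit(disp=0)
            assert res.loc[f"snp{j}", "beta"] == pytest.approx(ref.params[1], abs=1e-6)
            assert res.loc[f"snp{j}", "p"] == pytest.approx(ref.pvalues[1], abs=1e-6)

    def test_null_p_values_uniform(self, rng):
        geno = rng.binomial(2, 0.3, (500, 150)).astype(float)
        y = rng.integers(0, 2, 500)
        res = snp_logistic_assoc(_panel(geno), _phenotypes(y))
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_constant_phenotype_raises(self, rng):
        geno = rng.binomial(2, 0.3, (50, 3)).astype(float)
        with pytest.raises(ValueError, match="constant"):
            snp_logistic_assoc(_panel(geno), _phenotypes(np.zeros(50, dtype=int)))


class TestSnpGeneMapping:
    def _regions(self):
        return pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": "1",
                             "start": [100_000, 100_500],
                             "end": [101_000, 102_000]})

    def test_boundary_inclusion(self):
        info = pd.DataFrame({"snp_id": ["s1"], "chrom": "1", "pos": [50_001],
                             "a1": "A", "a2": "G"})
        mapping = map_snps_to_genes(info, self._regions())
        assert "s1" in mapping["gA"]

    def test_boundary_exclusion(self):
        info = pd.DataFrame({"snp_id": ["s1"], "chrom": "1", "pos": [49_999],
                             "a1": "A", "a2": "G"})
        mapping = map_snps_to_genes(info, self._regions())
        assert "gA" not in mapping

    def test_multi_assignment_to_overlapping_windows(self):
        info = pd.DataFrame({"snp_id": ["s1"], "chrom": "1", "pos": [100_700],
                             "a1": "A", "a2": "G"})
        mapping = map_snps_to_genes(info, self._regions())
        assert "s1" in mapping["gA"] and "s1" in mapping["gB"]

    def test_bed_conversion_is_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t200\tgX\n")
        regions = bed_to_regions(bed)
        assert regions.loc[0, "start"] == 100 and regions.loc[0, "end"] == 200


class TestGeneBasedTest:
    def test_single_snp_identity(self, rng):
        res = gene_based_test([0.05], np.eye(1), n_sims=100_000, rng=rng,
                              max_sims=100_000)
        mc_se = np.sqrt(0.05 * 0.95 / 100_000)
        assert abs(res.p_empirical - 0.05) < 3 * mc_se

    def test_independent_snps_match_chi2(self, rng):
        p_in = np.array([0.2, 0.5, 0.01, 0.8, 0.3])
        res = gene_based_test(p_in, np.eye(5), n_sims=100_000, rng=rng,
                              max_sims=100_000)
        target = stats.chi2.sf(res.observed_stat, 5)
        mc_se = np.sqrt(target * (1 - target) / res.n_sims)
        assert abs(res.p_empirical - target) < 3 * mc_se

    def test_perfect_ld_collapses_to_single_snp(self, rng):
        res = gene_based_test([0.05, 0.05], np.ones((2, 2)), n_sims=100_000,
                              rng=rng, max_sims=100_000)
        # two copies of one signal: p stays near 0.05, not Fisher-combined
        assert abs(res.p_empirical - 0.05) < 0.01
        assert res.p_empirical > fisher_meta([0.05, 0.05])

    def test_adaptive_escalation_on_small_p(self, rng):
        res = gene_based_test([1e-6], np.eye(1), n_sims=1000, rng=rng,
                              max_sims=100_000)
        assert res.n_sims == 100_000  # escalated past the initial 1000
        assert res.p_empirical > 0.0  # add-one smoothing

    def test_empty_gene_raises(self, rng):
        with pytest.raises(ValueError):
            gene_based_test([], np.eye(0), rng=rng)

    def test_zero_p_clamped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="clamped"):
            res = gene_based_test([0.0], np.eye(1), n_sims=1000, rng=rng,
                                  max_sims=1000)
        assert np.isfinite(res.observed_stat)


class TestFisherMeta:
    def test_closed_form_two_halves(self):
        # X = -2(ln .5 + ln .5) = 2.7726; chi2_4 survival = 0.5966
        assert fisher_meta([0.5, 0.5]) == pytest.approx(0.5966, abs=5e-5)

    def test_single_p_identity(self):
        assert fisher_meta([0.123]) == pytest.approx(0.123, abs=1e-12)

    def test_all_ones(self):
        assert fisher_meta([1.0, 1.0]) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        ps = rng.uniform(0.01, 1.0, 5)
        assert fisher_meta(ps) == pytest.approx(fisher_meta(ps[::-1]), rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fisher_meta([])


class TestBonferroni:
    def test_gene_count_threshold(self):
        assert bonferroni_threshold(23_678) == pytest.approx(2.11e-6, rel=5e-3)

    def test_identity_and_scaling(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(1000) == pytest.approx(5e-5)


class TestVcfInput:
    def test_minimal_vcf_round_trip(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t0/0\n")
        panel = read_vcf_genotypes(vcf)
        assert panel.genotypes.loc["A", "rs1"] == 0.0
        assert panel.genotypes.loc["B", "rs1"] == 1.0
        assert panel.genotypes.loc["C", "rs1"] == 2.0
        assert np.isnan(panel.genotypes.loc["A", "rs2"])
        assert panel.snp_info["pos"].tolist() == [100, 200]


class TestLdEstimation:
    def test_ld_diagonal_and_range(self, rng):
        geno = rng.binomial(2, 0.3, (100, 6)).astype(float)
        panel = _panel(geno)
        ld = estimate_ld(panel, [f"snp{j}" for j in range(6)])
        assert np.allclose(np.diag(ld), 1.0)
        assert np.all(np.abs(ld) <= 1.0 + 1e-12)
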