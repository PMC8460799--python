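"""Splits, logistic fits, stepwise selection, ROC, cutpoints."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import statsmodels.api as sm

from ardsomics.mortality_prediction import (
    fit_logistic,
    good_model_check,
    optimal_cutpoint,
    protein_model_pipeline,
    roc_auc,
    stepwise_logistic,
    stratified_split,
    transcription_model_pipeline,
)
from ardsomics.synthetic_cohort import generate_cohort

from conftest import small_config


class TestStratifiedSplit:
    def test_balanced_ten_subjects(self):
        spec = stratified_split(list(range(10)), [0] * 5 + [1] * 5, 0.7, seed=1)
        assert len(spec.train_ids) == 7 and len(spec.test_ids) == 3
        labels = {i: int(i >= 5) for i in range(10)}
        train_pos = sum(labels[i] for i in spec.train_ids)
        assert train_pos in (3, 4)  # per-class rounding 4+3 or 3+4

    def test_seeded_determinism(self):
        a = stratified_split(list(range(30)), [0] * 20 + [1] * 10, seed=9)
        b = stratified_split(list(range(30)), [0] * 20 + [1] * 10, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            stratified_split([1, 2, 3], [1, 1, 1])

    def test_partition_is_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(47)]
        labels = [i % 3 == 0 for i in range(47)]
        spec = stratified_split(ids, labels, seed=2)
        assert set(spec.train_ids) | set(spec.test_ids) == set(ids)
        assert not set(spec.train_ids) & set(spec.test_ids)


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        x = pd.DataFrame({"f": np.repeat([1.0, 0.0], 100)})
        y = pd.Series(np.concatenate(
            [np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]))
        fit = fit_logistic(x, y)
        assert fit.coef[1] == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
        assert fit.coef[1] == pytest.approx(1.35, abs=0.01)

    def test_agreement_with_statsmodels(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (150, 3)), columns=list("abc"))
        y = pd.Series((rng.random(150) < expit(X["a"] - 0.5)).astype(int),
                      index=X.index)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.p, ref.pvalues.to_numpy(), atol=1e-6)

    def test_constant_feature_excluded(self, rng):
        X = pd.DataFrame({"zero": np.zeros(60), "x": rng.normal(0, 1, 60)})
        y = pd.Series(rng.integers(0, 2, 60), index=X.index)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_logistic(X, y)
        assert fit.names == ["(intercept)", "x"]

    def test_separation_flagged(self):
        x = pd.DataFrame({"f": np.concatenate([np.zeros(20), np.ones(20)])})
        y = pd.Series(np.concatenate([np.zeros(20), np.ones(20)]))
        fit = fit_logistic(x, y)
        assert fit.separated


class TestStepwise:
    def test_sle_zero_selects_nothing(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 4)), columns=list("abcd"))
        y = pd.Series(rng.integers(0, 2, 100), index=X.index)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = stepwise_logistic(X, y, sle=0.0)
        assert model.selected == []

    def test_sle_sls_one_selects_all(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 4)), columns=list("abcd"))
        y = pd.Series(rng.integers(0, 2, 100), index=X.index)
        model = stepwise_logistic(X, y, sle=1.0, sls=1.0)
        assert set(model.selected) == set("abcd")

    def test_strong_predictor_enters_first(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (300, 5)),
                         columns=[f"p{j}" for j in range(5)])
        y = pd.Series((rng.random(300) < expit(-1 + 1.5 * X["p3"])).astype(int),
                      index=X.index)
        model = stepwise_logistic(X, y)
        assert model.history[0] == ("enter", "p3", model.history[0][2])


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=50, seed=0)
        assert r.auc == 1.0

    def test_exhaustive_pair_counting(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        r = roc_auc(scores, labels, n_boot=10, seed=0)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n)
                   for p, n in itertools.product(pos, neg))
        assert r.auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)

    def test_interleaved_example(self):
        r = roc_auc([1, 2, 3, 4], [0, 1, 0, 1], n_boot=50, seed=0)
        assert r.auc == pytest.approx(0.75)

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(0, 1, 500)
        labels = rng.integers(0, 2, 500)
        r = roc_auc(scores, labels, n_boot=50, seed=0)
        assert abs(r.auc - 0.5) < 0.05

    def test_score_negation_complements(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        a1 = roc_auc(scores, labels, n_boot=10, seed=0).auc
        a2 = roc_auc(-scores, labels, n_boot=10, seed=0).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_ci_covers_point_estimate(self):
        covered = 0
        for seed in range(60):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 2, 80)
            if labels.sum() in (0, 80):
                labels[0] = 1 - labels[0]
            scores = r.normal(0, 1, 80) + 0.8 * labels
            roc = roc_auc(scores, labels, n_boot=400, seed=seed)
            if roc.ci90[0] <= roc.auc <= roc.ci90[1]:
                covered += 1
        assert covered >= 51  # >= 85% of repetitions


class TestGoodModel:
    def test_reported_model_passes(self):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10, seed=0)
        r.auc, r.ci90 = 0.83, (0.62, 1.00)
        assert good_model_check(r)

    @pytest.mark.parametrize("auc,lo", [(0.72, 0.49), (0.70, 0.6), (0.69, 0.55)])
    def test_boundary_failures(self, auc, lo):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10, seed=0)
        r.auc, r.ci90 = auc, (lo, 1.0)
        assert not good_model_check(r)


class TestOptimalCutpoint:
    def test_perfectly_separated(self):
        res = optimal_cutpoint([10, 10, 14, 14], [0, 0, 1, 1])
        assert res.threshold == 12.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_matches_brute_force_on_toy(self):
        scores = [13, 15, 9, 8, 20, 5, 6, 7, 11, 10]
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        res = optimal_cutpoint(scores, labels)
        s, l = np.asarray(scores, float), np.asarray(labels)
        distinct = np.unique(s)
        best = max(((s >= t)[l == 1].mean() + (s < t)[l == 0].mean() - 1)
                   for t in (distinct[:-1] + distinct[1:]) / 2)
        got = res.sensitivity + res.specificity - 1
        assert got == pytest.approx(best, rel=1e-12)

    def test_brute_force_property_random_data(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 1, 40)
            labels = rng.integers(0, 2, 40)
            if labels.sum() in (0, 40):
                labels[0] = 1 - labels[0]
            res = optimal_cutpoint(scores, labels)
            distinct = np.unique(scores)
            youden = [(scores >= t)[labels == 1].mean()
                      + (scores < t)[labels == 0].mean() - 1
                      for t in (distinct[:-1] + distinct[1:]) / 2]
            assert res.sensitivity + res.specificity - 1 == pytest.approx(
                max(youden), rel=1e-12)

    def test_degenerate_equal_scores(self):
        res = optimal_cutpoint([5, 5, 5], [1, 0, 1])
        assert res.degenerate


class TestProteinPipeline:
    def test_coverage_boundary_excluded(self, rng):
        ids = [f"s{i}" for i in range(300)]
        rows = []
        for i, s in enumerate(ids):
            for day in (0, 7):
                rows.append((s, "rich", day, float(rng.lognormal(2, 0.3))))
                if i < 149:
                    rows.append((s, "sparse", day, float(rng.lognormal(2, 0.3))))
        proteins = pd.DataFrame(rows, columns=["subject_id", "protein_name",
                                               "day", "concentration"])
        pheno = pd.DataFrame({"subject_id": ids,
                              "death_28d": rng.integers(0, 2, 300),
                              "age": 50.0, "sex": "M", "ancestry": "EUR"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = protein_model_pipeline(proteins, pheno, seed=0, n_boot=50)
        assert rep["proteins_retained"] == ["rich"]
        assert rep["proteins_excluded"] == ["sparse"]

    def test_study_like_coverage_retains_seven_of_eleven(self):
        cfg = small_config(
            n_subjects_total=300,
            n_per_omic={"genetics": 50, "rnaseq": 30, "longitudinal": 40,
                        "methylation": 30, "protein": 240}, seed=8)
        bundle, _ = generate_cohort(cfg)
        coverage = bundle.proteins.groupby("protein_name")["subject_id"].nunique()
        assert (coverage >= 150).sum() == 7

    def test_empty_candidate_set_raises(self, rng):
        proteins = pd.DataFrame({
            "subject_id": ["s1"], "protein_name": ["p"], "day": [0],
            "concentration": [1.0]})
        pheno = pd.DataFrame({"subject_id": ["s1"], "death_28d": [1],
                              "age": [50.0], "sex": ["M"], "ancestry": ["EUR"]})
        with pytest.raises(ValueError, match="coverage"):
            protein_model_pipeline(proteins, pheno)


class TestTranscriptionPipeline:
    def test_strong_signal_yields_good_model(self, rng):
        n = 120
        ids = [f"s{i}" for i in range(n)]
        y = rng.integers(0, 2, n)
        expr = pd.DataFrame(rng.normal(0, 1, (6, n)),
                            index=[f"g{i}" for i in range(6)], columns=ids)
        expr.loc["g0"] += 2.0 * y
        pheno = pd.DataFrame({"subject_id": ids, "death_28d": y,
                              "age": 50.0, "sex": "M", "ancestry": "EUR"})
        rep = transcription_model_pipeline(expr, ["g0", "g1"], pheno,
                                           seed=1, n_boot=100)
        assert rep["roc"].auc > 0.8
        assert rep["good_model"]

    def test_no_candidate_genes_raises(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (2, 4)), index=["a", "b"],
                            columns=["s0", "s1", "s2", "s3"])
        pheno = pd.DataFrame({"subject_id": ["s0", "s1", "s2", "s3"],
                              "death_28d": [0, 1, 0, 1], "age": 50.0,
                              "sex": "M", "ancestry": "EUR"})
        with pytest.raises(ValueError, match="candidate"):
            transcription_model_pipeline(expr, ["zz"], pheno)
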