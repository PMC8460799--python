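"""Mortality-prediction models for transcription and protein biomarkers.

Builds the two prediction arms: a logistic model of 28-day death on the
candidate gene set's baseline expression, and protein models with
stepwise variable selection (score-test entry / Wald-test stay at
SLE = SLS = 0.25) over analytes with sufficient assay coverage.  Models
are developed on stratified 7:3 train/test splits, evaluated by ROC AUC
(Mann-Whitney with tie correction) with a 90% subject-level percentile
bootstrap interval, judged by the "good model" rule (AUC > 0.70 with CI
lower limit > 0.50), and, for a single circulating biomarker, reduced
to an optimal concentration cutpoint maximizing the Youden index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import LogisticFit, logistic_irls

__all__ = [
    "SplitSpec",
    "RocResult",
    "CutpointResult",
    "stratified_split",
    "fit_logistic",
    "stepwise_logistic",
    "roc_auc",
    "good_model_check",
    "optimal_cutpoint",
    "transcription_model_pipeline",
    "protein_model_pipeline",
]


@dataclass
class SplitSpec:
    train_ids: list
    test_ids: list
    validation_ids: list
    ratio: float
    seed: int


@dataclass
class RocResult:
    auc: float
    ci90: tuple
    n_boot: int
    curve: pd.DataFrame  # fpr, tpr, threshold


@dataclass
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    objective: str = "youden"
    degenerate: bool = False


@dataclass
class StepwiseModel:
    selected: list
    fit: LogisticFit | None
    history: list = field(default_factory=list)


def stratified_split(ids, labels, ratio: float = 0.7, seed: int = 0,
                     validation_ids=None) -> SplitSpec:
    """Seeded stratified train/test split preserving class proportions.

    Per-class training counts follow the largest-remainder rule so the
    total matches ``round(ratio * n)`` with per-class deviation at most
    one subject; every class is guaranteed at least one subject in both
    parts.  ``validation_ids`` (already held out) pass through.
    """
    ids = list(ids)
    labels = np.asarray(list(labels))
    if len(ids) != labels.size:
        raise ValueError("ids and labels length mismatch")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("single-class input; stratified split undefined")
    rng = np.random.default_rng(seed)
    n_train_total = int(round(ratio * len(ids)))
    quotas = {}
    remainders = []
    for c in classes:
        exact = ratio * int((labels == c).sum())
        quotas[c] = int(np.floor(exact))
        remainders.append((exact - quotas[c], rng.random(), c))
    short = n_train_total - sum(quotas.values())
    for _, _, c in sorted(remainders, reverse=True)[:short]:
        quotas[c] += 1
    train, test = [], []
    for c in classes:
        members = [i for i, lab in zip(ids, labels) if lab == c]
        rng.shuffle(members)
        q = min(max(quotas[c], 1), len(members) - 1)  # both parts non-empty
        train.extend(members[:q])
        test.extend(members[q:])
    return SplitSpec(train_ids=sorted(train), test_ids=sorted(test),
                     validation_ids=sorted(validation_ids or []),
                     ratio=ratio, seed=seed)


def fit_logistic(features: pd.DataFrame, labels: pd.Series) -> LogisticFit:
    """IRLS logistic regression of a binary outcome on feature columns.

    Zero-variance features are excluded (reported in the fit's names as
    absent).  Coefficients are ordered intercept first, then the
    retained feature columns (see ``fit.names``).
    """
    y = labels.loc[features.index].to_numpy(dtype=float)
    x = features.to_numpy(dtype=float)
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(features.columns, keep) if not k]
        warnings.warn(f"constant feature(s) excluded: {dropped}", stacklevel=2)
    x = x[:, keep]
    names = ["(intercept)"] + [c for c, k in zip(features.columns, keep) if k]
    X = np.column_stack([np.ones(len(y)), x])
    return logistic_irls(X, y, names=names)


def _score_test_p(X_base: np.ndarray, y: np.ndarray, x_new: np.ndarray) -> float:
    """Rao score test p-value for adding one covariate to a logistic model."""
    fit = logistic_irls(X_base, y)
    mu = 1.0 / (1.0 + np.exp(-np.clip(X_base @ fit.coef, -30, 30)))
    w = mu * (1.0 - mu)
    u = float(x_new @ (y - mu))
    xtwx = X_base.T @ (X_base * w[:, None]) + 1e-10 * np.eye(X_base.shape[1])
    xtwz = X_base.T @ (x_new * w)
    v = float(x_new @ (x_new * w) - xtwz @ np.linalg.solve(xtwx, xtwz))
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, 1))


def stepwise_logistic(candidates: pd.DataFrame, labels: pd.Series,
                      sle: float = 0.25, sls: float = 0.25) -> StepwiseModel:
    """Forward-backward stepwise logistic selection.

    Forward steps add the candidate with the smallest score-test p-value
    when it is below ``sle``; backward steps remove the in-model term
    with the largest Wald p-value above ``sls``; the two alternate until
    stable.  Ties break by candidate column order.  With no entering
    candidate the intercept-only model is returned with a warning.
    """
    y = labels.loc[candidates.index].to_numpy(dtype=float)
    cols = [c for c in candidates.columns
            if candidates[c].std() > 0]
    selected: list = []
    history: list = []
    seen_states = {frozenset()}
    changed = True
    while changed:
        changed = False
        # forward
        base = np.column_stack(
            [np.ones(len(y))] + [candidates[c].to_numpy(dtype=float) for c in selected])
        best_p, best_c = None, None
        for c in cols:
            if c in selected:
                continue
            p = _score_test_p(base, y, candidates[c].to_numpy(dtype=float))
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < sle:
            selected.append(best_c)
            history.append(("enter", best_c, best_p))
            changed = True
        # backward
        while selected:
            X = np.column_stack(
                [np.ones(len(y))] + [candidates[c].to_numpy(dtype=float) for c in selected])
            fit = logistic_irls(X, y)
            wald = fit.p[1:]
            worst = int(np.argmax(wald))
            if wald[worst] > sls:
                removed = selected.pop(worst)
                history.append(("remove", removed, float(wald[worst])))
                changed = True
            else:
                break
        # a revisited model means enter/remove cycling; stop at this state
        state = frozenset(selected)
        if changed and state in seen_states:
            break
        seen_states.add(state)
    if not selected:
        warnings.warn("no candidate entered; intercept-only model", stacklevel=2)
        fit = logistic_irls(np.ones((len(y), 1)), y)
        fit.names = ["(intercept)"]
        return StepwiseModel(selected=[], fit=fit, history=history)
    final = fit_logistic(candidates[selected], labels)
    return StepwiseModel(selected=selected, fit=final, history=history)


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """ROC AUC with tie-corrected Mann-Whitney estimate and bootstrap CI.

    AUC = U / (n1 * n0) with half credit for ties; the 90% interval is a
    subject-level percentile bootstrap (5th/95th percentiles).  The
    curve enumerates every distinct score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1} or np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes, coded 0/1")
    auc = _auc_mann_whitney(scores, labels)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = scores.size
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if np.unique(labels[idx]).size == 2:
                break
        boot[b] = _auc_mann_whitney(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [5.0, 95.0])
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tpr = [(scores[labels == 1] >= t).mean() for t in thresholds]
    fpr = [(scores[labels == 0] >= t).mean() for t in thresholds]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocResult(auc=float(auc), ci90=(float(lo), float(hi)),
                     n_boot=n_boot, curve=curve)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def good_model_check(roc: RocResult) -> bool:
    """AUC strictly above 0.70 with CI lower limit strictly above 0.50."""
    return roc.auc > 0.70 and roc.ci90[0] > 0.50


def optimal_cutpoint(scores, labels, objective: str = "youden") -> CutpointResult:
    """Optimal biomarker threshold over all midpoints between distinct scores.

    Positive (death) calls are scores at or above the threshold.  The
    Youden index sensitivity + specificity - 1 is maximized; ties break
    toward higher specificity, then the higher threshold.
    """
    if objective != "youden":
        raise ValueError(f"unsupported objective: {objective}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        return CutpointResult(threshold=float(distinct[0]),
                              sensitivity=1.0, specificity=0.0,
                              degenerate=True)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for t in mids:
        pred = scores >= t
        sens = float(pred[labels == 1].mean())
        spec = float((~pred)[labels == 0].mean())
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return CutpointResult(threshold=float(t), sensitivity=sens, specificity=spec)


def transcription_model_pipeline(expr: pd.DataFrame, genes, phenotypes: pd.DataFrame,
                                 ratio: float = 0.7, seed: int = 0,
                                 n_boot: int = 2000) -> dict:
    """Candidate-gene logistic model on baseline expression.

    ``expr`` is gene x subject (normalized); the model regresses death
    on the candidate genes' expression, trains on a stratified 7:3
    split, and reports the test-set ROC.
    """
    genes = [g for g in genes if g in expr.index]
    if not genes:
        raise ValueError("no candidate genes present in expression data")
    pheno = phenotypes.set_index("subject_id")
    subjects = [s for s in expr.columns if s in pheno.index]
    y = pheno.loc[subjects, "death_28d"]
    split = stratified_split(subjects, y.loc[subjects], ratio=ratio, seed=seed)
    X = expr.loc[genes, subjects].T
    fit = fit_logistic(X.loc[split.train_ids], y)
    test_scores = fit.predict_proba(
        np.column_stack([np.ones(len(split.test_ids)),
                         X.loc[split.test_ids,
                               [n for n in fit.names if n != "(intercept)"]]]))
    roc = roc_auc(test_scores, y.loc[split.test_ids].to_numpy(),
                  n_boot=n_boot, seed=seed)
    return {"split": split, "fit": fit, "roc": roc,
            "good_model": good_model_check(roc), "genes": genes}


def protein_model_pipeline(proteins: pd.DataFrame, phenotypes: pd.DataFrame,
                           min_n: int = 150, trainpool_n: int = 190,
                           ratio: float = 0.7, seed: int = 0,
                           sle: float = 0.25, sls: float = 0.25,
                           n_boot: int = 2000) -> dict:
    """Protein biomarker models with stepwise selection and validation.

    Proteins measured in fewer than ``min_n`` subjects are excluded.
    ``trainpool_n`` subjects form the stratified 7:3 train/test pool and
    the remainder the validation cohort.  Day-0 and day-7 models are
    developed independently; each reports the stepwise-selected
    analytes, test-set and validation-set ROC, and — when a single-
    analyte day-7 model emerges — the optimal concentration cutpoint on
    the validation set.
    """
    coverage = proteins.groupby("protein_name")["subject_id"].nunique()
    retained = sorted(coverage.index[coverage >= min_n])
    if not retained:
        raise ValueError("no protein meets the coverage requirement")
    pheno = phenotypes.set_index("subject_id")
    report: dict = {"proteins_retained": retained,
                    "proteins_excluded": sorted(coverage.index[coverage < min_n])}
    rng = np.random.default_rng(seed)
    all_ids = sorted(set(proteins["subject_id"]) & set(pheno.index))
    if len(all_ids) > trainpool_n:
        pool = sorted(rng.choice(all_ids, size=trainpool_n, replace=False))
    else:
        pool = all_ids
    validation = sorted(set(all_ids) - set(pool))
    report["n_trainpool"] = len(pool)
    report["n_validation"] = len(validation)
    for day in (0, 7):
        wide = (proteins[(proteins["day"] == day)
                         & proteins["protein_name"].isin(retained)]
                .pivot_table(index="subject_id", columns="protein_name",
                             values="concentration", aggfunc="first"))
        wide = wide.dropna()
        pool_ids = [s for s in pool if s in wide.index]
        val_ids = [s for s in validation if s in wide.index]
        y = pheno.loc[wide.index, "death_28d"]
        split = stratified_split(pool_ids, y.loc[pool_ids], ratio=ratio,
                                 seed=seed, validation_ids=val_ids)
        model = stepwise_logistic(wide.loc[split.train_ids], y.loc[split.train_ids],
                                  sle=sle, sls=sls)
        entry = {"split": split, "model": model, "selected": model.selected}
        if model.selected:
            def _scores(ids):
                Xm = wide.loc[ids, model.selected].to_numpy(dtype=float)
                return model.fit.predict_proba(
                    np.column_stack([np.ones(len(ids)), Xm]))
            roc_test = roc_auc(_scores(split.test_ids),
                               y.loc[split.test_ids].to_numpy(),
                               n_boot=n_boot, seed=seed)
            entry["roc_test"] = roc_test
            entry["good_model"] = good_model_check(roc_test)
            if val_ids and y.loc[val_ids].nunique() == 2:
                entry["roc_validation"] = roc_auc(
                    _scores(val_ids), y.loc[val_ids].to_numpy(),
                    n_boot=n_boot, seed=seed)
            top = model.selected[0]
            if val_ids and y.loc[val_ids].nunique() == 2:
                entry["cutpoint"] = optimal_cutpoint(
                    wide.loc[val_ids, top].to_numpy(),
                    y.loc[val_ids].to_numpy())
                entry["cutpoint_protein"] = top
        report[f"day{day}"] = entry
    return report
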