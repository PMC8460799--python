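"""Longitudinal gene-set validation on day-0/7/14 expression.

Candidate pathways are validated against the longitudinal transcription
cohort: genes are standardized across all measurements, group-wise
median gene-set trajectories summarize the pattern, and a permutation
score test asks whether the expression pattern over time differs
between survivors and non-survivors.  The statistic

    Q = sum_genes sum_days n_eff(g, d) * (mean_NS(g, d) - mean_S(g, d))^2

(with n_eff the harmonic mean of the per-group subject counts at that
gene/day cell) is compared with its distribution under random
permutation of subject group labels; permuting subjects rather than
rows preserves within-subject correlation.  The parametric mixed-model
score test this realizes is itself approximated by permutation here, as
is appropriate for the small samples the design targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from ._stats import bh_adjust

__all__ = [
    "GeneSetTrajectoryResult",
    "standardize_genes",
    "median_set_trajectory",
    "trajectory_group_test",
    "run_trajectory_tests",
    "cluster_patterns",
]


@dataclass
class GeneSetTrajectoryResult:
    pathway: str
    statistic: float
    p_perm: float
    n_perm: int
    p_adj: float = np.nan
    median_trajectories: pd.DataFrame | None = None  # group x day medians


def standardize_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene to mean 0, SD 1 across all measurements.

    ``expr`` is long-format (subject_id, day, gene, value).  Genes with
    zero variance are dropped with a warning.
    """
    out = expr.copy()
    stats_ = out.groupby("gene")["value"].agg(["mean", "std"])
    zero_sd = stats_.index[(stats_["std"] == 0) | stats_["std"].isna()]
    if len(zero_sd):
        warnings.warn(f"{len(zero_sd)} constant gene(s) dropped", stacklevel=2)
        out = out[~out["gene"].isin(zero_sd)]
    mu = out["gene"].map(stats_["mean"])
    sd = out["gene"].map(stats_["std"])
    out = out.assign(value=(out["value"] - mu) / sd)
    return out.reset_index(drop=True)


def median_set_trajectory(expr: pd.DataFrame, gene_set, groups: pd.Series,
                          group: str | int) -> pd.Series:
    """Per-day median of (subject, gene) values for one group's gene set."""
    genes = set(gene_set)
    sub = expr[expr["gene"].isin(genes)]
    in_group = sub["subject_id"].map(groups) == group
    return sub[in_group].groupby("day")["value"].median()


def _cell_matrix(expr: pd.DataFrame, gene_set):
    """Pivot to subjects x (gene, day) cell means; returns (X, mask, subjects)."""
    genes = set(gene_set)
    sub = expr[expr["gene"].isin(genes)]
    pivot = sub.pivot_table(index="subject_id", columns=["gene", "day"],
                            values="value", aggfunc="mean")
    x = pivot.to_numpy(dtype=float)
    return x, ~np.isnan(x), list(pivot.index)


def _q_statistics(x: np.ndarray, mask: np.ndarray,
                  labels: np.ndarray) -> np.ndarray:
    """Vectorized Q for one or many label assignments.

    ``labels`` is (n_perm, n_subjects) of 0/1; returns one Q per row.
    Cells where either group is empty are skipped.
    """
    x0 = np.where(mask, x, 0.0)
    m = mask.astype(float)
    n1 = labels @ m                       # per-perm, per-cell group-1 counts
    n0 = (1.0 - labels) @ m
    s1 = labels @ x0
    s0 = (1.0 - labels) @ x0
    valid = (n1 > 0) & (n0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = s1 / n1 - s0 / n0
        n_eff = 2.0 * n1 * n0 / (n1 + n0)  # harmonic mean of group counts
    contrib = np.where(valid, n_eff * diff ** 2, 0.0)
    return contrib.sum(axis=1)


def trajectory_group_test(expr: pd.DataFrame, gene_set, groups: pd.Series,
                          n_perm: int = 1000,
                          rng: np.random.Generator | None = None,
                          pathway: str = "") -> GeneSetTrajectoryResult:
    """Permutation test of group-by-time expression-pattern differences.

    ``groups`` maps subject -> {0 (survivor), 1 (non-survivor)}.  The
    permutation p-value uses add-one smoothing and is never exactly 0.
    A warning is emitted for gene/day cells where one group is empty;
    those terms are skipped.
    """
    if rng is None:
        rng = np.random.default_rng()
    x, mask, subjects = _cell_matrix(expr, gene_set)
    if x.size == 0:
        raise ValueError("gene set has no measurements")
    lab = np.asarray([groups[s] for s in subjects], dtype=float)
    if min(int((lab == 1).sum()), int((lab == 0).sum())) < 2:
        raise ValueError("need >= 2 subjects with data in each group")
    n1_cell = (lab[None, :] @ mask.astype(float)).ravel()
    n0_cell = ((1 - lab)[None, :] @ mask.astype(float)).ravel()
    if np.any((n1_cell == 0) | (n0_cell == 0)):
        warnings.warn("cells with an empty group skipped in Q", stacklevel=2)
    observed = float(_q_statistics(x, mask, lab[None, :])[0])
    perms = np.empty((n_perm, lab.size))
    for i in range(n_perm):
        perms[i] = rng.permutation(lab)
    null = _q_statistics(x, mask, perms)
    p = (1.0 + float(np.sum(null >= observed - 1e-12))) / (1.0 + n_perm)
    medians = pd.DataFrame({
        g: median_set_trajectory(expr, gene_set, groups, lab_val)
        for g, lab_val in (("survivor", 0), ("non_survivor", 1))
    }).T
    return GeneSetTrajectoryResult(pathway=pathway, statistic=observed,
                                   p_perm=p, n_perm=n_perm,
                                   median_trajectories=medians)


def run_trajectory_tests(expr: pd.DataFrame, pathways: dict,
                            groups: pd.Series, n_perm: int = 1000,
                            rng: np.random.Generator | None = None) -> list:
    """Run the trajectory test per pathway and BH-adjust across pathways."""
    if rng is None:
        rng = np.random.default_rng()
    results = [trajectory_group_test(expr, genes, groups, n_perm=n_perm,
                                     rng=rng, pathway=name)
               for name, genes in pathways.items()]
    adj = bh_adjust(np.array([r.p_perm for r in results]))
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    return results


def cluster_patterns(expr: pd.DataFrame, gene_set, groups: pd.Series,
                     group, max_k: int = 4) -> dict:
    """Cluster within-group gene trajectories (complete-linkage, Euclidean).

    Each gene is summarized by its mean per-day trajectory in the group;
    the cut is chosen by mean silhouette over k in 2..max_k, falling
    back to a single cluster when no k reaches a mean silhouette of
    0.25.  Cluster labels are relabeled by the lexicographically
    smallest member gene so the output is invariant to input order.
    """
    genes = sorted(set(gene_set))
    sub = expr[expr["gene"].isin(genes)]
    in_group = sub["subject_id"].map(groups) == group
    traj = (sub[in_group].groupby(["gene", "day"])["value"].mean()
            .unstack("day").loc[[g for g in genes if g in
                                 sub[in_group]["gene"].unique()]])
    if traj.shape[0] == 0:
        raise ValueError("no genes with data in this group")
    if traj.shape[0] == 1:
        return {traj.index[0]: 1}
    x = traj.to_numpy(dtype=float)
    z = linkage(x, method="complete", metric="euclidean")
    if np.allclose(pdist(x), 0):
        return {g: 1 for g in traj.index}
    best_k, best_sil = 1, -1.0
    for k in range(2, min(max_k, traj.shape[0] - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        sil = silhouette_score(x, labels, metric="euclidean")
        if sil > best_sil:
            best_k, best_sil = k, sil
    if best_sil < 0.25:
        best_k = 1
    if best_k == 1:
        return {g: 1 for g in traj.index}
    labels = fcluster(z, t=best_k, criterion="maxclust")
    # canonical relabeling: clusters ordered by their smallest gene id
    by_cluster = {}
    for g, lab in zip(traj.index, labels):
        by_cluster.setdefault(lab, []).append(g)
    order = sorted(by_cluster, key=lambda lab: min(by_cluster[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {g: remap[lab] for g, lab in zip(traj.index, labels)}
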