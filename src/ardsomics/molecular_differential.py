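"""Single-omic differential analyses for ARDS mortality.

Three arms share this module: RNA-seq differential expression (low-count
filter, median-of-ratios variance-stabilizing normalization, and an
empirical-Bayes moderated t-test with Benjamini-Hochberg FDR);
methylation (M-values from intensity pairs, probe/sample detection
filters, pooled quantile normalization across the two array platforms,
probe-wise two-group tests); and per-protein logistic regression of
28-day death on concentration with age and sex as covariates, fitted
separately at day 0 and day 7 to avoid within-subject correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from ._stats import bh_adjust, logistic_irls

__all__ = [
    "filter_low_counts",
    "vst_normalize",
    "moderated_t_de",
    "fit_variance_prior",
    "compute_m_values",
    "filter_probes",
    "quantile_normalize_pooled",
    "probe_differential",
    "protein_logistic",
]


# ---------------------------------------------------------------------------
# RNA-seq arm

def filter_low_counts(counts: pd.DataFrame, min_count: int = 6,
                      per_sample: bool = False):
    """Remove low-expression genes.

    By default a gene is removed when its total count across samples is
    below ``min_count`` (a total of exactly ``min_count`` is retained);
    with ``per_sample=True`` the criterion is instead that every sample
    is below ``min_count``.  Returns ``(filtered, removed_gene_list)``.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
    if per_sample:
        keep = (counts >= min_count).any(axis=1)
    else:
        keep = counts.sum(axis=1) >= min_count
    removed = counts.index[~keep].tolist()
    return counts.loc[keep], removed


def vst_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing normalization of filtered counts.

    Size factors are median-of-ratios against the geometric-mean
    reference over genes expressed in every sample; the stabilized value
    is ``log2(count / size_factor + 1)``.  Monotone in counts, and a
    sample whose library is scaled by a constant keeps (up to the +1
    offset) the same normalized column.
    """
    x = counts.to_numpy(dtype=float)
    if np.any(x.sum(axis=0) == 0):
        raise ValueError("sample with all-zero counts")
    positive = np.all(x > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene expressed in every sample; cannot form reference")
    log_ref = np.mean(np.log(x[positive]), axis=1)
    size_factors = np.exp(np.median(np.log(x[positive]) - log_ref[:, None], axis=0))
    y = np.log2(x / size_factors + 1.0)
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


def fit_variance_prior(s2: np.ndarray, df_resid: float):
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s^2)`` to the digamma/trigamma
    moments of the log-F sampling distribution, yielding the prior
    degrees of freedom ``d0`` and prior variance ``s0^2`` used for
    empirical-Bayes shrinkage of gene-wise residual variances.  When the
    observed spread of ``log(s^2)`` does not exceed its pure sampling
    variability, ``d0`` is infinite (complete shrinkage to ``s0^2``).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    n = e.size
    e_var = np.mean((e - e.mean()) ** 2) * n / (n - 1.0)
    excess = e_var - polygamma(1, df_resid / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        return d0, s0_sq
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t_de(normalized: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    ``groups`` maps sample -> {0, 1} with 1 the non-survivor group;
    ``logFC`` is group-1 minus group-0 mean on the normalized (log2)
    scale.  Gene-wise residual variances are shrunk toward the
    method-of-moments prior, the moderated t is referred to a
    t-distribution with ``d0 + df_resid`` degrees of freedom, and BH
    adjustment is applied across genes.
    """
    g = groups.loc[normalized.columns].to_numpy()
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 samples per group")
    df_resid = n0 + n1 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    x = normalized.to_numpy(dtype=float)
    m1 = x[:, g == 1].mean(axis=1)
    m0 = x[:, g == 0].mean(axis=1)
    ss = (np.sum((x[:, g == 1] - m1[:, None]) ** 2, axis=1)
          + np.sum((x[:, g == 0] - m0[:, None]) ** 2, axis=1))
    s2 = ss / df_resid
    d0, s0_sq = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    logfc = m1 - m0
    stderr = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(stderr > 0, logfc / stderr, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame({
        "gene_id": normalized.index,
        "logFC": logfc,
        "t_mod": t_mod,
        "p_raw": p,
        "fdr": bh_adjust(p),
    }).set_index("gene_id")


# ---------------------------------------------------------------------------
# methylation arm

def compute_m_values(meth: pd.DataFrame, unmeth: pd.DataFrame,
                     alpha: float = 1.0) -> pd.DataFrame:
    """M-values: log2((methylated + alpha) / (unmethylated + alpha)).

    The offset ``alpha`` keeps the ratio finite at zero intensities;
    with ``alpha = 0`` the raw log-ratio is returned (may be infinite).
    """
    m = meth.to_numpy(dtype=float)
    u = unmeth.to_numpy(dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    with np.errstate(divide="ignore"):
        vals = np.log2(m + alpha) - np.log2(u + alpha)
    return pd.DataFrame(vals, index=meth.index, columns=meth.columns)


def filter_probes(m_or_meth: pd.DataFrame, detection_p: pd.DataFrame,
                  probe_info: pd.DataFrame,
                  sex_chroms: tuple = ("X", "Y"),
                  detection_max: float = 0.05):
    """Detection and sex-chromosome probe/sample filters.

    Samples whose median detection p exceeds ``detection_max`` are
    dropped first; then any probe failing detection in one or more
    retained samples, or located on a sex chromosome, is removed.
    Returns ``(filtered_matrix, kept_probe_info)``.
    """
    det = detection_p.loc[m_or_meth.index, m_or_meth.columns]
    keep_samples = det.median(axis=0) <= detection_max
    det = det.loc[:, keep_samples]
    info = probe_info.set_index("probe_id").loc[m_or_meth.index]
    on_sex = info["chrom"].astype(str).isin([str(c) for c in sex_chroms])
    fails = (det > detection_max).any(axis=1)
    keep = ~(on_sex.to_numpy() | fails.to_numpy())
    out = m_or_meth.loc[m_or_meth.index[keep], keep_samples[keep_samples].index]
    return out, info.loc[out.index].rename_axis("probe_id").reset_index()


def quantile_normalize_pooled(m_matrix: pd.DataFrame,
                              platform_labels: pd.Series | None = None) -> pd.DataFrame:
    """Full quantile normalization across the pooled samples.

    Every column is mapped onto the mean sorted profile, so all samples
    share the same sorted values afterwards; ties within a column receive
    the average of the reference values at their rank positions.
    ``platform_labels`` is accepted for provenance (the pooling is across
    both platforms) but does not alter the arithmetic.
    """
    x = m_matrix.to_numpy(dtype=float)
    order = np.sort(x, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), reference)
    return pd.DataFrame(out, index=m_matrix.index, columns=m_matrix.columns)


def probe_differential(m_matrix: pd.DataFrame, groups: pd.Series,
                       probe_info: pd.DataFrame | None = None,
                       moderated: bool = False) -> pd.DataFrame:
    """Probe-wise two-group comparison of M-values.

    Ordinary equal-variance t-test by default (empirical-Bayes moderation
    available via ``moderated=True``), BH adjustment across probes.
    """
    if moderated:
        res = moderated_t_de(m_matrix, groups)
        out = pd.DataFrame({
            "probe_id": res.index,
            "delta_m": res["logFC"].to_numpy(),
            "p_raw": res["p_raw"].to_numpy(),
            "fdr": res["fdr"].to_numpy(),
        })
    else:
        g = groups.loc[m_matrix.columns].to_numpy()
        x1 = m_matrix.to_numpy()[:, g == 1]
        x0 = m_matrix.to_numpy()[:, g == 0]
        t, p = stats.ttest_ind(x1, x0, axis=1)
        p = np.nan_to_num(p, nan=1.0)
        out = pd.DataFrame({
            "probe_id": m_matrix.index,
            "delta_m": x1.mean(axis=1) - x0.mean(axis=1),
            "p_raw": p,
            "fdr": bh_adjust(p),
        })
    if probe_info is not None:
        gene_of = probe_info.set_index("probe_id")["gene_id"]
        out.insert(1, "gene_id", out["probe_id"].map(gene_of))
    return out.set_index("probe_id")


# ---------------------------------------------------------------------------
# protein arm

@dataclass
class ProteinAssoc:
    protein: str
    day: int
    estimate: float
    se: float
    p: float
    odds_pct: float
    n: int


def protein_logistic(proteins: pd.DataFrame, phenotypes: pd.DataFrame,
                     day: int, min_n: int = 10) -> pd.DataFrame:
    """Per-protein logistic model of death on concentration at one day.

    Age and sex enter as covariates.  ``odds_pct`` is the percent change
    in mortality odds per ng/mL, ``100 * (exp(estimate) - 1)``.  Proteins
    measured in fewer than ``min_n`` subjects at that day are skipped
    with a warning.
    """
    pheno = phenotypes.set_index("subject_id")
    rows = []
    day_data = proteins[proteins["day"] == day]
    for protein, sub in day_data.groupby("protein_name"):
        sub = sub.drop_duplicates(subset="subject_id")
        ids = [s for s in sub["subject_id"] if s in pheno.index]
        if len(ids) < min_n:
            warnings.warn(f"{protein}: only {len(ids)} subjects at day {day}; skipped",
                          stacklevel=2)
            continue
        conc = sub.set_index("subject_id").loc[ids, "concentration"].to_numpy(dtype=float)
        y = pheno.loc[ids, "death_28d"].to_numpy(dtype=float)
        if np.unique(y).size < 2:
            warnings.warn(f"{protein}: single outcome class at day {day}; skipped",
                          stacklevel=2)
            continue
        X = np.column_stack([
            np.ones(len(ids)), conc,
            pheno.loc[ids, "age"].to_numpy(dtype=float),
            (pheno.loc[ids, "sex"] == "M").to_numpy(dtype=float),
        ])
        fit = logistic_irls(X, y)
        est = fit.coef[1]
        rows.append({
            "protein": protein, "day": day, "estimate": est,
            "se": fit.se[1], "p": fit.p[1],
            "odds_pct": 100.0 * (np.exp(est) - 1.0), "n": len(ids),
        })
    return pd.DataFrame(rows)
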