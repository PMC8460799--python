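"""Shared low-level statistical routines.

Small, dependency-light helpers used by several analysis modules: an IRLS
logistic-regression fitter with Wald inference, the exact Hardy-Weinberg
equilibrium test, Benjamini-Hochberg adjustment, and a nearest
positive-semi-definite repair for empirical correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogisticFit",
    "logistic_irls",
    "hwe_exact_p",
    "bh_adjust",
    "nearest_psd_correlation",
]

# |coefficient| beyond which a logistic fit is treated as (quasi-)separated
SEPARATION_COEF_LIMIT = 15.0


@dataclass
class LogisticFit:
    """Result of an IRLS logistic regression.

    ``coef``/``se``/``p`` are aligned with the design-matrix columns
    (intercept first when ``add_intercept`` was used).
    """

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    loglik: float
    names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.coef)


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    names: list[str] | None = None,
) -> LogisticFit:
    """Fit logistic regression by iteratively reweighted least squares.

    Iterates Newton steps until the score (gradient of the log-likelihood)
    has sup-norm below ``tol`` or ``max_iter`` is reached.  A tiny ridge is
    added to the information matrix purely for numerical stability.  Fits
    with any non-intercept coefficient exceeding ``SEPARATION_COEF_LIMIT``
    in absolute value are flagged as separated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; logistic model undefined")
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    info = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None]) + 1e-10 * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # dampen absurd steps (near-separation)
        step_norm = np.max(np.abs(step))
        if step_norm > 10.0:
            step *= 10.0 / step_norm
        beta = beta + step
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None]) + 1e-10 * np.eye(p)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    loglik = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    separated = bool(np.any(np.abs(beta[1:] if p > 1 else beta) > SEPARATION_COEF_LIMIT))
    return LogisticFit(
        coef=beta,
        se=se,
        p=pvals,
        converged=converged,
        separated=separated,
        n_iter=it,
        loglik=loglik,
        names=list(names) if names is not None else [],
    )


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional exact test on the observed allele counts: sums, over all
    heterozygote counts compatible with the rare-allele total, the
    probabilities no larger than that of the observed configuration
    (Wigginton-Cutler-Abecasis recursion).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele total
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het_values.size == 0:
        return 1.0
    # unnormalized probabilities by recurrence from the smallest het count
    log_probs = np.zeros(het_values.size)
    for i in range(1, het_values.size):
        h = float(het_values[i])
        hom_r = (n_rare - h) / 2.0  # rare homozygotes at het count h
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        log_probs[i] = log_probs[i - 1] + np.log(4.0 * (hom_r + 1.0) * (hom_c + 1.0)) - np.log(h * (h - 1.0))
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count incompatible with allele total")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def nearest_psd_correlation(corr: np.ndarray, *, min_eig: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to a positive-semi-definite correlation.

    Eigenvalues below ``min_eig`` are clipped and the diagonal is rescaled
    back to one.  Emits a warning when a repair was needed.
    """
    corr = np.asarray(corr, dtype=float)
    corr = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 0:
        return corr
    warnings.warn("correlation matrix not PSD; clipping negative eigenvalues", stacklevel=2)
    vals = np.clip(vals, min_eig, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed
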