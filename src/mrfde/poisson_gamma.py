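"""Per-gene Poisson-Gamma marginal likelihoods and maximum-likelihood fitting.

Model: within one condition group, a gene's pseudobulk counts across the
samples of one cell type are iid Poisson with a shared mean, and that mean
carries a Gamma(alpha, rate beta) prior.  Integrating the mean analytically
gives the group marginal

    f(y_1..y_m) = beta^alpha * Gamma(S + alpha)
                  / (prod_j y_j! * Gamma(alpha) * (m + beta)^(S + alpha)),

with S = sum_j y_j.  For m = 1 this is the negative binomial pmf with
r = alpha and p = beta / (1 + beta).  A DE cell type uses two independent
group marginals (one per condition); an EE cell type pools all samples into
a single group.  One (alpha, beta) pair is shared across all cell types and
both states of a gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

THETA_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class PGParams:
    """Gamma prior parameters: shape ``alpha`` and rate ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)
                and self.alpha > 0 and self.beta > 0):
            raise ValueError(f"alpha and beta must be positive finite, got {self}")


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty count vector")
    if not np.issubdtype(y.dtype, np.integer):
        if not np.all(y == np.floor(y)):
            raise ValueError("counts must be integral")
        y = y.astype(np.int64)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    return y


def log_group_marginal(y, theta: PGParams) -> float:
    """Log marginal density of one group of counts under the shared-mean
    Poisson-Gamma model (computed entirely in log-gamma arithmetic)."""
    y = _validate_counts(y)
    m = y.shape[-1]
    S = y.sum(axis=-1, dtype=np.int64)
    a, b = theta.alpha, theta.beta
    val = (a * np.log(b) + gammaln(S + a) - gammaln(y + 1.0).sum(axis=-1)
           - gammaln(a) - (S + a) * np.log(m + b))
    return float(val) if np.ndim(val) == 0 else val


def log_conditional_density(y_k, m: int, n: int, x_k: int, theta: PGParams) -> float:
    """Log density of one cell type's pseudobulk given its DE state.

    ``y_k`` holds the m condition-1 samples followed by the n condition-2
    samples.  State 1 factorizes into the two per-condition marginals;
    state 0 pools all m+n samples into one group.
    """
    y_k = _validate_counts(y_k)
    if m < 1 or n < 1 or y_k.shape[-1] != m + n:
        raise ValueError(f"need m,n >= 1 with m+n == len(y_k); got m={m}, n={n}, len={y_k.shape[-1]}")
    if x_k not in (0, 1):
        raise ValueError(f"state must be 0 or 1, got {x_k}")
    if x_k == 1:
        return log_group_marginal(y_k[..., :m], theta) + log_group_marginal(y_k[..., m:], theta)
    return log_group_marginal(y_k, theta)


def gene_log_likelihood(pb_gene, x, m: int, n: int, theta: PGParams) -> float:
    """Log likelihood of a gene's K x (m+n) pseudobulk given the state vector."""
    pb_gene = np.atleast_2d(_validate_counts(pb_gene))
    x = np.asarray(x)
    if x.shape != (pb_gene.shape[0],):
        raise ValueError("state vector length must equal the number of cell types")
    return float(sum(log_conditional_density(pb_gene[k], m, n, int(x[k]), theta)
                     for k in range(pb_gene.shape[0])))


def _group_sums(pb_gene: np.ndarray, x: np.ndarray, m: int, n: int):
    """(group sum, group size) pairs implied by the state vector, plus the
    state-independent -sum log(y!) constant."""
    sums, sizes = [], []
    for k in range(pb_gene.shape[0]):
        row = pb_gene[k]
        if x[k] == 1:
            sums += [row[:m].sum(), row[m:].sum()]
            sizes += [m, n]
        else:
            sums.append(row.sum())
            sizes.append(m + n)
    const = -float(gammaln(pb_gene + 1.0).sum())
    return np.asarray(sums, dtype=float), np.asarray(sizes, dtype=float), const


def _loglik_from_groups(log_ab: np.ndarray, S: np.ndarray, M: np.ndarray, const: float):
    a, b = np.exp(log_ab)
    ll = (len(S) * (a * np.log(b) - gammaln(a))
          + gammaln(S + a).sum() - ((S + a) * np.log(M + b)).sum() + const)
    # gradient wrt (log a, log b)
    da = (len(S) * (np.log(b) - digamma(a)) + digamma(S + a).sum() - np.log(M + b).sum()) * a
    db = (len(S) * a / b - ((S + a) / (M + b)).sum()) * b
    return ll, np.array([da, db])


def moment_init(pb_gene: np.ndarray) -> PGParams:
    """Moment-matching start: pooled mean/variance over all pseudobulk values."""
    vals = np.asarray(pb_gene, dtype=float).ravel()
    mu = vals.mean()
    v = vals.var()
    lo, hi = THETA_BOUNDS
    beta0 = mu / (v - mu) if v > mu and mu > 0 else 1.0
    alpha0 = mu * beta0 if mu > 0 else 1.0
    return PGParams(float(np.clip(alpha0, lo, hi)), float(np.clip(beta0, lo, hi)))


def fit_theta(pb_gene, x, m: int, n: int,
              bounds: tuple[float, float] = THETA_BOUNDS) -> tuple[PGParams, bool]:
    """Maximize the gene log likelihood over (alpha, beta) at fixed states.

    Bounded quasi-Newton (L-BFGS-B) in (log alpha, log beta) with a
    moment-matching start.  Returns ``(theta_hat, degenerate)``; an all-zero
    gene is degenerate and gets the sentinel (1, 1).  The returned point
    never has lower likelihood than the start.
    """
    pb_gene = np.atleast_2d(_validate_counts(pb_gene))
    x = np.asarray(x)
    if not pb_gene.any():
        return PGParams(1.0, 1.0), True
    S, M, const = _group_sums(pb_gene, x, m, n)
    theta0 = moment_init(pb_gene)
    x0 = np.log([theta0.alpha, theta0.beta])
    log_lo, log_hi = np.log(bounds[0]), np.log(bounds[1])

    def neg(log_ab):
        ll, grad = _loglik_from_groups(log_ab, S, M, const)
        return -ll, -grad

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   bounds=[(log_lo, log_hi)] * 2, options={"ftol": 1e-12, "gtol": 1e-10})
    ll0, _ = _loglik_from_groups(x0, S, M, const)
    if -res.fun >= ll0:
        a, b = np.exp(res.x)
    else:  # optimizer failed to improve; keep the start (ascent guarantee)
        a, b = theta0.alpha, theta0.beta
    return PGParams(float(a), float(b)), False
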