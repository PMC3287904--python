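"""Per-SNP marginal test statistics and per-gene joint coefficient estimation.

All regressions include an intercept.  For quantitative traits the joint
covariance uses the OLS design block with the residual variance fixed at 1:
scores are only ever compared through a permutation null, so the common trait
scale cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr, stdtr

from .data_io import GeneBlock, PhenotypeVector

logger = logging.getLogger(__name__)

P_MIN = 1e-300  # keep P-values inside (0, 1] through floating underflow


class GeneTooLargeError(ValueError):
    """Gene has too many SNPs for joint estimation (n <= L + 1)."""


class ConvergenceError(RuntimeError):
    """Joint logistic fit failed even after ridge stabilization."""


@dataclass
class MarginalStats:
    stat: np.ndarray  # T (quantitative) or Z (binary) per SNP
    pvalue: np.ndarray  # two-sided, in (0, 1]
    df: int | None = None  # residual df, quantitative only


@dataclass
class JointEstimate:
    beta: np.ndarray  # SNP coefficients, intercept excluded
    sigma: np.ndarray  # L x L covariance of beta
    stabilized: bool = False


def two_sided_normal_p(z: np.ndarray | float) -> np.ndarray | float:
    return np.clip(2.0 * ndtr(-np.abs(z)), P_MIN, 1.0)


def marginal_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Slope t-test of the simple linear regression of y on x (with intercept).

    Returns (t, two-sided P from Student t with n-2 df, df).  A zero-variance
    x yields (0, 1, df) — gene cleaning normally prevents that input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    df = n - 2
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0:
        return 0.0, 1.0, df
    sxy = xc @ yc
    syy = yc @ yc
    slope = sxy / sxx
    sse = syy - slope * sxy
    if sse <= 0:
        return float(np.sign(slope)) * np.inf if slope != 0 else 0.0, P_MIN, df
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    p = float(np.clip(2.0 * stdtr(df, -abs(t)), P_MIN, 1.0))
    return float(t), p, df


def marginal_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Score (trend) test of single-covariate logistic regression of y on x.

    z = sum((x-xbar)(y-ybar)) / sqrt(ybar(1-ybar) sum((x-xbar)^2)); N(0,1)
    under the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("phenotype has one class")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        return 0.0, 1.0
    z = (xc @ (y - ybar)) / np.sqrt(ybar * (1.0 - ybar) * sxx)
    return float(z), float(two_sided_normal_p(z))


def _marginal_t_block(X: np.ndarray, y: np.ndarray) -> MarginalStats:
    """Vectorised marginal t over the columns of X."""
    n = len(y)
    df = n - 2
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = yc @ yc
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        sse = syy - slope * sxy
        var = sse / df / np.where(sxx > 0, sxx, 1.0)
        t = np.where((sxx > 0) & (var > 0), slope / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        t = np.where((sxx > 0) & (var <= 0) & (slope != 0), np.sign(slope) * np.inf, t)
    p = np.clip(2.0 * stdtr(df, -np.abs(np.where(np.isfinite(t), t, 1e12))), P_MIN, 1.0)
    p = np.where(sxx > 0, p, 1.0)
    return MarginalStats(stat=t, pvalue=p, df=df)


def _marginal_z_block(X: np.ndarray, y: np.ndarray) -> MarginalStats:
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("phenotype has one class")
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    num = Xc.T @ (y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sxx > 0, num / np.sqrt(ybar * (1 - ybar) * np.where(sxx > 0, sxx, 1.0)), 0.0)
    p = np.where(sxx > 0, two_sided_normal_p(z), 1.0)
    return MarginalStats(stat=z, pvalue=p)


def marginal_stats(block: GeneBlock | np.ndarray, y: PhenotypeVector) -> MarginalStats:
    """Marginal statistics for every SNP of a gene: T for quantitative, Z for binary."""
    X = block.X if isinstance(block, GeneBlock) else np.asarray(block)
    X = X.astype(float)
    if y.trait_type == "quantitative":
        return _marginal_t_block(X, y.values)
    return _marginal_z_block(X, y.values)


def joint_ols(block: GeneBlock | np.ndarray, y: PhenotypeVector | np.ndarray) -> JointEstimate:
    """Least-squares joint estimate for a gene's SNPs.

    beta-hat is the OLS coefficient block of y on [1, X]; its covariance is the
    SNP block of (X~' X~)^-1 with the residual variance fixed at 1, i.e.
    (Xc' Xc)^-1 for the centred design.
    """
    X = (block.X if isinstance(block, GeneBlock) else np.asarray(block)).astype(float)
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n, L = X.shape
    if n <= L + 1:
        raise GeneTooLargeError(f"gene too large for joint estimation (n={n}, L={L})")
    Xc = X - X.mean(axis=0)
    G = Xc.T @ Xc
    sigma = np.linalg.inv(G)
    beta = sigma @ (Xc.T @ (yv - yv.mean()))
    return JointEstimate(beta=beta, sigma=sigma)


def joint_logistic(
    block: GeneBlock | np.ndarray,
    y: PhenotypeVector | np.ndarray,
    ridge_eps: float = 1e-4,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> JointEstimate:
    """Maximum-likelihood multicovariate logistic fit (Newton iteration).

    Rare variants frequently produce (quasi-)separation; on divergence the fit
    restarts with a small ridge ``ridge_eps`` added to the information matrix
    and the estimate is flagged ``stabilized``.
    """
    X = (block.X if isinstance(block, GeneBlock) else np.asarray(block)).astype(float)
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n, L = X.shape
    if yv.mean() in (0.0, 1.0):
        raise ValueError("phenotype has one class")
    if n <= L + 1:
        raise GeneTooLargeError(f"gene too large for joint estimation (n={n}, L={L})")
    Xt = np.column_stack([np.ones(n), X])

    def _newton(eps: float) -> tuple[np.ndarray, np.ndarray, bool]:
        # eps > 0 maximizes the ridge-penalized log-likelihood
        # l(beta) - eps/2 ||beta||^2, which is finite even under separation
        beta = np.zeros(L + 1)
        info = None
        for _ in range(max_iter):
            eta = Xt @ beta
            mu = expit(eta)
            w = mu * (1.0 - mu)
            info = (Xt * w[:, None]).T @ Xt
            grad = Xt.T @ (yv - mu)
            if eps > 0:
                info = info + eps * np.eye(L + 1)
                grad = grad - eps * beta
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                return beta, info, False
            beta = beta + step
            if not np.isfinite(beta).all() or np.abs(beta).max() > 1e3:
                return beta, info, False
            if np.abs(step).max() < tol:
                return beta, info, True
        return beta, info, False

    beta, info, ok = _newton(0.0)
    stabilized = False
    if not ok:
        beta, info, ok = _newton(ridge_eps)
        stabilized = True
        if not ok or not np.isfinite(beta).all():
            raise ConvergenceError("joint logistic fit did not converge after stabilization")
    cov = np.linalg.inv(info)
    return JointEstimate(beta=beta[1:], sigma=cov[1:, 1:], stabilized=stabilized)
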