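"""Higher Criticism gene scores and their correlation-aware variants.

The HC statistic scans the ordered P-values of a gene's SNPs for the largest
standardized excess of observed over expected significance.  Because nearby
SNPs are in linkage disequilibrium, their test statistics are correlated; the
variants here first transform the per-SNP quantities toward independence:

* iHC  — whiten the joint coefficient estimate with the inverse Cholesky
  factor of its covariance, band-trimmed to bandwidth ``b = max(1, floor(ln L))``
  and column-normalised, then apply HC to the two-sided normal P-values.
* eHC  — whiten exactly via the eigen-decomposition of the covariance
  (``Z = Lambda^{-1/2} Q' beta``), then apply HC.
* iHCM — the iHC transform applied to marginal single-SNP statistics with
  their correlation matrix estimated across trait replicates or from the
  genotype correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .association import JointEstimate, MarginalStats, two_sided_normal_p

logger = logging.getLogger(__name__)


class NonPDError(np.linalg.LinAlgError):
    """Covariance/correlation matrix is not positive definite."""


@dataclass
class HCConfig:
    #: lower bound of the significance range; order statistics below it are
    #: excluded from the scan (they replace the classical 1/L bound)
    p_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 < self.p_floor < 1.0:
            raise ValueError("p_floor must lie in (0, 1)")


@dataclass
class WhiteningOperator:
    V: np.ndarray
    kind: str  # "cholesky_banded" | "eigen"
    bandwidth: int | None = None


def hc_statistic(pvalues: np.ndarray, cfg: HCConfig | None = None) -> float:
    """HC = max_i sqrt(L) (i/L - p_(i)) / sqrt(p_(i)(1 - p_(i))).

    The maximum runs over order statistics with p_(i) >= p_floor; if every
    P-value is below the floor they are clamped to it and the scan runs on the
    clamped values.  Larger HC means more significant.
    """
    cfg = cfg or HCConfig()
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("P-values must lie in (0, 1]")
    ps = np.sort(p)
    L = ps.size
    mask = ps >= cfg.p_floor
    if not mask.any():
        ps = np.full(L, cfg.p_floor)
        mask = np.ones(L, dtype=bool)
    i = np.arange(1, L + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.sqrt(L) * (i / L - ps) / np.sqrt(ps * (1.0 - ps))
    # p = 1 exactly: the i = L term tends to 0, earlier terms to -inf
    at_one = ps == 1.0
    terms[at_one] = np.where(i[at_one] == L, 0.0, -np.inf)
    return float(terms[mask].max())


def default_bandwidth(L: int) -> int:
    """Trimming bandwidth b = max(1, floor(ln L))."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return max(1, int(np.floor(np.log(L))))


def cholesky_whitener(sigma: np.ndarray) -> np.ndarray:
    """U = C^-1 where sigma = C C' is the lower Cholesky factorization.

    U is lower triangular with positive diagonal and satisfies U sigma U' = I.
    """
    sigma = np.asarray(sigma, dtype=float)
    try:
        C = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise NonPDError("covariance is not positive definite") from exc
    return solve_triangular(C, np.eye(sigma.shape[0]), lower=True)


def band_trim(U: np.ndarray, b: int) -> np.ndarray:
    """Zero entries more than b-1 sub-diagonals below the diagonal.

    Entry (k, j) survives iff k - b + 1 <= j <= k; b = 1 keeps only the
    diagonal, b >= L leaves a lower-triangular matrix unchanged.
    """
    if b < 1:
        raise ValueError("bandwidth must be >= 1")
    U = np.asarray(U, dtype=float)
    k = np.arange(U.shape[0])[:, None]
    j = np.arange(U.shape[1])[None, :]
    return np.where((j <= k) & (j >= k - b + 1), U, 0.0)


def column_normalize(U: np.ndarray) -> np.ndarray:
    """Scale each column to unit Euclidean norm."""
    U = np.asarray(U, dtype=float)
    norms = np.linalg.norm(U, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column encountered during normalization")
    return U / norms


def banded_whitener(sigma: np.ndarray, b: int | None = None) -> WhiteningOperator:
    L = sigma.shape[0]
    b = default_bandwidth(L) if b is None else b
    V = column_normalize(band_trim(cholesky_whitener(sigma), b))
    return WhiteningOperator(V=V, kind="cholesky_banded", bandwidth=b)


def eigen_whitener(sigma: np.ndarray) -> WhiteningOperator:
    """V = Lambda^{-1/2} Q' with eigenvalues descending and deterministic signs.

    Each eigenvector's sign is fixed so its largest-magnitude entry is
    positive — HC is invariant to permuting Z but not to an arbitrary basis
    inside a degenerate eigenspace, so the basis must be reproducible.
    """
    sigma = np.asarray(sigma, dtype=float)
    vals, vecs = np.linalg.eigh(sigma)
    order = np.argsort(vals, kind="stable")[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[-1] <= 1e-12 * max(vals[0], 0.0):
        raise NonPDError("covariance has a (near-)zero eigenvalue")
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    V = (vecs / np.sqrt(vals)).T
    return WhiteningOperator(V=V, kind="eigen")


def _whitened_hc(beta: np.ndarray, sigma: np.ndarray, cfg: HCConfig | None) -> float:
    op = banded_whitener(sigma)
    z = op.V @ np.asarray(beta, dtype=float)
    return hc_statistic(two_sided_normal_p(z), cfg)


def ihc_score(est: JointEstimate, cfg: HCConfig | None = None) -> float:
    """Innovated HC of a joint coefficient estimate (banded Cholesky whitening)."""
    return _whitened_hc(est.beta, est.sigma, cfg)


def ehc_score(est: JointEstimate, cfg: HCConfig | None = None) -> float:
    """Eigen-decomposition HC: exact whitening Z = Lambda^{-1/2} Q' beta."""
    op = eigen_whitener(est.sigma)
    z = op.V @ np.asarray(est.beta, dtype=float)
    return hc_statistic(two_sided_normal_p(z), cfg)


def ihcm_score(
    stats: MarginalStats | np.ndarray,
    corr: np.ndarray,
    cfg: HCConfig | None = None,
) -> float:
    """iHC applied to marginal statistics with an estimated correlation matrix."""
    vec = stats.stat if isinstance(stats, MarginalStats) else np.asarray(stats, dtype=float)
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if corr.shape[0] != vec.size:
        raise ValueError("correlation matrix and statistic vector sizes differ")
    return _whitened_hc(vec, corr, cfg)


# ---------------------------------------------------------------------------
# correlation estimation for iHCM


def _ensure_pd_correlation(C: np.ndarray, clip: float = 1e-6) -> np.ndarray:
    """Project to the nearest unit-diagonal PD matrix by eigenvalue clipping."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    C = np.where(np.isfinite(C), C, 0.0)
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < clip:
        vals = np.clip(vals, clip, None)
        C = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def estimate_stat_correlation_replicates(stats: np.ndarray) -> np.ndarray:
    """Pearson correlation of per-SNP statistics across trait replicates.

    ``stats`` is replicates x L; needs >= 3 replicates (use the genotype
    approach otherwise).
    """
    S = np.atleast_2d(np.asarray(stats, dtype=float))
    if S.shape[0] < 3:
        raise ValueError("need >= 3 replicates; use the genotype-based estimator")
    if S.shape[1] == 1:
        return np.ones((1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(S, rowvar=False)
    return _ensure_pd_correlation(C)


def estimate_stat_correlation_genotype(X: np.ndarray) -> np.ndarray:
    """Approximate the statistic correlation by the genotype-column correlation."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 1:
        return np.ones((1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    return _ensure_pd_correlation(C)
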