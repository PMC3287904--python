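"""Comparison gene scores: minimal P-value and ridge goodness-of-fit.

The ridge score is the residual sum of squares at the tuning parameter chosen
by generalized cross-validation (GCV); smaller SSR means a better joint fit of
the gene's SNPs and hence more evidence of association.  Binary traits are
scored by the same least-squares ridge, treating the 0/1 response numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .association import MarginalStats

_SV_TOL = 1e-10  # relative singular-value cutoff for the lambda = 0 (pseudoinverse) limit


def _default_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(1e-3, 50.0, 101)])


@dataclass
class RidgeConfig:
    #: candidate penalties; 0 (the OLS/pseudoinverse limit) plus a log-spaced sweep
    lambda_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        g = np.sort(np.asarray(self.lambda_grid, dtype=float))
        if g.size == 0 or np.any(g < 0):
            raise ValueError("lambda grid must be nonempty and nonnegative")
        self.lambda_grid = g


class RidgeFit(NamedTuple):
    coef: np.ndarray  # slopes on the original genotype scale
    intercept: float
    fitted: np.ndarray
    ssr: float


def minp_score(stats: MarginalStats) -> float:
    """Smallest marginal P-value in the gene; smaller is more significant."""
    p = np.asarray(stats.pvalue, dtype=float)
    if p.size == 0:
        raise ValueError("empty gene")
    return float(p.min())


class RidgeScorer:
    """Precomputed SVD path for one gene: standardized design, SSR and GCV per lambda.

    The design is column-standardized (unit population SD) and the response
    centred, with an unpenalized intercept absorbed by the centring.
    """

    def __init__(self, X: np.ndarray, cfg: RidgeConfig | None = None) -> None:
        self.cfg = cfg or RidgeConfig()
        X = np.asarray(X, dtype=float)
        self.n = X.shape[0]
        self.xmean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.xscale = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.xmean) / self.xscale
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        keep = s > _SV_TOL * (s[0] if s.size else 1.0)
        self.U, self.s, self.Vt = U[:, keep], s[keep], Vt[keep]

    def _factors(self, lam: float) -> np.ndarray:
        s2 = self.s**2
        if lam == 0.0:
            return np.ones_like(self.s)
        return s2 / (s2 + lam)

    def ssr_path(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(SSR, GCV) along the lambda grid for response y."""
        yc = np.asarray(y, dtype=float)
        yc = yc - yc.mean()
        c = self.U.T @ yc
        base = yc @ yc - c @ c  # part of y orthogonal to the column space
        grid = self.cfg.lambda_grid
        s2 = self.s**2
        with np.errstate(divide="ignore", invalid="ignore"):
            F = s2[None, :] / (s2[None, :] + grid[:, None])
        F[grid == 0.0] = 1.0
        ssr = base + ((1.0 - F) ** 2) @ (c**2)
        edf = 1.0 + F.sum(axis=1)  # +1 for the intercept
        denom = np.maximum(self.n - edf, 1e-8)
        gcv = self.n * ssr / denom**2
        return ssr, gcv

    def score(self, y: np.ndarray) -> float:
        """SSR at the GCV optimum, relative to the total centred sum of squares.

        The division by TSS is a gene-independent monotone rescaling for a
        fixed response — every within-replicate comparison across genes is
        unchanged — but it makes the score scale-free, which a permutation
        null shared across trait replicates of differing variance requires.
        """
        yc = np.asarray(y, dtype=float)
        tss = float(np.sum((yc - yc.mean()) ** 2))
        ssr, gcv = self.ssr_path(y)
        return float(ssr[int(np.argmin(gcv))] / tss) if tss > 0 else np.nan


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeFit:
    """Ridge solution at a fixed penalty, fitted values on the original scale."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    scorer = RidgeScorer(X, RidgeConfig(lambda_grid=np.array([max(lam, 0.0), 1.0])))
    y = np.asarray(y, dtype=float)
    ymean = y.mean()
    yc = y - ymean
    c = scorer.U.T @ yc
    f = scorer._factors(lam)
    # beta in the standardized basis, then back to the original scale
    beta_std = scorer.Vt.T @ (f / scorer.s * c)
    coef = beta_std / scorer.xscale
    intercept = ymean - scorer.xmean @ coef
    fitted = intercept + np.asarray(X, dtype=float) @ coef
    ssr = float(np.sum((y - fitted) ** 2))
    return RidgeFit(coef=coef, intercept=float(intercept), fitted=fitted, ssr=ssr)


def select_lambda(X: np.ndarray, y: np.ndarray, cfg: RidgeConfig | None = None) -> float:
    """Penalty minimizing GCV over the grid; ties go to the smallest lambda."""
    scorer = RidgeScorer(X, cfg)
    _, gcv = scorer.ssr_path(y)
    return float(scorer.cfg.lambda_grid[int(np.argmin(gcv))])


def ridge_score(X: np.ndarray, y: np.ndarray, cfg: RidgeConfig | None = None) -> float:
    """SSR at the GCV-selected penalty; smaller means more significant."""
    return RidgeScorer(X, cfg).score(y)
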