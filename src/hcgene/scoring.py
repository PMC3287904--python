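"""Per-gene scoring engine shared by the observed pass and the permutation null.

Everything that depends only on the genotypes is precomputed once per gene
(centred designs, OLS projection matrices, whitening operators, ridge SVD
paths) so that scoring a permuted response is a handful of small mat-vecs per
gene.  The six method identifiers and their significance orientations:

==========  =========================================  ==============
method       statistic                                  orientation
==========  =========================================  ==============
minp        smallest marginal P-value                  smaller_better
ridge       SSR at the GCV-chosen penalty              smaller_better
hc          HC of the marginal P-values                larger_better
ihc         HC of banded-whitened joint estimate       larger_better
ehc         HC of eigen-whitened joint estimate        larger_better
ihcm        HC of banded-whitened marginal statistics  larger_better
==========  =========================================  ==============
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import stdtr

from .association import (
    P_MIN,
    GeneTooLargeError,
    JointEstimate,
    joint_logistic,
    two_sided_normal_p,
)
from .baselines import RidgeConfig, RidgeScorer
from .data_io import GeneBlock, PhenotypeVector
from .hc import (
    HCConfig,
    NonPDError,
    banded_whitener,
    eigen_whitener,
    estimate_stat_correlation_genotype,
    hc_statistic,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ("minp", "ridge", "hc", "ihc", "ehc", "ihcm")

ORIENTATION = {
    "minp": "smaller_better",
    "ridge": "smaller_better",
    "hc": "larger_better",
    "ihc": "larger_better",
    "ehc": "larger_better",
    "ihcm": "larger_better",
}


@dataclass
class GenePrecomp:
    gene_id: str
    block: GeneBlock
    Xc: np.ndarray | None = None  # centred design
    sxx: np.ndarray | None = None  # column sums of squares of Xc
    ols_proj: np.ndarray | None = None  # (Xc'Xc)^-1 Xc'  (quantitative joint)
    V_ihc: np.ndarray | None = None  # banded whitener of the OLS covariance
    V_ehc: np.ndarray | None = None  # eigen whitener of the OLS covariance
    V_ihcm: np.ndarray | None = None  # banded whitener of the statistic correlation
    ridge: RidgeScorer | None = None
    joint_ok: bool = True  # False => ihc/ehc reported missing for this gene
    notes: list[str] = field(default_factory=list)

    @property
    def testable(self) -> bool:
        return self.block.testable


def precompute_genes(
    blocks: list[GeneBlock],
    trait_type: str,
    methods: tuple[str, ...] = ALL_METHODS,
    ihcm_corr: dict[str, np.ndarray] | None = None,
    ridge_cfg: RidgeConfig | None = None,
) -> list[GenePrecomp]:
    """Build per-gene precomputations for the requested methods.

    ``ihcm_corr`` maps gene_id -> statistic correlation matrix (the
    replicate-based estimator); when absent the genotype-based approximation
    is used.  Genes with n <= L + 1 (joint estimation infeasible) keep
    marginal-based methods and report ihc/ehc as missing.
    """
    out: list[GenePrecomp] = []
    for b in blocks:
        pc = GenePrecomp(gene_id=b.gene_id, block=b)
        if not b.testable:
            pc.joint_ok = False
            out.append(pc)
            continue
        X = b.X.astype(float)
        n, L = X.shape
        pc.Xc = X - X.mean(axis=0)
        pc.sxx = np.einsum("ij,ij->j", pc.Xc, pc.Xc)
        if "ridge" in methods:
            pc.ridge = RidgeScorer(X, ridge_cfg)
        needs_joint = ("ihc" in methods or "ehc" in methods)
        if needs_joint:
            if n <= L + 1:
                pc.joint_ok = False
                pc.notes.append("joint estimation infeasible (n <= L + 1)")
            elif trait_type == "quantitative":
                try:
                    sigma = np.linalg.inv(pc.Xc.T @ pc.Xc)
                    pc.ols_proj = sigma @ pc.Xc.T
                    pc.V_ihc = banded_whitener(sigma).V
                    pc.V_ehc = eigen_whitener(sigma).V
                except (np.linalg.LinAlgError, NonPDError):
                    pc.joint_ok = False
                    pc.notes.append("singular OLS covariance")
        if "ihcm" in methods:
            corr = None if ihcm_corr is None else ihcm_corr.get(b.gene_id)
            if corr is None:
                corr = estimate_stat_correlation_genotype(X)
            pc.V_ihcm = banded_whitener(corr).V
        out.append(pc)
    return out


def _marginal_vec(pc: GenePrecomp, yc: np.ndarray, trait_type: str,
                  ybar: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(stat, pvalue) for every SNP of one gene against a centred response."""
    num = pc.Xc.T @ yc
    if trait_type == "quantitative":
        df = n - 2
        syy = yc @ yc
        slope = num / pc.sxx
        sse = syy - slope * num
        sse = np.maximum(sse, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = slope * np.sqrt(df * pc.sxx / np.where(sse > 0, sse, 1.0))
            t = np.where(sse > 0, t, np.where(slope != 0, np.sign(slope) * 1e12, 0.0))
        p = np.clip(2.0 * stdtr(df, -np.abs(t)), P_MIN, 1.0)
        return t, p
    z = num / np.sqrt(ybar * (1.0 - ybar) * pc.sxx)
    return z, np.asarray(two_sided_normal_p(z))


def score_genes(
    precomp: list[GenePrecomp],
    y: PhenotypeVector | np.ndarray,
    trait_type: str,
    methods: tuple[str, ...] = ALL_METHODS,
    hc_cfg: HCConfig | None = None,
) -> dict[str, np.ndarray]:
    """Score every gene with every requested method; NaN marks missing scores."""
    hc_cfg = hc_cfg or HCConfig()
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n = len(yv)
    ybar = float(yv.mean())
    yc = yv - ybar
    I = len(precomp)
    out = {m: np.full(I, np.nan) for m in methods}
    needs_marginal = any(m in methods for m in ("minp", "hc", "ihcm"))
    for gi, pc in enumerate(precomp):
        if not pc.testable:
            continue
        if needs_marginal:
            stat, pval = _marginal_vec(pc, yc, trait_type, ybar, n)
            if "minp" in methods:
                out["minp"][gi] = pval.min()
            if "hc" in methods:
                out["hc"][gi] = hc_statistic(pval, hc_cfg)
            if "ihcm" in methods and pc.V_ihcm is not None:
                z = pc.V_ihcm @ stat
                out["ihcm"][gi] = hc_statistic(two_sided_normal_p(z), hc_cfg)
        if "ridge" in methods and pc.ridge is not None:
            out["ridge"][gi] = pc.ridge.score(yv)
        if ("ihc" in methods or "ehc" in methods) and pc.joint_ok:
            est = _joint_estimate(pc, yv, yc, trait_type)
            if est is None:
                continue
            if "ihc" in methods and pc.V_ihc is not None:
                z = pc.V_ihc @ est.beta
                out["ihc"][gi] = hc_statistic(two_sided_normal_p(z), hc_cfg)
            if "ehc" in methods and pc.V_ehc is not None:
                z = pc.V_ehc @ est.beta
                out["ehc"][gi] = hc_statistic(two_sided_normal_p(z), hc_cfg)
    return out


def _joint_estimate(pc: GenePrecomp, yv: np.ndarray, yc: np.ndarray,
                    trait_type: str) -> JointEstimate | None:
    if trait_type == "quantitative":
        if pc.ols_proj is None:
            return None
        # trait standardized to unit sample variance: with the residual
        # variance fixed at 1, this keeps the whitened components scale-free,
        # which the null shared across trait replicates requires; under
        # permutations of one response it changes nothing at all
        sd = yc.std()
        if sd == 0:
            return None
        return JointEstimate(beta=pc.ols_proj @ (yc / sd), sigma=None)
    try:
        est = joint_logistic(pc.block.X, yv)
    except (GeneTooLargeError, ValueError, np.linalg.LinAlgError, RuntimeError):
        return None
    # binary: whiteners depend on the per-fit covariance, build them fresh
    try:
        pc.V_ihc = banded_whitener(est.sigma).V
        pc.V_ehc = eigen_whitener(est.sigma).V
    except NonPDError:
        return None
    return est
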