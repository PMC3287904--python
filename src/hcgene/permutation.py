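"""Permutation calibration across genes and the multi-replicate rank evaluation.

Raw gene scores are not comparable across genes (different SNP counts, LD).
The calibration shuffles the response; within one permutation a single shuffle
is shared by every gene and every method, so the LD-induced dependence between
gene scores is preserved under the null.  Two comparable quantities result:

* empirical P-value  P = (1 + #{null at least as extreme}) / (J + 1)
* normalized score   (S - mean(null)) / sd(null), sign-flipped so that larger
  always means more significant.

Because the null distribution depends only on the genotypes, the null built by
permuting one trait replicate calibrates every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import GeneBlock, PhenotypeVector
from .hc import HCConfig
from .baselines import RidgeConfig
from .scoring import ALL_METHODS, ORIENTATION, GenePrecomp, precompute_genes, score_genes

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    S_star: np.ndarray  # I genes x J permutations
    method_id: str
    orientation: str
    seed: int
    gene_ids: list[str]

    @property
    def J(self) -> int:
        return self.S_star.shape[1]


@dataclass
class GeneScoreSet:
    method_id: str
    replicate_id: int
    gene_ids: list[str]
    raw: np.ndarray
    emp_p: np.ndarray
    norm_score: np.ndarray
    rank: np.ndarray  # from empirical P-values; 1 = most significant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "method": self.method_id,
                "replicate": self.replicate_id,
                "raw_stat": self.raw,
                "emp_p": self.emp_p,
                "norm_score": self.norm_score,
                "rank": self.rank,
            }
        )


def build_null(
    genes: list[GeneBlock] | list[GenePrecomp],
    y: PhenotypeVector,
    methods: tuple[str, ...] = ALL_METHODS,
    J: int = 10_000,
    seed: int = 0,
    hc_cfg: HCConfig | None = None,
    ridge_cfg: RidgeConfig | None = None,
    ihcm_corr: dict[str, np.ndarray] | None = None,
    on_permutation: Callable[[int, np.ndarray], None] | None = None,
) -> dict[str, PermutationNull]:
    """Genes x permutations score matrices, one per method.

    Each of the J permutations draws one Fisher-Yates shuffle of the response
    and applies it identically to all genes and methods.  ``on_permutation``
    (if given) receives ``(j, permutation_index_vector)`` — a hook for
    verifying the shared-shuffle contract.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if genes and isinstance(genes[0], GeneBlock):
        precomp = precompute_genes(genes, y.trait_type, methods,
                                   ihcm_corr=ihcm_corr, ridge_cfg=ridge_cfg)
    else:
        precomp = genes  # type: ignore[assignment]
    skipped = [pc.gene_id for pc in precomp if not pc.testable]
    if skipped:
        logger.info("excluding %d untestable gene(s) from the null: %s",
                    len(skipped), skipped[:5])
    I = len(precomp)
    rng = np.random.default_rng(seed)
    S = {m: np.full((I, J), np.nan) for m in methods}
    n = len(y.values)
    for j in range(J):
        perm = rng.permutation(n)
        if on_permutation is not None:
            on_permutation(j, perm)
        scores = score_genes(precomp, y.values[perm], y.trait_type, methods, hc_cfg)
        for m in methods:
            S[m][:, j] = scores[m]
    gene_ids = [pc.gene_id for pc in precomp]
    return {
        m: PermutationNull(S_star=S[m], method_id=m, orientation=ORIENTATION[m],
                           seed=seed, gene_ids=gene_ids)
        for m in methods
    }


def _extreme_mask(null_row: np.ndarray, s: float, orientation: str) -> np.ndarray:
    if orientation == "larger_better":
        return null_row >= s
    return null_row <= s


def empirical_pvalue(S_i: float, null_row: np.ndarray, orientation: str) -> float:
    """Add-one empirical P: (1 + #{at least as extreme}) / (J + 1); ties count."""
    null_row = np.asarray(null_row, dtype=float)
    if null_row.size < 1:
        raise ValueError("null row must contain at least one permutation value")
    if not np.isfinite(S_i):
        return np.nan
    k = int(_extreme_mask(null_row, S_i, orientation).sum())
    return (1 + k) / (null_row.size + 1)


def normalized_score(S_i: float, null_row: np.ndarray, orientation: str) -> float:
    """Null z-score of the statistic, oriented so larger = more significant."""
    null_row = np.asarray(null_row, dtype=float)
    sd = null_row.std(ddof=1) if null_row.size > 1 else 0.0
    if sd == 0 or not np.isfinite(S_i):
        return np.nan
    z = (S_i - null_row.mean()) / sd
    return float(-z if orientation == "smaller_better" else z)


def calibrate(raw: np.ndarray, null: PermutationNull) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised empirical P-values and normalized scores for one method."""
    raw = np.asarray(raw, dtype=float)
    S = null.S_star
    J = S.shape[1]
    if null.orientation == "larger_better":
        counts = (S >= raw[:, None]).sum(axis=1)
    else:
        counts = (S <= raw[:, None]).sum(axis=1)
    emp_p = (1.0 + counts) / (J + 1.0)
    mean = S.mean(axis=1)
    sd = S.std(axis=1, ddof=1) if J > 1 else np.zeros(S.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mean) / sd
    if null.orientation == "smaller_better":
        z = -z
    bad = ~np.isfinite(raw)
    emp_p = np.where(bad, np.nan, emp_p)
    z = np.where(bad | ~np.isfinite(z), np.nan, z)
    return emp_p, z


def rank_genes(values: np.ndarray, larger_better: bool = False) -> np.ndarray:
    """Significance ranks: 1 = most significant, ties averaged, NaN = worst.

    Testable genes are ranked 1..#testable; genes without a score (NaN) get
    rank = total number of genes.
    """
    v = np.asarray(values, dtype=float)
    ranks = np.full(v.size, float(v.size))
    ok = np.isfinite(v)
    if ok.any():
        ranks[ok] = rankdata(-v[ok] if larger_better else v[ok], method="average")
    return ranks


def share_null_across_replicates(
    nulls: dict[str, PermutationNull],
    replicate_raw: dict[int, dict[str, np.ndarray]],
) -> list[GeneScoreSet]:
    """Calibrate every replicate's raw scores against the single shared null."""
    out: list[GeneScoreSet] = []
    for rep_id in sorted(replicate_raw):
        for method, null in nulls.items():
            raw = np.asarray(replicate_raw[rep_id][method], dtype=float)
            if raw.size != len(null.gene_ids):
                raise ValueError("replicate score length does not match the null")
            emp_p, z = calibrate(raw, null)
            out.append(
                GeneScoreSet(
                    method_id=method,
                    replicate_id=rep_id,
                    gene_ids=null.gene_ids,
                    raw=raw,
                    emp_p=emp_p,
                    norm_score=z,
                    rank=rank_genes(emp_p, larger_better=False),
                )
            )
    return out


def evaluate_methods(
    score_sets: Sequence[GeneScoreSet] | pd.DataFrame,
    causative_genes: Sequence[str],
    rank_on: str = "emp_p",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Causative-gene rank summary over replicates.

    Returns (per_gene, overall): per causative gene the mean/SD of its rank
    across replicates, and per method the mean/SD over replicates of the
    average rank across causative genes, with the best (smallest mean) method
    flagged.  ``rank_on`` selects ranking by empirical P-value ("emp_p") or by
    normalized score ("norm_score").
    """
    causative = list(dict.fromkeys(causative_genes))
    if not causative:
        raise ValueError("causative gene set is empty")
    if isinstance(score_sets, pd.DataFrame):
        df = score_sets.copy()
    else:
        df = pd.concat([s.to_frame() for s in score_sets], ignore_index=True)
    missing = set(causative) - set(df["gene_id"])
    if missing:
        raise ValueError(f"causative genes absent from results: {sorted(missing)[:5]}")
    if rank_on == "emp_p":
        key, larger = "emp_p", False
    elif rank_on == "norm_score":
        key, larger = "norm_score", True
    else:
        raise ValueError("rank_on must be 'emp_p' or 'norm_score'")
    df = df.copy()
    df["rank_used"] = np.nan
    for (_, _), idx in df.groupby(["method", "replicate"]).groups.items():
        sub = df.loc[idx]
        df.loc[idx, "rank_used"] = rank_genes(sub[key].to_numpy(), larger_better=larger)
    causal = df[df["gene_id"].isin(causative)]
    per_gene = (
        causal.groupby(["method", "gene_id"])["rank_used"]
        .agg(mean_rank="mean", sd_rank="std")
        .reset_index()
    )
    per_gene["sd_rank"] = per_gene["sd_rank"].fillna(0.0)
    rep_avg = (
        causal.groupby(["method", "replicate"])["rank_used"].mean().reset_index()
    )
    overall = (
        rep_avg.groupby("method")["rank_used"]
        .agg(mean_avg_rank="mean", sd_avg_rank="std")
        .reset_index()
    )
    overall["sd_avg_rank"] = overall["sd_avg_rank"].fillna(0.0)
    overall["best"] = overall["mean_avg_rank"] == overall["mean_avg_rank"].min()
    return per_gene, overall
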