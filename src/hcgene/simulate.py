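"""Synthetic genotype panels and trait replicates in the exome-panel regime.

The generator emulates the regime of large exonic SNP panels on unrelated
individuals: a heavily right-skewed MAF spectrum (most variants rare, median
near 0.002), small genes (median 2 SNPs, long right tail), linkage
disequilibrium decaying with ordinal SNP distance, and a handful of causal
genes with weak effects.  Genotypes come from a latent-Gaussian threshold
model: two AR(1)-correlated latent haplotype vectors per individual are
thresholded at each SNP's MAF quantile, so target MAF and LD decay are
controlled independently.  Trait replicates share the genotype panel and
redraw only the noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data_io import (
    GenotypeMatrix,
    PhenotypeVector,
    write_allele_count_table,
    write_gene_map,
    write_phenotype,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_individuals: int = 697
    n_genes: int = 500
    #: SNPs per gene: 1 + geometric mixture, median 2 with a long right tail
    geom_p_common: float = 0.4
    geom_p_tail: float = 0.05
    tail_weight: float = 0.1
    max_snps_per_gene: int = 205
    #: MAF mixture: mostly rare (log-uniform) with a common-variant tail
    maf_rare_range: tuple[float, float] = (7e-4, 0.01)
    maf_common_range: tuple[float, float] = (0.01, 0.5)
    rare_weight: float = 0.8
    #: latent AR(1) correlation between adjacent SNPs within a gene
    ld_decay: float = 0.5
    n_causal_genes: int = 5
    causal_snps_per_gene: int = 2
    #: causal variants are rare: drawn from SNPs with 0 < MAF <= this bound
    causal_maf_max: float = 0.05
    #: effect per genotype standard deviation, on a unit-noise trait: every
    #: causal SNP carries marginal noncentrality ~ effect_size * sqrt(n)
    #: regardless of its MAF (rarer causative alleles get larger per-allele
    #: effects, as in the exome regime being emulated)
    effect_size: float = 1.0
    trait_model: str = "linear-gaussian"  # | liability-binary | logistic-binary
    prevalence: float = 0.3
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("n_individuals", "n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _draw_gene_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    tail = rng.random(cfg.n_genes) < cfg.tail_weight
    p = np.where(tail, cfg.geom_p_tail, cfg.geom_p_common)
    sizes = 1 + rng.geometric(p) - 1  # geometric support starts at 1
    return np.minimum(sizes, cfg.max_snps_per_gene)


def _draw_mafs(L: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    rare = rng.random(L) < cfg.rare_weight
    lo_r, hi_r = cfg.maf_rare_range
    lo_c, hi_c = cfg.maf_common_range
    u = rng.random(L)
    rare_maf = lo_r * (hi_r / lo_r) ** u
    common_maf = lo_c * (hi_c / lo_c) ** u
    return np.where(rare, rare_maf, common_maf)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotype panel + gene map; deterministic given the config seed."""
    rng = rng or np.random.default_rng(cfg.seed)
    sizes = _draw_gene_sizes(cfg, rng)
    n = cfg.n_individuals
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    gene_ids: list[str] = []
    positions: list[int] = []
    rho = cfg.ld_decay
    innov = np.sqrt(1.0 - rho**2)
    for g, L in enumerate(sizes):
        gid = f"GENE{g:04d}"
        maf = _draw_mafs(L, cfg, rng)
        thresh = ndtri(maf)  # latent < threshold => minor allele
        eps = rng.standard_normal((n, 2, L))
        z = np.empty_like(eps)
        z[:, :, 0] = eps[:, :, 0]
        for j in range(1, L):
            z[:, :, j] = rho * z[:, :, j - 1] + innov * eps[:, :, j]
        minor = (z < thresh).sum(axis=1)  # 0/1/2 minor-allele count
        major = 2 - minor
        cols.append(major)
        snp_ids.extend(f"{gid}_snp{j}" for j in range(L))
        gene_ids.extend([gid] * L)
        positions.extend(range(L))
    values = np.concatenate(cols, axis=1).astype(np.int16)
    g = GenotypeMatrix(
        values=values,
        snp_ids=snp_ids,
        sample_ids=[f"ind{i:04d}" for i in range(n)],
        gene_ids=np.asarray(gene_ids),
        positions=np.asarray(positions),
    )
    gene_map = pd.DataFrame({"snp_id": snp_ids, "gene_id": gene_ids, "position": positions})
    return g, gene_map


def plan_causals(g: GenotypeMatrix, cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Choose causal genes and SNPs; truth table ``gene_id snp_id beta``.

    Causative variants are rare, as in the exome regime being emulated:
    candidates are SNPs with 0 < MAF <= ``causal_maf_max``, and within a
    causal gene the largest-MAF candidates carry the effect (so the causal
    allele has carriers in the sample and is learnable at all).  Causal genes
    are drawn among genes with enough candidates.

    The ``beta`` column is the realised per-minor-allele effect,
    ``effect_size / sd(minor count)``, so every causal SNP contributes the
    same marginal signal strength on a unit-noise trait.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if cfg.n_causal_genes == 0:
        return pd.DataFrame(columns=["gene_id", "snp_id", "beta"])
    gene_ids = np.asarray(g.gene_ids)

    def _candidates(cols: np.ndarray) -> np.ndarray:
        ok = cols[(g.maf[cols] > 0) & (g.maf[cols] <= cfg.causal_maf_max)]
        return ok[np.argsort(g.maf[ok], kind="stable")[::-1]]

    eligible = [gid for gid in pd.unique(gene_ids)
                if len(_candidates(np.where(gene_ids == gid)[0]))
                >= cfg.causal_snps_per_gene]
    if len(eligible) < cfg.n_causal_genes:
        raise ValueError("not enough eligible genes for the requested causal count")
    chosen = rng.choice(np.asarray(eligible), size=cfg.n_causal_genes, replace=False)
    rows = []
    for gid in chosen:
        cand = _candidates(np.where(gene_ids == gid)[0])
        for c in cand[: cfg.causal_snps_per_gene]:
            sd = float((2.0 - g.values[:, c].astype(float)).std())
            rows.append({"gene_id": gid, "snp_id": g.snp_ids[c],
                         "beta": cfg.effect_size / sd})
    return pd.DataFrame(rows)


def simulate_traits(g: GenotypeMatrix, truth: pd.DataFrame, cfg: SimConfig,
                    rng: np.random.Generator | None = None) -> list[PhenotypeVector]:
    """Trait replicates over a fixed genotype panel (noise redrawn per replicate)."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    idx = {s: j for j, s in enumerate(g.snp_ids)}
    signal = np.zeros(g.n_individuals)
    for _, row in truth.iterrows():
        j = idx[row["snp_id"]]
        minor = 2.0 - g.values[:, j].astype(float)
        signal += float(row["beta"]) * minor
    trait_type = "quantitative" if cfg.trait_model == "linear-gaussian" else "binary"
    reps: list[PhenotypeVector] = []
    for r in range(1, cfg.n_replicates + 1):
        noise = rng.standard_normal(g.n_individuals)
        if cfg.trait_model == "linear-gaussian":
            y = signal + noise
        elif cfg.trait_model == "liability-binary":
            liability = signal + noise
            cut = np.quantile(liability, 1.0 - cfg.prevalence)
            y = (liability > cut).astype(float)
        elif cfg.trait_model == "logistic-binary":
            from scipy.special import expit, logit

            eta = logit(cfg.prevalence) + signal - signal.mean()
            y = (rng.random(g.n_individuals) < expit(eta)).astype(float)
        else:
            raise ValueError(f"unknown trait_model {cfg.trait_model!r}")
        reps.append(PhenotypeVector(values=y, trait_type=trait_type, replicate_id=r))
    return reps


PRESETS: dict[str, dict] = {
    "tiny": dict(n_individuals=200, n_genes=50, max_snps_per_gene=10,
                 n_replicates=20, n_causal_genes=3),
    "gaw17-like": dict(n_individuals=697, n_genes=500, n_replicates=200,
                       n_causal_genes=5),
}


def make_fixture(preset: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a complete on-disk dataset for a preset; returns the directory.

    Files: genotypes.tsv (allele-count table), genemap.tsv, truth.tsv,
    phenotypes/replicate_###.tsv, manifest.json.  The tiny preset plants two
    duplicate SNP columns so the cleaning step has real work to do.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = SimConfig(seed=seed, **PRESETS[preset])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, gene_map = simulate_genotypes(cfg)
    if preset == "tiny":
        g, gene_map = _plant_duplicates(g, gene_map, n_dups=2)
    truth = plan_causals(g, cfg)
    reps = simulate_traits(g, truth, cfg)
    write_allele_count_table(g, out / "genotypes.tsv")
    write_gene_map(gene_map, out / "genemap.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    pheno_dir = out / "phenotypes"
    pheno_dir.mkdir(exist_ok=True)
    for y in reps:
        write_phenotype(y, g.sample_ids, pheno_dir / f"replicate_{y.replicate_id:03d}.tsv")
    manifest = {"preset": preset, "seed": seed, "config": asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _plant_duplicates(g: GenotypeMatrix, gene_map: pd.DataFrame, n_dups: int
                      ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append exact copies of the first SNP of the first n_dups multi-SNP genes."""
    gene_ids = np.asarray(g.gene_ids)
    values = g.values
    snp_ids = list(g.snp_ids)
    gm_rows = gene_map.to_dict("records")
    planted = 0
    out_cols = []
    new_rows = []
    for gid in pd.unique(gene_ids):
        cols = np.where(gene_ids == gid)[0]
        if planted < n_dups and len(cols) >= 2 and g.values[:, cols[0]].std() > 0:
            src = cols[0]
            dup_id = f"{snp_ids[src]}_dup"
            out_cols.append((gid, values[:, src].copy(), dup_id, len(cols)))
            planted += 1
    for gid, col, dup_id, pos in out_cols:
        values = np.column_stack([values, col])
        snp_ids.append(dup_id)
        new_rows.append({"snp_id": dup_id, "gene_id": gid, "position": pos})
    gm = pd.concat([pd.DataFrame(gm_rows), pd.DataFrame(new_rows)], ignore_index=True)
    gm = gm.sort_values(["gene_id", "position"], kind="stable").reset_index(drop=True)
    order = [snp_ids.index(s) for s in gm["snp_id"]]
    g2 = GenotypeMatrix(
        values=values[:, order].astype(np.int16),
        snp_ids=gm["snp_id"].tolist(),
        sample_ids=g.sample_ids,
        gene_ids=gm["gene_id"].to_numpy(),
        positions=gm["position"].to_numpy(),
    )
    return g2, gm
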