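"""End-to-end orchestration: load -> clean -> score -> calibrate -> rank -> evaluate."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import marginal_stats
from .baselines import RidgeConfig
from .data_io import (
    GenotypeMatrix,
    PhenotypeVector,
    attach_gene_map,
    gene_blocks,
    read_gene_map,
    read_genotypes,
    read_phenotype,
)
from .hc import HCConfig, estimate_stat_correlation_replicates
from .permutation import (
    GeneScoreSet,
    build_null,
    evaluate_methods,
    share_null_across_replicates,
)
from .scoring import ALL_METHODS, precompute_genes, score_genes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: Path
    genemap: Path
    out: Path
    pheno: Path | None = None
    pheno_dir: Path | None = None
    trait_type: str = "quantitative"
    genotype_format: str = "table"  # | "vcf"
    methods: tuple[str, ...] = ALL_METHODS
    ihcm_correlation: str = "replicates"  # | "genotype"
    J: int = 10_000
    p_floor: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be nonempty")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.pheno is None and self.pheno_dir is None:
            raise ValueError("one of pheno / pheno_dir is required")


def _load_replicates(cfg: RunConfig, sample_ids) -> list[PhenotypeVector]:
    reps: list[PhenotypeVector] = []
    if cfg.pheno_dir is not None:
        files = sorted(Path(cfg.pheno_dir).glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no phenotype TSVs in {cfg.pheno_dir}")
        for r, f in enumerate(files, start=1):
            reps.append(read_phenotype(f, cfg.trait_type, sample_ids, replicate_id=r))
    else:
        reps.append(read_phenotype(cfg.pheno, cfg.trait_type, sample_ids, replicate_id=1))
    return reps


def run_scoring(cfg: RunConfig) -> pd.DataFrame:
    """Score every gene with every requested method, calibrated against a
    shared permutation null built from replicate 1; writes TSVs + manifest."""
    out_dir = Path(cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = read_genotypes(cfg.genotypes, cfg.genotype_format)
    g = attach_gene_map(g, read_gene_map(cfg.genemap))
    blocks = gene_blocks(g, clean=True)
    n_removed = sum(len(b.removed_snp_ids) for b in blocks)
    logger.info("cleaned %d genes; removed %d SNP column(s)", len(blocks), n_removed)
    reps = _load_replicates(cfg, g.sample_ids)

    hc_cfg = HCConfig(p_floor=cfg.p_floor)
    ihcm_corr = None
    if "ihcm" in cfg.methods:
        if cfg.ihcm_correlation == "replicates" and len(reps) >= 3:
            ihcm_corr = {}
            for b in blocks:
                if not b.testable:
                    continue
                S = np.vstack([marginal_stats(b, y).stat for y in reps])
                ihcm_corr[b.gene_id] = estimate_stat_correlation_replicates(S)
        elif cfg.ihcm_correlation == "replicates":
            logger.info("fewer than 3 replicates: iHCM falls back to the "
                        "genotype-based correlation estimator")

    precomp = precompute_genes(blocks, cfg.trait_type, cfg.methods,
                               ihcm_corr=ihcm_corr, ridge_cfg=RidgeConfig())
    nulls = build_null(precomp, reps[0], cfg.methods, J=cfg.J, seed=cfg.seed,
                       hc_cfg=hc_cfg)
    replicate_raw = {
        y.replicate_id: score_genes(precomp, y, cfg.trait_type, cfg.methods, hc_cfg)
        for y in reps
    }
    score_sets = share_null_across_replicates(nulls, replicate_raw)
    frames = []
    for rep_id in sorted(replicate_raw):
        rep_sets = [s for s in score_sets if s.replicate_id == rep_id]
        df = pd.concat([s.to_frame() for s in rep_sets], ignore_index=True)
        df.to_csv(out_dir / f"scores_rep{rep_id:03d}.tsv", sep="\t", index=False,
                  float_format="%.10g")
        frames.append(df)
    all_scores = pd.concat(frames, ignore_index=True)
    for method in cfg.methods:
        summary = (
            all_scores[all_scores["method"] == method]
            .groupby("gene_id")
            .agg(mean_emp_p=("emp_p", "mean"), mean_norm_score=("norm_score", "mean"),
                 mean_rank=("rank", "mean"))
            .reset_index()
            .sort_values("mean_rank")
        )
        summary.to_csv(out_dir / f"summary_{method}.tsv", sep="\t", index=False,
                       float_format="%.10g")
    manifest = {
        "hcgene_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": {k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_genes": len(blocks),
        "n_testable_genes": sum(b.testable for b in blocks),
        "n_removed_snps": n_removed,
        "n_replicates": len(reps),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return all_scores


def run_evaluation(results_dir: str | Path, truth_path: str | Path,
                   out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Causative-gene rank tables (empirical-P and normalized-score rankings)."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(results_dir.glob("scores_rep*.tsv"))
    if not files:
        raise FileNotFoundError(f"no scores_rep*.tsv in {results_dir}")
    df = pd.concat([pd.read_csv(f, sep="\t") for f in files], ignore_index=True)
    truth = pd.read_csv(truth_path, sep="\t")
    causative = truth["gene_id"].astype(str).unique().tolist()
    missing_methods = set(ALL_METHODS) - set(df["method"].unique())
    if missing_methods:
        logger.warning("methods absent from results, evaluated without them: %s",
                       sorted(missing_methods))
    tables: dict[str, pd.DataFrame] = {}
    lines: list[str] = []
    for rank_on in ("emp_p", "norm_score"):
        per_gene, overall = evaluate_methods(df, causative, rank_on=rank_on)
        per_gene.to_csv(out_dir / f"eval_per_gene_{rank_on}.tsv", sep="\t",
                        index=False, float_format="%.6g")
        overall.to_csv(out_dir / f"eval_overall_{rank_on}.tsv", sep="\t",
                       index=False, float_format="%.6g")
        tables[f"per_gene_{rank_on}"] = per_gene
        tables[f"overall_{rank_on}"] = overall
        lines.append(f"== ranking by {rank_on} ==")
        for _, row in overall.sort_values("mean_avg_rank").iterrows():
            star = " *best*" if row["best"] else ""
            lines.append(f"  {row['method']:>6}: mean avg rank "
                         f"{row['mean_avg_rank']:.2f} (SD {row['sd_avg_rank']:.2f}){star}")
        lines.append("")
    (out_dir / "evaluation.txt").write_text("\n".join(lines))
    return tables
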