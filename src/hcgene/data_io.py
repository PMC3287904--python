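"""Genotype, phenotype and gene-map I/O with major-allele coding and gene-level cleaning.

Genotypes are coded as the number of MAJOR alleles per SNP (0/1/2), so a rare
variant shows up as a deficit from 2.  Within each gene, genotype columns that
are linearly dependent are removed smallest-MAF-first until the remaining
columns are linearly independent; the removal never changes the linear span of
the gene's genotype data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: singular values below this multiple of the largest count as zero in rank tests
RANK_RTOL = 1e-10


class FormatError(ValueError):
    """Input file does not parse in the declared dialect."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs major-allele counts plus per-SNP metadata."""

    values: np.ndarray  # (n_individuals, L_total) integers in {0,1,2}
    snp_ids: list[str]
    sample_ids: list[str]
    gene_ids: np.ndarray | None = None  # per-SNP gene label, set via attach_gene_map
    positions: np.ndarray | None = None
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.maf is None:
            self.maf = compute_maf(self.values)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeVector:
    values: np.ndarray
    trait_type: str  # "quantitative" | "binary"
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary trait must contain only 0/1 values")
        else:
            if not np.isfinite(self.values).all() or self.values.var() <= 0:
                raise ValueError("quantitative trait must have finite positive variance")


@dataclass
class GeneBlock:
    """One gene's cleaned genotype submatrix.

    ``L == 0`` (empty X) is the untestable sentinel for genes whose columns
    were all constant; such genes are excluded from scoring but kept for
    bookkeeping so ranks can assign them the worst position.
    """

    gene_id: str
    X: np.ndarray  # n x L
    snp_ids: list[str]
    maf: np.ndarray
    removed_snp_ids: list[str] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.X.shape[1]

    @property
    def testable(self) -> bool:
        return self.L >= 1


def compute_maf(values: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column: min(f, 1-f) with f = colsum / 2n."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(values.shape[1] if values.ndim == 2 else 0)
    f = values.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def recode_major(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns so the counted allele is the more frequent one.

    Ties (frequency exactly 0.5) are left as given, i.e. broken toward the
    allele already counted (REF / first allele).  Returns (coded, flipped_mask).
    """
    values = np.asarray(values)
    f = values.mean(axis=0) / 2.0
    flip = f < 0.5
    coded = values.copy()
    coded[:, flip] = 2 - coded[:, flip]
    return coded, flip


def read_genotypes(path: str | Path, format: str = "table") -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic sites) or an allele-count table.

    Either way the returned matrix is in major-allele coding with MAF
    populated.  SNP columns that are entirely missing are dropped with a
    warning; remaining missing entries are imputed to the rounded per-SNP
    mean major-allele count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format in ("table", "allele-count-table"):
        return _read_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_table(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse allele-count table {path}: {exc}") from exc
    if df.columns[0] != "sample":
        raise FormatError("allele-count table must start with a 'sample' column")
    sample_ids = df["sample"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    raw = df[snp_ids].to_numpy()
    if not np.issubdtype(raw.dtype, np.number):
        raise FormatError("allele-count table cells must be integers")
    values = _impute_and_drop(raw.astype(float), snp_ids)
    values, snp_ids = values
    coded, _ = recode_major(values)
    return GenotypeMatrix(values=coded.astype(np.int16), snp_ids=snp_ids, sample_ids=sample_ids)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT}); split or filter before loading"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types)
        alt_count = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        cols.append(alt_count)
        snp_ids.append(vid)
    if not cols:
        raise FormatError(f"no biallelic records in {path}")
    alt = np.column_stack(cols)
    # REF-allele count; ties in frequency then stay coded toward REF
    values = 2.0 - alt
    values[np.isnan(alt)] = np.nan
    (values, snp_ids) = _impute_and_drop(values, snp_ids)
    coded, _ = recode_major(values)
    return GenotypeMatrix(values=coded.astype(np.int16), snp_ids=snp_ids, sample_ids=sample_ids)


def _impute_and_drop(values: np.ndarray, snp_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop all-missing columns; impute remaining NaNs to rounded column mean."""
    missing = np.isnan(values)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        dropped = [s for s, m in zip(snp_ids, all_missing) if m]
        logger.warning("dropping %d all-missing SNP column(s): %s", len(dropped), dropped)
        values = values[:, ~all_missing]
        snp_ids = [s for s, m in zip(snp_ids, all_missing) if not m]
        missing = missing[:, ~all_missing]
    if missing.any():
        frac = missing.mean()
        logger.info("imputing %.4f%% missing genotypes to rounded column means", 100 * frac)
        col_mean = np.nanmean(values, axis=0)
        fill = np.rint(col_mean)
        idx = np.where(missing)
        values[idx] = fill[idx[1]]
    return values, snp_ids


def write_allele_count_table(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.values, columns=g.snp_ids)
    df.insert(0, "sample", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """3-column TSV ``snp_id gene_id position``, sorted by gene then position."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    expected = ["snp_id", "gene_id", "position"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"gene map must have columns {expected}, got {list(df.columns)}")
    return df


def write_gene_map(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def attach_gene_map(g: GenotypeMatrix, gene_map: pd.DataFrame) -> GenotypeMatrix:
    """Reorder SNP columns to gene-map order (gene, then position) and label them.

    Genomic order within a gene is what banding distance and the
    correlation-by-distance summaries rely on, so it is enforced here.
    """
    gm = gene_map.sort_values(["gene_id", "position"], kind="stable")
    col_index = {s: i for i, s in enumerate(g.snp_ids)}
    keep = gm["snp_id"].isin(col_index)
    if not keep.all():
        logger.warning("%d gene-map SNPs absent from genotypes; skipped", (~keep).sum())
        gm = gm[keep]
    order = [col_index[s] for s in gm["snp_id"]]
    unmapped = set(g.snp_ids) - set(gm["snp_id"])
    if unmapped:
        logger.warning("%d genotype SNPs missing from gene map; dropped", len(unmapped))
    return GenotypeMatrix(
        values=g.values[:, order],
        snp_ids=gm["snp_id"].tolist(),
        sample_ids=g.sample_ids,
        gene_ids=gm["gene_id"].to_numpy(),
        positions=gm["position"].to_numpy(),
    )


def read_phenotype(
    path: str | Path,
    trait_type: str,
    sample_ids: Sequence[str] | None = None,
    replicate_id: int = 1,
) -> PhenotypeVector:
    """2-column TSV ``sample value``; aligned to ``sample_ids`` when given."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if list(df.columns[:2]) != ["sample", "value"]:
        raise FormatError("phenotype file must have columns 'sample' and 'value'")
    if sample_ids is not None:
        df = df.set_index("sample")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise FormatError(f"phenotype missing {len(missing)} sample(s), e.g. {missing[:3]}")
        values = df.loc[list(sample_ids), "value"].to_numpy(dtype=float)
    else:
        values = df["value"].to_numpy(dtype=float)
    return PhenotypeVector(values=values, trait_type=trait_type, replicate_id=replicate_id)


def write_phenotype(y: PhenotypeVector, sample_ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample": sample_ids, "value": y.values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# gene-level cleaning


def _matrix_rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    s = np.linalg.svd(M.astype(float), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > RANK_RTOL * s[0]))


def clean_linear_dependence(block: GeneBlock) -> GeneBlock:
    """Remove smallest-MAF columns until the genotype vectors are linearly independent.

    At each step, among the columns whose removal leaves the column span
    unchanged (i.e. columns lying in the span of the others), the one with the
    smallest MAF is deleted; MAF ties are broken toward the largest column
    index.  The returned block has full column rank and records deletions in
    order.
    """
    X = np.asarray(block.X, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("gene block must have at least one SNP column")
    keep = list(range(X.shape[1]))
    removed: list[int] = []
    while True:
        sub = X[:, keep]
        r = _matrix_rank(sub)
        if r == len(keep):
            break
        candidates = [
            j for pos, j in enumerate(keep)
            if _matrix_rank(X[:, [k for k in keep if k != j]]) == r
        ]
        # smallest MAF; tie -> largest column index
        maf = block.maf
        best = max(candidates, key=lambda j: (-maf[j], j))
        keep.remove(best)
        removed.append(best)
    return GeneBlock(
        gene_id=block.gene_id,
        X=block.X[:, keep],
        snp_ids=[block.snp_ids[j] for j in keep],
        maf=np.asarray(block.maf)[keep],
        removed_snp_ids=list(block.removed_snp_ids) + [block.snp_ids[j] for j in removed],
    )


def gene_blocks(g: GenotypeMatrix, clean: bool = True) -> list[GeneBlock]:
    """Split the genotype matrix into per-gene blocks, optionally cleaned.

    Zero-variance (constant) columns are unidentifiable next to the intercept
    every downstream regression carries, so they are dropped first; a gene left
    with no columns becomes an untestable L=0 sentinel block.
    """
    if g.gene_ids is None:
        raise ValueError("genotype matrix has no gene labels; attach_gene_map first")
    blocks: list[GeneBlock] = []
    gene_ids = np.asarray(g.gene_ids)
    # preserve first-appearance order (gene map is sorted by gene)
    seen: dict[str, list[int]] = {}
    for j, gid in enumerate(gene_ids):
        seen.setdefault(str(gid), []).append(j)
    for gid, cols in seen.items():
        X = g.values[:, cols]
        snp_ids = [g.snp_ids[j] for j in cols]
        maf = g.maf[cols]
        removed: list[str] = []
        if clean:
            var = X.astype(float).var(axis=0)
            const = var == 0
            if const.any():
                removed = [s for s, c in zip(snp_ids, const) if c]
                logger.info("gene %s: dropping %d constant SNP column(s)", gid, len(removed))
                X = X[:, ~const]
                snp_ids = [s for s, c in zip(snp_ids, const) if not c]
                maf = maf[~const]
        block = GeneBlock(gene_id=gid, X=X, snp_ids=snp_ids, maf=maf, removed_snp_ids=removed)
        if clean and block.L >= 1:
            block = clean_linear_dependence(block)
        blocks.append(block)
    return blocks


def summarize_dataset(g: GenotypeMatrix) -> dict:
    """Dataset summaries: MAF quantiles, SNPs-per-gene quantiles, within-gene
    |Pearson r| between SNP pairs at ordinal distances 1, 2 and 3."""
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")

    def _quant(v: np.ndarray) -> dict:
        v = np.asarray(v, dtype=float)
        return {
            "min": float(v.min()),
            "q1": float(np.quantile(v, 0.25)),
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(v.max()),
        }

    summary: dict = {"maf": _quant(g.maf)}
    corr_by_distance: dict[int, np.ndarray] = {1: [], 2: [], 3: []}  # type: ignore[assignment]
    if g.gene_ids is not None:
        gene_ids = np.asarray(g.gene_ids)
        sizes = pd.Series(gene_ids).value_counts()
        summary["snps_per_gene"] = _quant(sizes.to_numpy())
        values = g.values.astype(float)
        for gid in sizes.index:
            cols = np.where(gene_ids == gid)[0]
            Lg = len(cols)
            for d in (1, 2, 3):
                for a in range(Lg - d):
                    x1 = values[:, cols[a]]
                    x2 = values[:, cols[a + d]]
                    if x1.var() == 0 or x2.var() == 0:
                        continue
                    r = np.corrcoef(x1, x2)[0, 1]
                    corr_by_distance[d].append(abs(r))
        summary["abs_corr_by_distance"] = {
            d: np.asarray(v, dtype=float) for d, v in corr_by_distance.items()
        }
        summary["abs_corr_quantiles"] = {
            d: (_quant(v) if len(v) else None)
            for d, v in summary["abs_corr_by_distance"].items()
        }
    return summary
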