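# Methods

This note describes what `hcgene` computes and why, in the package's own
terms. It covers the statistical model, each scoring method, the permutation
calibration, the synthetic data generator, and the numerical conventions.

## Problem setting

The unit of inference is the gene. A gene contributes `L` SNP genotype
columns (allele counts 0/1/2, major-allele coding) for `n` unrelated
individuals, and the question is whether the gene as a whole is associated
with a trait `y` (quantitative or binary). The intended regime is exonic
panels: most variants are rare, genes are small (median around 2 SNPs with a
long right tail), effects are weak and spread over several variants, and the
same genotype panel is reused across many simulated trait replicates.

A single strongly associated SNP is easy; the hard case — and the one the
higher-criticism methods target — is several weak signals inside one gene,
none individually significant.

## Data cleaning

Before scoring, each gene block is cleaned:

1. **Major-allele recoding.** Columns are flipped so the counted allele is
   the more frequent one; frequency-0.5 ties keep the given coding.
2. **Constant columns** are dropped. Every regression here carries an
   intercept, so a zero-variance genotype column is unidentifiable. A gene
   whose columns are all constant becomes an untestable `L = 0` sentinel; it
   is excluded from scoring and assigned the worst rank.
3. **Linear dependence.** While the block is column-rank-deficient, among
   the columns lying in the span of the others the one with the smallest
   minor-allele frequency is removed (ties toward the largest column index).
   Rationale: the rarest member of a dependent set carries the least
   information. Rank is judged by SVD with a relative singular-value cutoff
   of `1e-10`.

## Marginal and joint association statistics

- **Quantitative traits:** per-SNP simple linear regression t statistics
  (df = n − 2); the joint model is OLS of the centred trait on the centred
  gene block, `β̂ = (Xc'Xc)⁻¹Xc'yc`, with coefficient covariance
  `Σ̂ = (Xc'Xc)⁻¹` at unit residual variance. So that gene scores are
  scale-free (see "Scale-freeness" below), the centred trait is standardized
  to unit sample variance before the joint fit.
- **Binary traits:** per-SNP trend z statistics
  `z = Σ(x−x̄)(y−ȳ) / √(ȳ(1−ȳ)Σ(x−x̄)²)`; the joint model is logistic
  regression fitted by Newton iteration. If the iteration diverges (e.g.
  complete separation), the fit is retried maximizing a ridge-penalized
  likelihood with penalty `ε = 1e-4` (the gradient gets `−εβ`, the
  information matrix `+εI`) and the estimate is flagged `stabilized`.

Two-sided P-values are floored at `1e-10` to keep the HC denominator finite.

## The six gene scores

| id | statistic | orientation |
|------|------------------------------------------------|---------|
| minp | smallest marginal P-value | smaller is more significant |
| ridge | SSR/TSS at the GCV-chosen ridge penalty | smaller |
| hc | HC of the marginal P-values | larger |
| ihc | HC of the banded-whitened joint estimate | larger |
| ehc | HC of the eigen-whitened joint estimate | larger |
| ihcm | HC of banded-whitened marginal statistics | larger |

**Higher criticism (HC).** Sort the gene's P-values ascending; the score is

```
HC = max over i with p(i) >= 1e-10 of  √L · (i/L − p(i)) / √(p(i)(1 − p(i)))
```

If every P-value is below the floor they are all clamped to it. A P-value of
exactly 1 contributes 0 at `i = L` and is otherwise skipped (−∞ term). HC
grows when an unusually large fraction of the gene's P-values are unusually
small — exactly the several-weak-signals pattern.

**iHC.** The joint estimate `β̂` has correlated components. Let `U` be the
inverse of the lower Cholesky factor of `Σ̂` (so `UΣ̂U' = I`), keep only the
band `k − b + 1 ≤ j ≤ k` with bandwidth `b = max(1, floor(ln L))`, and
rescale each column of the trimmed matrix to unit Euclidean norm. Apply the
resulting `V` to `β̂`, convert to two-sided normal P-values, and take HC.
Banding regularizes the whitener when `Σ̂` is noisy; the trimming and column
normalization deliberately give up exact whitening (`VΣ̂V' ≠ I`), which is
why scores are compared only through the permutation null, never against a
theoretical HC distribution.

**eHC.** Whiten by the eigendecomposition instead: `Z = Λ^(−1/2)Q'β̂` with
eigenvalues sorted descending and each eigenvector's sign fixed so its
largest-magnitude entry is positive (making the transform deterministic).

**iHCM.** The same banded-whitening pipeline applied to the vector of
marginal statistics, whose correlation matrix is estimated either from the
marginal statistics across trait replicates (Pearson, needs ≥ 3 replicates)
or, failing that, from the genotype column correlations. Estimated
correlation matrices are forced positive definite by clipping eigenvalues at
`1e-6` and restoring the unit diagonal. iHCM needs no joint fit, so it
remains available when `n ≤ L + 1`.

**ridge.** Ridge regression of the trait on the standardized gene block
(intercept unpenalized, absorbed by centring), computed along a penalty grid
`{0} ∪ 101 log-spaced points in [1e-3, 50]` via one SVD. The penalty is
chosen by generalized cross-validation, `GCV(λ) = n·SSR(λ)/(n − 1 − df(λ))²`
with `df(λ) = Σ s²/(s² + λ)`; ties go to the smallest λ, and `λ = 0` is the
pseudoinverse (OLS) limit. The score is the residual sum of squares at the
chosen penalty divided by the total centred sum of squares.

## Permutation calibration

Raw scores are not comparable across genes (different `L`, different LD). A
permutation null fixes this: for `j = 1..J` draw one shuffle of the response
and apply the *same* shuffle to every gene and every method, preserving the
LD-induced dependence between gene scores. From each gene's null row:

- **Empirical P-value** `P = (1 + #{null values at least as extreme}) / (J + 1)`
  (add-one convention; ties count as extreme).
- **Normalized score** `(S − mean)/sd` (sd with ddof = 1), sign-flipped for
  smaller-is-better methods so larger always means more significant.

Genes are ranked by empirical P-value; rank 1 is most significant, ties get
average ranks, and unscorable genes get the worst rank (the total gene
count).

**Shared null.** The null distribution of every score depends only on the
genotypes, so the null built by permuting replicate 1 calibrates every
replicate — `J` permutations total instead of `J` per replicate.

### Scale-freeness

The shared null is only valid if a gene's score does not depend on the scale
of the response, because different trait replicates have different variances
while the permutation null holds replicate 1's variance fixed. Two design
choices enforce this: the ridge score divides SSR by TSS, and the
quantitative joint path standardizes the trait before the OLS fit. Both are
gene-independent monotone transformations for a fixed response — they change
no within-replicate comparison, and they are exactly invariant under
permutations — but they make every score a function of the trait only
through its standardized values, so one null serves all replicates.
Marginal t/z statistics and their P-values are scale-free already.

## Multi-replicate evaluation

Given many trait replicates over one panel and a truth set of causative
genes, each method is summarized by the rank of each causative gene in each
replicate. The headline number per method is the mean over replicates of the
average causative-gene rank (smaller is better); the method with the
smallest mean is flagged best.

## Synthetic data generator

The generator emulates the exome-panel regime; it is a study in miniature,
not a population-genetics simulator (no mutation/recombination model, no
population structure, no relatedness).

- **Genotypes.** Per gene, two latent AR(1)-correlated Gaussian haplotype
  vectors per individual (adjacent-SNP correlation `ld_decay = 0.5`) are
  thresholded at each SNP's MAF quantile; minor count = number of latent
  values below threshold; stored major-coded as `2 − minor`. Target MAF and
  LD decay are controlled independently.
- **MAF spectrum.** Mixture: 80% log-uniform on [7e-4, 0.01] (rare), 20%
  log-uniform on [0.01, 0.5].
- **Gene sizes.** `1 +` a geometric mixture (90% p = 0.4, 10% p = 0.05),
  capped at 205 SNPs; median 2 with a long right tail.
- **Causal plan.** Causative variants are rare: candidates are SNPs with
  `0 < MAF ≤ 0.05`, and within each causal gene the largest-MAF candidates
  carry the effect so the causal allele has carriers at all. `effect_size`
  is the effect per genotype standard deviation: the realised per-allele
  coefficient is `effect_size / sd(minor count)`, so every causal SNP
  contributes the same marginal noncentrality `≈ effect_size·√n` regardless
  of MAF — rarer causative alleles get larger per-allele effects, as in the
  regime being emulated.
- **Traits.** Replicates share the genotype panel and redraw only the
  noise. Models: `linear-gaussian` (signal + N(0,1)), `liability-binary`
  (top `prevalence` fraction of the liability), `logistic-binary`.
- **Determinism.** The genotype stream uses `seed`, the causal plan
  `seed + 1`, the trait stream `seed + 2`; everything is reproducible
  byte-for-byte from the config.

## Problem sizes and cost

Per-gene genotype-only quantities (centred design, OLS projection, whitening
operators, the ridge SVD path) are precomputed once, so scoring a permuted
response is a handful of small matrix-vector products per gene. Indicative
timings on one CPU: a 50-gene, 200-individual panel with `J = 2000`
permutations and all six methods runs in well under a minute; a 200-gene,
697-individual panel with 50 replicates in a few minutes. Memory is
dominated by the `genes × permutations` null matrices (a few MB).

## Limitations

- The banded/normalized whitener is *not* an exact whitener by construction;
  iHC/eHC/iHCM scores are meaningful only after permutation calibration.
- The binary-trait joint path refits the logistic model per permutation and
  is correspondingly slower; ridge treats a binary response numerically.
- Joint-estimate methods (ihc/ehc) are unavailable for genes with
  `n ≤ L + 1`; such genes fall back to NaN scores and worst ranks for those
  methods while marginal-based methods still apply.
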