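# Methods

This note documents the statistical model, the defaults and the design
choices behind `pathprs`, and what the synthetic-data experiments do and
do not establish about behaviour on real cohorts.

## Scoring model

A polygenic score is the weighted sum `PRS_i = Σ_j β̂_j g_ij` over index
SNPs, with discovery effects `β̂_j` oriented to the target's alt allele
and dosages `g_ij ∈ [0, 2]`. We use the raw weighted sum rather than a
per-allele average: downstream association results are invariant to any
affine rescaling of the score, so the two conventions differ only in the
units of the reported beta (and scores are z-standardized before fitting
by default, making betas per-SD of score).

**Harmonization.** Summary statistics are matched to target variants by
(chromosome, position). `A1/A2 = alt/ref` keeps the effect sign;
`A1/A2 = ref/alt` negates it. Strand-ambiguous (palindromic A/T and C/G)
pairs are dropped outright — without discovery allele frequencies their
orientation cannot be resolved — as are allele-pair mismatches and
position-level duplicates. Flipping a variant's ref/alt coding in the
target (d → 2−d) therefore changes every sample's score by the same
constant and leaves association inference untouched; this invariance is
property-tested.

**Selection order.** For pathway scores the order is: restrict to the
pathway SNP set, apply the APOE mask, threshold by P, clump. Clumping
*within* the pathway (rather than inheriting genome-wide index SNPs)
keeps the best pathway SNP per LD block; the alternative remains
available via `clump_scope="genomewide"`. Thresholding is inclusive
(`p ≤ P_T`), and the APOE region is a closed interval on both ends —
boundary behaviour is deterministic and tested.

**LD clumping.** Greedy: repeatedly take the unclumped SNP with the
smallest discovery P as index (ties broken by smaller position, then
variant ID, so the result is independent of input order) and remove
unclumped SNPs on the same chromosome within the window whose r² with
the index exceeds the cut-off. Defaults r² > 0.2, window 500 kb, matching
standard clumping practice for this design. r² is the squared Pearson
correlation of dosage columns computed on the target cohort itself,
pairwise-complete over non-missing calls; no external LD reference panel
is used, since each target dataset is clumped within itself. A
zero-variance variant is defined to have r² = 0 with everything and so
cannot clump neighbours. The implementation is checked against a
brute-force reference on random instances including tied P-values.

**Missing dosages.** Mean imputation by default: a missing call
contributes `2 p̂_alt β̂`, with `p̂_alt` the alt-allele frequency among
non-missing target calls (the behaviour of standard scoring tools);
`omit` simply skips the term.

**Score grid.** Labels are {genome-wide} ∪ pathways; thresholds are the
primary 0.001 plus the secondary ladder 0.5, 0.3, 0.1, 0.01, 1e-4, 1e-5,
1e-6; APOE modes are with/without/only. A column that ends up with zero
SNPs is recorded as all-missing with `n_snps_used = 0` rather than
aborting the grid.

## Quality control

* Sample filter first (completeness ≥ 0.97), then variant filters —
  mirroring the usual sample-then-variant ordering — with MAF computed on
  the sample-filtered matrix.
* The three variant predicates (call rate ≥ 0.98, MAF ≥ 0.01, HWE
  P ≥ 1e-4) are evaluated independently on the unfiltered matrix, so the
  retained set does not depend on their order; removal counts attribute
  each failing variant to the first filter in (call rate, MAF, HWE).
* HWE is a 1-df χ² goodness-of-fit test against p², 2pq, q² expectations
  from the observed allele frequency, computed on hard genotype counts
  (non-integer dosages are rounded for counting only, since the filters
  describe array genotypes). A monomorphic site is defined as P = 1 with
  a flag; it will normally be removed by the MAF filter instead.
* ROI outliers: a single pass per ROI sets values with
  |x − mean| > 2.5 SD (SD with ddof = 1) to missing; mean and SD are not
  recomputed after removals, and other ROIs of the same sample are kept.
* Ancestry PCs come from the SVD of per-variant standardized,
  mean-imputed dosages; signs are fixed by making each component's
  largest-magnitude variant loading positive, so PCs are fully
  deterministic. Requests beyond the matrix rank are truncated with a
  warning.

## Association grid

Each (score column, ROI) cell is an OLS fit of the ROI on [intercept,
score, covariates] over that cell's complete cases. Numeric covariates
enter as-is; categoricals (site, array) are dummy-coded. The 95 % CI uses
the t quantile at the residual degrees of freedom rather than 1.96 —
exact in small samples and matching standard regression output. A
constant score or rank-deficient design is flagged unestimable, never
silently pseudo-inverted; ΔR², by contrast, is well-defined under
collinearity (the increment is zero) and is computed by least squares
directly, as `R²(y ~ X + s) − R²(y ~ X)` on the same rows.

BH-FDR is the step-up rule `q_(i) = min_{j≥i}(p_(j) m / j)` capped at 1,
applied within blocks of (ROI family × APOE mode × threshold) — the
"all scores × all family ROIs" testing grid, with each APOE stratum
corrected as its own analysis. Unestimable cells are excluded from the
block's m. A `joint` scope pooling both families is available, since the
grouping of a cross-family correction is a genuinely open choice.

`beats_apoe` compares each cell's ΔR² with the ΔR² of the genome-wide
APOE-region-only score at the same threshold for the same ROI, answering
whether the (pathway) score explains more variance than the APOE locus
alone.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Genotypes.** Haplotypes per LD block come from a latent
  exchangeable-correlation Gaussian (correlation `within_block_r`, 0.8 by
  default) thresholded at each variant's MAF quantile (MAFs uniform on
  [0.05, 0.5]); dosage is the sum of two independent haplotypes, blocks
  are independent, and 1 % of calls are set missing. An exchangeable
  latent factor was chosen over a coalescent simulator because it gives
  direct control of the r² that clumping consumes. Default geometry: 500
  SNPs, 25 blocks of 20, 20 genes tiling the chromosome (25 SNPs each),
  5 kb spacing.
* **Discovery GWAS.** An independent cohort (default n = 8 000, kept
  several-fold larger than the target as in the real design) from the
  same genotype law; a quantitative liability is linear in planted
  standardized per-SNP effects (per pathway, N(0.05, 0.015²) by default)
  plus unit Gaussian noise, and per-SNP marginal OLS supplies betas and
  P-values. A quantitative liability stands in for logistic case-control
  effects because scoring only needs relative weights; the emitted betas
  should be read like log-odds-scale weights.
* **Annotation.** Three overlapping pathways (two share genes, two
  include the APOE-like gene); one pathway avoids the APOE-like region
  entirely, reproducing the one-pathway-without-APOE structure of the
  real gene-set table. The APOE analogue is a single large-effect SNP
  (standardized 0.3) in the last gene.
* **Phenotypes.** Each ROI is `base + sign · effect_size · z(burden) +
  covariate effects + N(0, 1)`, where the burden is the linked pathway's
  planted-effect-weighted dosage sum; unlinked ROIs are covariates +
  noise only. With unit noise, `effect_size` is approximately the
  standardized slope of the true burden (0.15 by default, the planted
  magnitude used in the recovery experiments). ROI units are arbitrary
  (offset constants chosen only to keep values positive), not mm or mm³.
  Covariates are age, sex, ICV, site, array, plus ancestry PCs computed
  from the simulated genotypes themselves — deliberately reproducing the
  circularity of the real pipeline, where adjustment PCs derive from the
  same genotypes being scored. Opposite-direction ROI pairs (the same
  pathway burden raising volume in one ROI and lowering it in another)
  emulate younger/older cohort contrasts within a single table.

Everything is a pure function of (config, seed) via spawned
`SeedSequence` streams, down to the bytes of the emitted VCF/TSV/GMT/BED
files; floats are written with shortest round-trip reprs and read back
with round-trip parsing.

## Validation experiments and their scope

`pathprs.evaluation` runs the full pipeline over seeded replicates:

* **Type-I error** — 50 null cohorts (no planted effects; n = 1 000, 500
  SNPs, 3 pathways) scored at the lenient threshold 0.5 so columns stay
  populated under the null; the pooled fraction of cells at p < 0.05
  should sit near 0.05.
* **Power/sign recovery** — one planted (tau-pathway, hippocampus) cell
  of standardized size 0.15 at n = 2 000 among null ROIs; detection,
  sign, and smallest-q rank are tracked over 50 replicates, and a
  sign-flip configuration checks that opposite planted directions are
  recovered with opposite betas.
* **Threshold profile** — a dense-weak-effects condition (every SNP
  causal, per-SNP effects N(0.006, 0.004²), discovery n = 4 000 so
  discovery P-values spread across the ladder); ΔR² of the genome-wide
  score should be at least as large at P_T = 0.5 as at 1e-6. The
  per-seed check compares the two endpoints of the ladder, since
  adjacent-threshold differences are noise-dominated.

Replicate counts (50/50/25/20) keep the full suite within a few minutes
on one CPU while leaving the binomial uncertainty of each fraction well
inside the asserted bands.

**What passing does not show.** The generator has exchangeable
within-block LD, a single chromosome, no relatedness or population
structure beyond what the PC circularity induces, quantitative (not
ascertained case-control) discovery traits, and Gaussian ROI noise.
Calibration and recovery under these conditions demonstrate that the
machinery is correct and well-calibrated, not that effect sizes or power
transfer to real imaging-genetics cohorts, where LD is irregular,
pathway annotation is contested, and imaging measures have structured
artefacts.

## Numerical and degenerate-input choices

* Thresholding, region masks and gene windows use closed intervals; all
  boundary cases are pinned by tests.
* `bh_fdr` rejects p ∉ (0, 1]; perfect-fit cells (ssr ≈ 0, se = 0) are
  flagged and excluded from FDR blocks along with unestimable cells.
* `pairwise_r2` returns 0 for pairs with < 2 complete observations or
  zero variance.
* Monomorphic draws in the genotype simulator are re-sampled column-wise
  (fresh idiosyncratic noise, same block factor) with a bounded retry
  before erroring.
* The haplotype sampler works in float32 (memory-bound step); dosages are
  promoted to float64 at the matrix boundary. Discovery marginal OLS uses
  exact sums-of-squares identities instead of materializing centred
  copies of the genotype matrix.

## Known limitations

* No support for indels, multi-allelic sites, BGEN/PLINK binary inputs,
  or X-chromosome dosage conventions.
* No shrinkage/continuous-weight scoring methods (lassosum, PRS-CS);
  clumping + thresholding is the implemented estimator.
* LD for clumping always comes from the target cohort; an external
  reference panel is out of scope.
* Gene-set enrichment itself (how the pathways were discovered) is out
  of scope; pathway definitions are inputs.
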