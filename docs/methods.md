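# Methods

## Model

For each trait `y` (length n) the package fits the standard polygenic linear
mixed model

    y = X_L beta_L + x_snp gamma + g + e
    g ~ N(0, sigma^2 h^2 Phi),    e ~ N(0, sigma^2 (1 - h^2) I)

with kinship matrix `Phi` (symmetric PSD, positive diagonal), total variance
`sigma^2 > 0` (trait units squared) and heritability `h^2 in [0, 1)`.
Marginally `y ~ N(X beta, M)` with `M = sigma^2 (h^2 Phi + (1 - h^2) I)`.
Traits are treated univariately: a t-trait analysis is a grid of t
independent single-trait models sharing `Phi` and the covariates, not a
vector-valued mixed model. Matrices are factored, never explicitly inverted.

## Step one: variance components

Per trait, `(sigma^2, h^2)` are estimated by maximum likelihood under the
covariates-only (null) model. One symmetric eigendecomposition
`Phi = V Lambda V'` (computed once per study, eigenvalues clipped at zero
with a warning if any falls below `-1e-8 * lambda_max` — empirical kinships
are only near-PSD) rotates the data into the eigenbasis, where `M` is
diagonal with entries `sigma^2 (h^2 lambda_i + 1 - h^2)`. For fixed `h^2`
the fit is weighted least squares with weights `1 / w_i`,
`w_i = h^2 lambda_i + 1 - h^2`; `sigma^2` profiles to the weighted residual
mean square, leaving a 1-D likelihood in `h^2`.

The maximizer is located by a 21-point grid on `[0, 1 - 1e-6]` followed by
bounded scalar refinement (`xatol = 1e-6`, at most 30 extra evaluations), so
the per-trait budget v is at most ~55 likelihood evaluations, each `O(n p)`
after rotation. Ties within `1e-9` of the maximum resolve to the smallest
`h^2`: with `Phi = I` the likelihood is flat in `h^2` (unidentifiable) and
the estimator deterministically returns 0. The upper bound `1 - 1e-6` keeps
every weight positive even when `Phi` has zero eigenvalues. ML is the
default criterion; REML (which rescales by `n - p + 1` and adds the
`log det(X' W X)` adjustment) is available behind a flag. Traits with
missing values are rejected with a pointer to `mean_impute`; the two-step
scan assumes complete phenotype data.

## Step two: the scan engines

Both engines compute the identical GLS solution
`b = (X' M^-1 X)^-1 X' M^-1 y` for every (SNP, trait) cell; they differ only
in how the `M^-1` is realized. The coefficient covariance is reported as
`(X' M^-1 X)^-1` with `M` already carrying the step-one `sigma^2` — no
post-hoc residual rescaling by default (an optional flag rescales by the
whitened residual mean square). The SNP coefficient gets a two-sided Wald
test against chi-square with 1 df.

**Cholesky engine (single trait).** `M` is formed, factored as `L L'`, and
the covariates, trait and every SNP column are whitened by forward
substitution (`n^2/2` multiply-adds per column). The covariate
cross-products `X_L' X_L` and `X_L' y` (in whitened space) are computed once
and Cholesky-factored; each SNP then contributes only its `2p - 1` new
cross-products and an `O(p^2)` partitioned (Schur-complement) solve. The
factor `L` is rebuilt per trait since `M` is trait-specific.

**Eigen engine (trait grids).** `Phi` is eigendecomposed once; covariates,
every trait column and every streamed genotype block are rotated by `V'`
exactly once (asserted by call-count instrumentation in the tests). In the
eigenbasis each trait's `M` is diagonal, so every cell is a weighted
least-squares solve with per-sample weights
`1 / (sigma^2_j (h^2_j lambda_i + 1 - h^2_j))`, recomputed per trait from
the shared eigenvalues (`O(n)`) rather than cached for all traits
(`O(n t)` memory). The inner loop is trait-major over a resident block of
rotated SNPs; per (trait, block) the weighted covariate cross-products are
rebuilt and factored, after which each cell costs `O(n p)` via the same
partitioned solve as the Cholesky engine.

**Degenerate cells.** A SNP column numerically collinear with the covariates
(monomorphic markers against an intercept being the canonical case — Schur
pivot at or below `1e-10` relative to the SNP's whitened squared norm)
yields a flagged NaN record; the scan never aborts. Rank checks elsewhere
use pivot tolerance `1e-10` times the largest whitened column norm and name
the offending column.

**Bit-reproducible blocking.** Whitening and rotation kernels process matrix
columns one at a time, so a column's result never depends on which other
columns share its block; scan output is byte-identical for any block size.
This trades some large-matrix BLAS throughput for exact reproducibility of
the streamed pipeline, an acceptable cost at the problem sizes this package
targets.

## Planner and instrumentation

Engines charge each dispatched kernel its textbook multiply-add count to a
named phase (Cholesky `n^3/6`, triangular solve `n(n+1)/2`, rotation `n^2`
per column, eigendecomposition booked at the LAPACK-style `9 n^3`, plus the
per-cell cross-product and Schur-solve counts). The planner sums the same
per-kernel formulas analytically, so predicted costs are calibrated to the
instrumented implementation by construction and the two agree wherever both
are computable. Step one (the shared eigendecomposition plus `t v`
likelihood evaluations, default budget v = 50) is booked identically for
both algorithms and cancels in the comparison. `select_algorithm` returns
the engine with the smaller predicted total; for n = 1000, m = 10^6, p = 4
the crossover lands at t* = 3 resident traits — single-trait scans go to the
Cholesky engine (whose per-column triangular transform costs half a
rotation), trait grids to the eigen engine, and an explicit engine choice
always overrides the selector.

The memory contract is `n^2 + (k + p) n` resident matrix entries, where k
counts SNP plus trait columns held at once (minimum 2). Engines register
every kinship-sized and block-sized allocation with a meter; tests assert
the instrumented peak stays under the budget when streaming from disk.

## Data formats

Tab-delimited text (row = sample, header of column ids, first column sample
id, missing token `NA`) and the MMG1 raw binary matrix (magic, rows/cols/
element-size as little-endian 64-bit integers, row-major float64) are the
reference formats; result cubes use the BCUB container (dimensions, label
tables, then B, SE and chi-square payloads) with bit-exact round-trips.
Sample alignment across files is by strict id-sequence equality — a mismatch
is an error, never a silent reorder, since silent reordering is the classic
GWAS corruption mode. A minimal PLINK .bed/.bim/.fam importer decodes
2-bit SNP-major genotypes to A1-dosages with missing as NaN. Genotype
dosages outside [0, 2] only warn (imputed dosages can exceed the bounds).
Text output uses 6 significant digits; all internal arithmetic is double
precision.

## Synthetic cohorts

The generator draws what the model assumes and nothing more:

- **Kinship**: block-diagonal families (within-family coefficient 0.5,
  diagonal 1; default family size 4, roughly a nuclear-family/sibship
  scale), giving exact, interpretable ground truth; a genotype-derived GRM
  (`Z Z' / m` on column-standardized dosages) is available for
  pedigree-free use.
- **Genotypes**: independent biallelic dosages, `Binomial(2, f)` with
  `f ~ U(0.05, 0.5)` per SNP. Relatedness enters through `Phi` only; the
  two-step scan is insensitive to linkage disequilibrium, so none is
  simulated.
- **Phenotypes**: exactly the generative mixed model, with per-trait
  substreams split from one master seed so enlarging the design never
  perturbs previously drawn components.
- **Ratio traits**: the metabolomics convention of expanding k positive base
  measurements into the k originals plus all k(k-1) ordered pair-wise
  ratios (k^2 total; 328 bases give 107,584 traits).

Default study conditions used throughout the tests: `sigma^2 = 1`,
`h^2 = 0.5`, n = 500 for recovery checks. What passing tests show is that
the estimator and engines are correct and calibrated *under the model's own
assumptions*; real cohorts add LD, ascertainment, genotyping error,
non-Gaussian traits and mis-specified kinships, none of which the generator
emulates.

## Problem sizes

The verification suite runs everything at desk scale, chosen as the smallest
designs where each property is identifiable: 200 random designs (n ≤ 100,
p ≤ 5, t ≤ 8) for the three-way engine/oracle agreement at 1e-8 relative;
50 replicates of n = 500 family cohorts for heritability recovery; a
400 x 250 x 40 null grid (10,000 cells) for type-I error and
genomic-control lambda; and doubling experiments on instrumented counts for
the complexity exponents. The asymptotic claims at biobank scale follow from
the counted kernel totals, not from wall-clock measurements.

## Known limitations

- The two-step approximation holds `(sigma^2, h^2)` fixed across SNP tests;
  SNPs with large effects slightly violate the null-model variance estimate
  (the standard trade-off of this method family).
- Complete-data assumption per trait; only mean imputation is bundled.
- One random effect; no multi-component or low-rank variance structures.
- Univariate traits: no joint multi-trait test, and the Bonferroni helper
  ignores correlation between derived (e.g. ratio) traits, making it
  conservative there.
- The asynchronous compute/IO overlap of a production out-of-core solver is
  replaced by a synchronous bounded-memory block pipeline with the same
  working-set contract.
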