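# Methods

## Model

`mppqei` detects and classifies QTL-by-environment interactions (QEI) in
multi-parent populations (MPPs) phenotyped in multi-environment trials
(METs). The observation vector stacks genotypic means (BLUEs) for `N`
records over `C` families, `J` environments and `G` genotypes:

    Y = X beta + Z_q u_q + g + eps

* `X beta` — fixed family-by-environment cell means (equivalent to
  intercept + family + environment + interaction; environment means when
  C = 1).
* `Z_q u_q` — random parental QTL effects at a genome grid position `q`.
  Entries of `Z_q` are expected numbers of allele copies inherited from
  each founder (the IBD summaries `pi`, summing to 2 per observation for
  inbred lines). Four variance structures express the consistency of the
  parental effects:

  | type  | effects              | columns | covariance of u_q          |
  |-------|----------------------|---------|----------------------------|
  | EC&FC | one per parent       | P       | I_P * s2                   |
  | ES&FC | parent x environment | P*J     | direct sum of I_P * s2_j   |
  | EC&FS | parent-in-family     | 2C      | direct sum of I_2 * s2_c   |
  | ES&FS | both                 | 2C*J    | direct sum of I_2 * s2_jc  |

  For MAGIC designs (one funnel family, >2 founders) only the
  environment dimension applies; family-specific structures are rejected.
* `g` — polygenic background with Kronecker covariance
  `Sigma_MET (x) Sigma_MPP` over (environment, genotype) levels.
  `Sigma_MET` is `id` (one variance), `idh` (variance per environment) or
  `us` (unstructured); `Sigma_MPP` is `id`, `idh` (family weights) or
  `kin` (grid-based kinship `K = (1/2L) sum_m Pi_m Pi_m'`). The MET factor
  carries all scale; the MPP factor is normalized (identity, weights with
  the first family fixed at 1, or unit-scaled kinship) to remove the
  scale confounding inherent to a Kronecker product. The default is
  `us x idh`, the structure that worked best for real MET/MPP data.
* `eps` — independent residual with environment-specific variances
  (`idh`) by default, reflecting heterogeneous trial precision in
  stage-2 analyses of BLUEs; a homogeneous option is available.

## Estimation

Variance parameters are estimated by REML. The driver uses
average-information (AI) updates with step halving and an active-set
treatment of non-negativity bounds (variances reaching zero are fixed
there, and released when their score turns positive; boundary estimates
are reported as exactly 0). `Sigma_MET^us` is parameterized by a
triangular factor with log-scaled diagonal so it stays positive definite.
Because AI steps crawl when the factor approaches singularity (fitted
environment correlation near +/-1) or several parameters sit near
boundaries, the driver hands over to a projected-gradient polish
(L-BFGS-B on the analytic score) whenever progress stalls or the score is
not small at AI convergence, and falls back to a bounded derivative-free
search if the AI machinery fails outright. Convergence: relative
log-likelihood change < 1e-8 and relative parameter change < 1e-6, or a
flat likelihood over several iterations; iteration cap 200.

Two numerically equivalent likelihood kernels exist. The general kernel
assembles the dense N x N covariance. When the model is exactly
polygenic-with-diagonal-MPP plus diagonal residual, V is block-diagonal
over genotypes with one J x J pattern per (family, environment-set)
group, and all REML quantities (value, score, AI matrix) reduce to
batched small-matrix algebra — the hot path for genome scans and
replicated simulations. Equivalence to a textbook dense-covariance
oracle (explicit Kronecker products, generic determinants/solves) is
asserted to 1e-6 in the test suite across all nine polygenic and four
QTL structures.

The REML log-likelihood convention is
`-1/2 [log|V| + log|X'V^-1 X| + y'Py] - (N-p)/2 log(2 pi)`; all
comparisons (LRT, AIC) share the same fixed part, which keeps REML
likelihoods comparable.

## Testing and model selection

A QTL at a grid position is tested by a likelihood-ratio test of its
variance component(s); the p-value uses the boundary mixture
`p = 0.5 Pr(chi2_1 >= T)` with `p = 1` at `T = 0`. Multi-component types
(ES&FC, EC&FS, ES&FS) are tested jointly against the no-QTL null with the
same 0/1-df mixture by default; an equal `chi2_{df-1}/chi2_df` mixture is
available by configuration. Genome-wide significance uses a Bonferroni
threshold `-log10(alpha / n_grid_positions)` at alpha = 0.05 per scan
series.

The scan protocol per effect type: fit the no-QTL model (polygenic +
residual + current cofactors) once per round; hold those parameters fixed
while profiling each position's QTL variance on the whitened data through
low-rank (Woodbury) identities; add the highest supra-threshold peak as a
cofactor; mask a 20 cM exclusion window around it; repeat until no
position exceeds the threshold ("profile stabilized") or the round cap
(10) is reached. Cofactors enter later rounds as random QTL terms of the
type being scanned, keeping each series' model class homogeneous. A full
joint refit per position is available (`full_reml`), at substantially
higher cost.

Loci found by different type-scans within 10 cM (half the exclusion
window) on the same chromosome are merged, the merged position taken from
the most significant scan. Each locus's effect type is then resolved by
AIC (`-2 ll_REML + 2 k`, k = declared variance parameters, boundary-fixed
ones included): the combined multi-QTL model is refit once per candidate
type, loci being visited once in order of significance, and the smallest
AIC wins. A final joint model provides BLUP allele-effect profiles per
locus (shrinkage estimates `G Z' P y` at the REML estimates, labeled
parent / parent-in-family, by environment where applicable).

For single prespecified loci (calibration and recovery studies) the
package also offers an exact joint LRT in which background parameters are
re-maximized together with the QTL variance by nesting the cheap profiled
likelihood inside an outer bounded search. The fixed-background shortcut
slightly understates the statistic because the null-fitted background
absorbs locus-aligned variance; the joint version is the statistic the
chi-square-mixture approximation refers to.

### Finite-sample behavior of the boundary mass

The 0.5/0.5 mixture weight is asymptotic. For an EC&FC component in a
four-founder diallel, the design offers only ~3 estimable founder-contrast
directions after the family-by-environment means, and the null
probability of a boundary estimate (T = 0) is then well above 0.5 at any
realistic size — about 0.62 in our simulations even when the background
covariance is known exactly, and 0.61-0.64 when it is estimated. This is
the small-eigenstructure phenomenon known from exact restricted-LRT null
distributions. The test is conservative, never anti-conservative: the
empirical size of the joint statistic at nominal 0.05 is about 0.03-0.05,
and the fixed-background shortcut used inside genome scans is more
conservative still (about 0.025).

## GGE exploration

Before interpreting environment-specific QTLs, the genotype x environment
table of BLUEs can be summarized by a rank-2 principal-component fit:
environment-centered, unscaled, symmetric singular-value scaling of
genotype scores and environment loadings, first loading of each axis made
non-negative. Missing cells (<= 20%, no empty row/column) are imputed by
iterative rank-2 EM for the decomposition only. Pairwise environment
correlations use shared genotypes (minimum 3 per pair).

## Simulator

The simulator provides the study conditions for every statistical test.

* **Meiosis** — Haldane model (no interference): crossover count per
  chromosome ~ Poisson(length/100), positions uniform, alternating
  strands; count-location formulation.
* **Designs** — biparental DH (one doubled F1 gamete) and RIL-by-selfing
  families (explicit gamete simulation per generation; residual
  heterozygosity retained), assembled into diallel or NAM panels; MAGIC
  as a balanced funnel over a power-of-two founder set (one random funnel
  permutation per line; 16 founders: 8 two-way, 4 four-way, 2 eight-way,
  1 sixteen-way crosses) followed by selfing (default 6 generations).
* **IBD** — exact allele-copy counts on the evaluation grid (default step
  5 cM; 0.5 cM is typical for MAGIC); optional convex "blur" toward the
  family prior emulates the uncertainty of marker-derived IBD while
  preserving row sums of 2.
* **Phenotypes** — family-by-environment intercepts + QTL effects of any
  of the four types (explicit values or drawn with stated variances) +
  polygenic draw with covariance `Sigma_MET (x) Sigma_MPP` + independent
  Gaussian residual per environment. All true components are stored for
  recovery tests.

What the simulator does not emulate: marker ascertainment and genotyping
error, segregation distortion/selection during population development,
non-inbred offspring, spatial field trends (inputs are assumed to be
spatially adjusted BLUEs), and HMM-induced correlation structure of real
IBD uncertainty (the blur is i.i.d. across positions). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to these real-data features.

## Default study conditions in the test suite

Chosen once as representative desk-scale conditions; sizes are stated
here as the package's own choices.

* Null calibration: diallel 4 x 100 DH, J = 2, one 100 cM chromosome,
  polygenic `us` (variances 1, correlation 0.5) x `idh` weights
  (1, 1.3, 0.8, 1.1), residual (0.5, 0.8); 1000 replicates; one EC&FC
  locus test at 50 cM.
* Variance recovery: same background, 4 x 50 DH, ES&FC locus with
  environment variances (4, 0); 50 replicates.
* Type resolution: 4 x 20 DH, one 100 cM chromosome, component variance 8
  against residual 1 and polygenic 0.5; 50 replicates per type. The
  "noise-free" runs use fixed parental effects of magnitude ~3 (identical
  across the axis the type declares consistent) over residual 0.1: an
  effect-to-noise variance ratio around 30 is effectively noise-free while
  keeping the likelihood surface well conditioned — at residual variances
  near machine scale the covariance is close to singular and log-likelihood
  differences between nested structures blow up, letting any extra
  parameter win regardless of truth.
* Scan power/error: 4 x 50 DH, two 80 cM chromosomes, 5 cM grid, EC&FC
  variance 2 at chr 1, 40 cM; 50 power and 200 null replicates.

## Numerical choices and edge cases

* Observation order is canonical (environment, then family, then
  genotype); all direct sums are literally block-diagonal.
* Probability-style IBD input (rows summing to 1) is rescaled to allele
  copies on read; off-grid rows are linearly interpolated per parent and
  renormalized to sum 2.
* Ties in peak selection break by genomic order (chromosome label, then
  position); all randomness flows from a single configured seed, and
  inference itself contains no randomness, so scans are bit-reproducible.
* Initialization: the phenotypic variance is split equally across active
  terms; unstructured correlations start at 0.3; family weights at 1.
* Degenerate inputs (zero-length chromosomes, constant phenotypes,
  singular candidate covariances) are handled by rejection or boundary
  fits rather than crashes; non-converged scan positions are recorded as
  NA and excluded from peak selection.

## Known limitations

* Dense-covariance general path is O(N^3) per evaluation; the blocked
  fast path covers the common background models, but large unbalanced
  datasets with kinship backgrounds will be slow.
* The AIC type resolution visits loci once in significance order rather
  than iterating to a fixed point; with many closely linked loci of mixed
  types the provisional types of later loci could influence earlier
  decisions.
* BLUE standard errors are accepted on input but not used as weights by
  default (no weighting option is wired into the scan protocol yet).
* Single-trait analyses only; no dominance or epistasis design matrices.
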