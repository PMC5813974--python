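# Methods

## Model

For a quantitative phenotype `y` on `n` individuals and a haplotype
block `k`, the model is

    y = X beta + Z_k gamma_k + xi + eps

with `X` the fixed-effect design (intercept only by default — the
intended phenotypes are pre-adjusted breeding values; arbitrary
covariate columns can be supplied), `Z_k` the n × h haplotype
inheritance matrix, `gamma_k ~ N(0, I phi_k^2)` the random block
effect, `xi ~ N(0, K phi^2)` the polygenic effect and
`eps ~ N(0, I sigma^2)`. Hence

    var(y) = (Z_k Z_k' lambda_k + K lambda + I) sigma^2,
    lambda = phi^2 / sigma^2,   lambda_k = phi_k^2 / sigma^2.

Row j of `Z_k` counts the copies of each haplotype individual j
carries: a 1/2 heterozygote is `[1 1 0 0]`, a haplotype-3 homozygote
`[0 0 2 0]`; every row has at most two nonzero entries and sums to
exactly 2. Treating `gamma_k` as random with a variance estimated from
the same data is the empirical-Bayes element: the fitted `lambda_k` is
the prior scale under which the haplotype effects are predicted (BLUP)
and tested.

### Eigen-accelerated profiled REML

`K` is the VanRaden method-1 genomic relationship matrix built from all
MAF-filtered markers, including the tested block's own markers (no
leave-one-chromosome-out; the package exposes the kinship builder
separately, so a LOCO kinship can be passed in if wanted). With the
one-time eigendecomposition `K = U D U'` and rotated data `y* = U'y`,
`X* = U'X`, `Z* = U'Z_k`, the covariance of `y*` is
`(Z* Z*' lambda_k + R) sigma^2` with diagonal `R = D lambda + I`.
Profiling out `beta` and `sigma^2` leaves

    L(lambda_k, lambda) = -1/2 ln|H_k| - 1/2 ln|X*' H_k^-1 X*|
                          - (n - r)/2 ln(y*' P_k y*)

with `H_k = Z* Z*' lambda_k + R` and `P_k` the REML projection. All
solves and determinants use the Woodbury identity / determinant lemma on
diagonal-plus-rank-h structure, so one evaluation costs O(n h^2) after
the single O(n^3) eigendecomposition; no n × n inverse is ever formed.
Equivalence with a dense evaluation of `V = Z_k Z_k' lambda_k +
K lambda + I`, and of the BLUP with Henderson's mixed-model equations,
is enforced by tests to 1e-8 on small instances (measured deviations are
at machine precision, ~1e-13).

### Optimisation

`L` is maximised over `theta = (lambda_k, lambda)` by Newton–Raphson on
`(log lambda_k, log lambda)` — the log scale enforces nonnegativity —
with central finite-difference gradient and Hessian, step-halving line
search, and a step-norm cap. `lambda` is initialised by a null-model
grid search over {0.01, 0.1, 1, 10}; `lambda_k` starts at 0.01. Log
parameters are clamped at ±30, so a boundary estimate is reported as
exp(−30) ≈ 0. If Newton–Raphson stalls, a Nelder–Mead polish runs; a
fit is flagged converged when the gradient max-norm falls below
max(1e-6, 100·eps·|L|/1e-5) — the second term is the rounding noise
floor of a finite difference of `L`, which matters for n ≳ 1000 where
|L| is in the thousands — or when the only nonzero gradient components
push against the zero clamp. Non-converged fits keep their row in the
scan table but are never called significant.

### Test statistic

At the optimum, `sigma2_hat = y*' P_k y* / (n - r)`, `beta_hat` is the
GLS solution, and the empirical-Bayes effects are the BLUP
`gamma_hat = lambda_k Z*' P_k y*` with posterior covariance

    gamma_cov = sigma2_hat * lambda_k (I - lambda_k Z*' P_k Z*),

identical to the gamma block of the inverse mixed-model-equation
coefficient matrix. The Wald statistic is
`W_k = gamma_hat' pinv(gamma_cov) gamma_hat` (pseudo-inverse with
relative rank tolerance 1e-8) and `p_k = Pr(chi2_1 > W_k)`, with one
degree of freedom regardless of the number of haplotype columns, as
published for this method. `wald_test(..., df="rank")` instead refers
`W` to chi-square with rank(gamma_cov) degrees of freedom.

**Null calibration.** With more than two haplotypes the statistic
aggregates an (h−1)-dimensional contrast (the row-sum-2 constraint makes
one direction collinear with the intercept), so the chi2(1) reference
cannot be exact. Measured on 2000 blocks simulated under a purely
polygenic trait (lambda = 0.5, n = 200, generator defaults): roughly
60% of p-values exceed 0.9 — whenever the REML estimate of lambda_k is
small, both `gamma_hat` and `gamma_cov` shrink and `W -> 0` — while the
empirical Pr(p < 0.05) is about 0.07–0.09, slightly above nominal. The
test is therefore conservative in the bulk and mildly anticonservative
in the tail; genome-wide calls rely on the far tail (thresholds around
1e-4 and below), where the published method is followed as printed. The
acceptance suite contains an intentionally strict uniformity check that
documents this behaviour; the single-SNP scan (h = 1) does not share
the aggregation issue.

## Multiple-testing correction

Classical Bonferroni divides `alpha` (default 0.05) by the number of
tested blocks. The modified Bonferroni divides by an effective number
of independent tests `m_eff`, by default the Li & Ji estimator
`m_eff = sum_i [ I(|e_i| >= 1) + (|e_i| - floor|e_i|) ]` over the
eigenvalues of the correlation matrix of block lead-SNP dosages (lead =
largest-MAF marker of the block); Gao's simpleM (smallest k capturing
99.5% of eigenvalue mass) is available as `method="simpleM"`. The
published study's m_eff (618.31 over 13 476 blocks) is reproducible only
from the real genotypes; the estimator choice here is a package default,
since the original computation is not described. Blocks are labelled
"Both Bon& mBon" (p <= alpha/m), "Only mBon" (alpha/m < p <=
alpha/m_eff) or none; comparisons use <= at the threshold.

## Block detection

Pairwise |D'| confidence bounds come from likelihood profiling on a
101-point grid over [0, 1]: allele frequencies are fixed at their sample
values, the multinomial likelihood of the 2 × 2 gamete table is
evaluated on the grid, normalised, and 5% of the mass is cut from each
end. Phased data make gamete counts exact (no EM step). A pair is
"strong LD" when the lower bound exceeds 0.70 and the upper bound
reaches 0.98, "strong recombination" when the upper bound is below
0.90 (Haploview defaults, configurable). Every contiguous window of up
to 30 markers on a chromosome is a candidate; it qualifies when at
least 95% of its informative pairs are strong LD. Qualifying windows
are accepted greedily, largest first (ties to the leftmost), without
overlap; accepted runs longer than 4 markers are split left-to-right
into chunks of at most 4 (single-marker remainders are dropped),
because only 2–4-SNP blocks enter the scan. Block haplotypes are
labelled `H` + concatenated allele codes (0 = REF) and ordered by
descending chromosome frequency, ties lexicographic.

Haplotypes seen on fewer than `min_hap_count` chromosomes (default 5)
are pooled into a single "rare" design column rather than dropped,
preserving the row-sum-2 invariant; a block with fewer than two common
haplotypes is skipped with a logged reason.

## Synthetic data generator

Each block draws a pool of "prefix" haplotypes (000, 100, 110, 111 for
a 3-SNP block) with Dirichlet(1) pool frequencies; prefix pools never
produce all four gametes for any marker pair, so pool draws are in
complete LD (|D'| = 1). Every chromosome is an independent pool draw;
each site is then resampled from its marginal frequency with
probability `1 - block_ld`. Defaults and what they represent:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 500 | cohort size |
| `n_blocks` | 50 | LD blocks on the single simulated chromosome |
| `snps_per_block` | (2, 3, 4) | admissible block sizes, drawn uniformly |
| `maf_range` | (0.05, 0.5) | realised MAF bounds, enforced by rejection sampling |
| `block_ld` | 0.98 | within-block haplotype fidelity; 1.0 = perfect LD, 0 = independent sites |
| `inter_block_spacing_bp` | 50 000 | gap between blocks |
| `intra_block_spacing_bp` | 500 | gap within blocks |
| `n_causal_blocks` | 1 | blocks carrying true effects |
| `h2_block` | 0.05 | phenotypic variance share per causal block |
| `h2_polygenic` | 0.30 | polygenic variance share |
| `seed` | required | single source of randomness |

`block_ld = 0.98` was chosen so that simulated blocks are strong but
imperfect: the Gabriel scanner recovers most (~95% at n = 500) while
recombinant haplotypes still occur. At 0.9 the within-block |D'| (~0.8)
essentially never satisfies the strong-LD confidence rule, which would
make the default population useless for end-to-end runs. Real LD decay
in any particular cattle population is not calibrated — the knob is
free.

Phenotypes are drawn from the analysis model itself: causal haplotype
effects `gamma ~ N(0, phi_k^2 I)` with `phi_k^2` scaled by the trace of
the block design's row covariance so the expected variance share equals
`h2_block`; the polygenic term uses the realised GRM of all simulated
markers (so the fitted model is correctly specified); `sigma^2 = 1 -
h2_polygenic - n_causal * h2_block` puts total variance near 1. Ground
truth (causal block ids, effects, lambda, lambda_k, sigma2) is recorded
for recovery tests.

What the generator does **not** emulate: pedigree/family structure
(relatedness enters only through the realised GRM of independent pool
draws, so kinship is near-identity — weaker confounding than a real
half-sib cattle cohort), LD *between* blocks, recombination maps or
coalescent genealogy, multi-chromosome genomes, and the smoothness of
breeding-value phenotypes estimated from repeated test-day records.
Passing tests therefore demonstrate internal statistical correctness of
the machinery, not robustness to population structure of real dairy
data.

## Numerical choices

* Coordinates are 1-based inclusive (VCF convention) everywhere; BED
  input is converted on read.
* Missing or unphased genotypes are rejected at load, never imputed;
  imputation and phasing are upstream concerns.
* `D'` grid: 101 points; degenerate (in-sample monomorphic) pairs are
  uninformative for block building and an error for `dprime_ci`.
* Li & Ji eigenvalues are floored with a 1e-10 guard so an eigenvalue
  that is an integer up to round-off contributes exactly 1.
* Kinship eigenvalues are clipped at 0 (round-off can produce ~−1e-15).
* GLS/BLUP at the boundary lambda_k = exp(−30) is evaluated normally;
  W underflows to ~0 and p to 1, which is the intended degenerate
  behaviour.
* All simulation randomness flows from one integer seed through
  `numpy.random.default_rng([seed, stream])` with distinct fixed stream
  ids for genotypes and phenotypes, making the (genotypes, phenotypes,
  truth) triple bit-reproducible.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: oracle equivalence on 25 instances at n = 40; null
calibration on 2000 (tests) / 1000 (script) blocks at n = 200;
parameter recovery with 50 phenotype replicates at n = 2000 over one
fixed genotype draw (one eigendecomposition, redrawn effects and
noise); block-detection recovery on planted perfect-LD chromosomes of
~25 markers. These choices are stated here as the package's own
validation design.

## Known limitations

* The chi2(1) Wald reference is miscalibrated under the null for blocks
  with more than two haplotypes (see "Null calibration" above); this is
  inherent to the published test, not to this implementation.
* Whether the original analysis re-estimated lambda per block or fixed
  it genome-wide is not documented; here the two-parameter likelihood
  is maximised jointly per block, which is the literal reading of the
  profiled likelihood.
* Gabriel block membership depends on CI conventions; other tools'
  dialects (window caps, frequency pruning) will partition real data
  differently. Only internal consistency with the stated rule is
  guaranteed.
* The favorite-allele call uses the single-marker kinship-adjusted
  model; a haplotype-model-based definition would be equally defensible.
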