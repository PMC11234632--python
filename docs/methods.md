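# Methods

## The prediction problem

The package predicts additive genetic values of dairy cows from dense SNP
genotypes and yield deviations (YD): phenotypes corrected for systematic
effects and averaged over a cow-specific number of lactations `n_i`.
Because `n_i` varies, YD precision varies; with variance ratios
`lambda = sigma2_e / sigma2_g`, `kappa = sigma2_pe / sigma2_g` and
`alpha = sigma2_e / sigma2_pe`, the YD reliability and the observation
weight used throughout are

    r2_i = n_i / (n_i + lambda + n_i kappa)
    w_i  = n_i (alpha + 1) / (alpha + n_i)

`w_i` rises from 1 (one lactation) towards `alpha + 1`; the residual
covariance in every mixed model is `R sigma2_e` with `R = diag(1/w_i)`.
At `n = 1` the reliability equals the trait heritability — an algebraic
identity the tests exercise.

## Genomic relationship matrices

Genotype codes `M_ij` (0/1/2 copies of the alternate allele) are centered
with training-set, observation-weighted allele frequencies,
`X_ij = M_ij - 2 p_j`, which makes every column's weighted training mean
zero.  The weighted GRM is

    G_D = X D X' / sum_j 2 p_j (1 - p_j) D_jj

with nonnegative per-SNP weights `D_jj`; all weights equal gives the
standard (VanRaden method 1) `G_u`, and `G_D` is invariant to rescaling
`D` by any positive constant.  Because numerator and denominator are both
linear in `D`, `E(G_D) = E(G_u)`: weighting redistributes relationship
information without rescaling it.  Missing genotypes (supported although
typical inputs are imputed) are excluded from frequency estimation and
mean-imputed to 0 on the centered scale, preserving the zero-mean
property.  No blending toward the identity is applied by default; a
`clip`-style option exists only in the multitrait covariance handling.

## Mixed model machinery

All single-trait analyses share one model, `y = 1 mu + g + e` with
`g ~ N(0, G sigma2_g)` and `e ~ N(0, R sigma2_e)`, and one numerical
device: with `B = R^(-1/2) G_tt R^(-1/2) = U L U'`, the covariance is
diagonal in the rotated basis, so after a single O(n^3)
eigendecomposition every REML iteration, every GLS solve and every
per-SNP association test costs O(n).

* **REML.** Average-information updates for `(sigma2_g, sigma2_e)` with
  EM fallback whenever an AI step proposes a non-positive component, and
  step halving so the accepted restricted-likelihood path is monotone.
  Convergence: relative parameter change < 1e-6, at most 100 iterations;
  non-convergence is flagged, not raised.  Standard errors come from the
  inverse AI matrix.
* **GBLUP.** The mixed-model equations are solved by Cholesky
  factorization of `V_tt = sigma2_g G_tt + sigma2_e R` (a conjugate-
  gradient path exists for very large n; both paths agree to 1e-6).
  Animals without phenotypes are predicted through the cross-covariance
  block, `g_hat_v = sigma2_g G_vt V_tt^-1 (y - mu_hat)`, algebraically
  equal to `G_vt G_tt^-1 g_hat_t`.
* **SNP-BLUP.** The equivalent ridge formulation assigns SNP `j` prior
  variance `sigma2_g D_jj / sum_j 2 p_j (1-p_j) D_jj`; its genetic values
  reproduce weighted GBLUP exactly, which the tests verify to 1e-6.
* **Weighted-G variance components.** Predictions with a weighted matrix
  reuse the `G_u`-based REML estimates by default; re-estimation with
  `G_D` is available behind a flag.

The residual weighting `R = diag(1/w_i)` is applied in GBLUP as well
as in the association scan, so repeated-record precision is treated
consistently across the model stack.

## Association scan and SNP weights

The scan is EMMAX-type: variance components fixed at their null-model
estimates, each SNP tested by GLS.  For SNP `j`,

    b_hat_j = (X_j' V^-1 X_j)^-1 X_j' V^-1 y
    se_j    = (X_j' V^-1 X_j)^-1/2
    LR_j    = 1/2 y' V^-1 X_j b_hat_j = 1/2 (b_hat_j / se_j)^2

No intercept is fitted; the weighted centering of `X` makes the mean
orthogonal to each SNP effect, and `y` is centered by its weighted mean
to guard non-centered inputs.  P-values use the chi-square(1 df) upper
tail of `2 LR`; the log-scale tail (via the normal `log_ndtr`) keeps
`-log10 p` finite for arbitrarily large LR.

Weights are then built in three steps:

1. **Smoothing.**  A moving average of `LR_j` over an odd window `s`
   centred on each SNP (windows 1, 5, 11, 21, 41, 81, 161 exposed;
   default 5).  Windows truncate at chromosome boundaries — only
   same-chromosome neighbours enter and the divisor is the count actually
   used — so constant series are invariant and no signal leaks across
   chromosomes.  (Zero-padding and wraparound were the alternatives; the
   truncation rule is this package's convention.)
2. **Posterior probabilities.**  `PP_j = pi e^LR / (pi e^LR + 1 - pi)`
   with prior `pi = 0.001` by default, computed as a stable logistic in
   log space; no flooring or capping beyond the formula itself (weights
   are naturally >= ~pi, keeping `G_D` well defined).
3. **Assembly.**  `gwablup` uses the smoothed `PP_j` directly as `D_jj`;
   `topsnps` puts weight 1000 on one SNP per genome-wide-significant peak
   (p < 1e-7; significant SNPs on a chromosome closer than 1 Mb merge
   into one peak, the max-LR member is taken — a deterministic stand-in
   for manual per-chromosome selection) and 1 elsewhere; `uniform` and
   `custom` are as named.

## BayesGC

The Bayesian comparison model adds a BayesC term to GBLUP:
`y = mu + g + sum_j I_j X_j b_j + e`, `I_j ~ Bernoulli(pi)`,
`b_j ~ N(0, sigma2_g / 1000)`, variance components fixed at REML
estimates and `pi` fixed (not learned).  Gibbs sampling updates the mean,
then every SNP in a randomized order — sampling `(I_j, b_j)` jointly with
the effect integrated out of the inclusion odds — then the polygenic
vector, whose full conditional is diagonal in the spectral basis of the
weight-standardized G (one decomposition, reused every cycle).  Update
order and effect draws are keyed to SNP identity rather than column
position, so permuting columns permutes the posterior exactly.  Production
defaults are 10,000 cycles, 2,000 burn-in, 10 chains; the test bench
uses 2,000/500/2.

A sample-size caveat documented from the test bench: with a few hundred
animals the `sigma2_g/1000` effect prior dominates the per-SNP GLS
information, included effects are shrunk several-fold and the polygenic
term absorbs the remainder, so posterior inclusion probabilities stay
near the prior.  This disappears at the tens-of-thousands scale the
method targets; module tests therefore demonstrate the selection
mechanism with a looser prior, while the acceptance bench runs the full
configuration at n = 1000, where LD partners share the inclusion.

## Multitrait analysis

With complete records, the trait set is rotated by the canonical
transformation: `Q` solves the generalized symmetric eigenproblem of
(genetic covariance, environmental covariance), scaled so canonical
traits have unit environmental variance and diagonal genetic covariance
(ordered descending; sign convention: largest-magnitude row entry
positive).  Each canonical trait is analysed by single-trait GBLUP with
the shared `G`, observation weights unchanged, and the canonical GEBV are
back-transformed with `Q^-1`; the result equals the stacked multitrait
mixed-model solution, which the tests verify against a dense Kronecker
oracle.  Canonical traits are independent, so multitrait GWAS sums their
per-SNP LR values; one shared weight vector serves all canonical traits
(the related-traits assumption), with the per-trait-pair geometric-mean
weights `sqrt(PP_t PP_s)` available as an alternative mode.  Non-PD
covariance inputs are rejected by default (an eigenvalue-clipping
projection is behind an explicit flag) — notably, the published
three-trait environmental correlations (0.97, -0.17, 0.16) reconstruct a
non-PD matrix, so the printed canonical variances cannot be recomputed
from printed values.

## Forward validation

Prediction quality on validation animals (whose phenotypes never enter
any fit) is `cor(y_v, g_hat_v)^2`, usually reported relative to GBLUP;
dividing by the mean validation-YD reliability converts it to an actual
reliability.  Dispersion bias is the OLS slope of `y_v` on `g_hat_v`
(1 unbiased, < 1 inflated, > 1 deflated).  Method differences are tested
by a paired case-resampling bootstrap of `(y, g_hat_k, g_hat_l)` triples
— statistic: difference of correlations; two-sided p with the +1
small-sample correction; degenerate resamples redrawn and counted;
bit-reproducible given (B, seed); B = 10,000 by default.  A compact-
letter display summarizes pairwise significance groups.  Correlations
are unweighted by default (a `w_i`-weighted variant exists behind a
flag).

## Synthetic data

The generator emulates the structure of a dairy training population
without reproducing any real dataset:

* **Genotypes** are founder-haplotype mosaics: per chromosome, a pool of
  30 founder haplotypes with allele frequencies uniform on [0.05, 0.95];
  each gamete copies a founder and switches to a random founder with
  probability 0.05 per SNP step.  At the default 10 kb SNP spacing this
  gives LD blocks of roughly 10 SNPs (~100 kb), the scale at which strong
  LD is observed on livestock HD chips and the scale implied by a 5-SNP
  smoothing window.  A coalescent simulator would add genealogical
  realism the tests do not need; only the LD structure matters here.
* **Traits** follow the repeated-lactation model: genetic value = a
  handful of major QTL plus a polygenic tail over all SNPs (components
  rescaled so realized variances hit their targets exactly at the
  population level), plus a permanent-environment effect and independent
  lactation residuals; the YD is the mean over `n_i ~ uniform{1..4}`
  lactations.  Defaults: 2,000 training + 500 validation cows (the
  validation cows are the youngest birth year), 10,000 SNPs on five
  chromosomes, h2 = 0.30 and `kappa = 0.6` (milk-like ratios), five QTL
  jointly explaining half the genetic variance.
* **Causal loci are hidden by default** (`qtl_observed = False`): they
  are simulated beside the panel and removed from the returned
  genotypes, so their signal reaches the analysis only through LD —
  emulating a SNP chip that tags, rather than contains, causal variants.
  With causal variants on the panel, upweighting the single top SNP is
  trivially optimal and the comparison between weighting schemes is
  uninformative; hiding them reproduces the regime the method addresses.
  The BayesGC recovery bench sets `qtl_observed = True` because its
  success measure is inclusion probability within a +/-10-SNP window of a
  QTL located at a SNP.
* True breeding values are returned so tests can score predictions
  against the truth as well as against validation YD.

What passing simulation tests do **not** show: behaviour under
population structure and admixture, selection, genotyping error,
pedigree-based preadjustment of YD, or the million-SNP scale of real
HD data; runtimes and reliabilities quoted by the test bench are for the
scaled-down conditions above.

## Numerical choices and degenerate inputs

Eigenvalues of G are clipped at zero (round-off); degenerate scan
columns (no GLS information) get LR = 0 and a flag; zero-weight SNPs are
skipped in GRM accumulation; a GRM whose positive weights all sit on
monomorphic SNPs is an error; the HWE exact test uses cumulative-
probability two-sided ordering (not mid-p); MAF filtering is strict
(`>`) and call-rate inclusive (`>=`); QC is idempotent.  Bootstrap and
MCMC randomness always flow from explicit seeds; BayesGC chains use
per-chain `SeedSequence` spawns.

## Problem sizes of the test bench

The acceptance suite runs, per property: the worked examples (exact);
LR identity at n = 500, m = 2,000; null calibration at n = 500,
m = 20,000; reductions at n = 200-300, m = 1,000-1,500; oracle
equivalences at n <= 200; the method comparison at n = 2,000 + 500,
m = 10,000 with 20 seeds per architecture (5-SNP smoothing window for
the five-QTL architecture, 81-SNP window for the fully polygenic one,
matching the published window choices for strong- and weak-signal
traits); bias and bootstrap
calibration over 20 replicates and 500 null runs; BayesGC recovery at
n = 1,000, m = 2,000 with 2 chains x 2,000 cycles.  The acceptance
script reruns the same computations with 8 comparison seeds.
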