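# Methods

`uniblup` implements a single-step genomic evaluation of body-weight
uniformity for a family-structured aquaculture breeding design: relationship
matrices, a double hierarchical generalized linear model (DHGLM) for the
mean and the residual variance of body weight, derived genetic parameters,
masking cross-validation of (G)EBV, and index selection.  A synthetic-data
generator reproduces the statistical structure of the target design so that
every stage is testable without proprietary data.

## Relationship matrices

The numerator relationship matrix **A** is built by the tabular method:
`a_ij = (a_{s(i)j} + a_{d(i)j})/2` for each ordered animal with
`a_ii = 1 + F_i`, `F_i` half the parents' relationship; unknown parents
contribute zero.  The genomic matrix is VanRaden's `G = W W'/N` with
`w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))`; allele frequencies come
from the currently analysed genotyped set, and missing codes are imputed at
`2 p_j` (scaled value 0), which preserves exactly zero column means.  The
combined matrix uses the standard single-step block form

    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21,  H12 = A12 A22^-1 G,  H22 = G,

and its shortcut inverse `H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]`.  Because
`W W'/N` is rank-deficient whenever markers are fewer than genotyped
animals, G is blended as `0.99 G + 0.01 A22` (configurable) before any
inversion, and the blended G is used in both the direct and the inverse
route so the two agree to machine precision.  SNP quality control applies
call rate (>= 0.90), a chi-square (1 df) Hardy-Weinberg test (P > 1e-15) and
minor allele frequency (>= 0.01), sequentially in that order, each stage
counting its own removals.

## The DHGLM

Two sub-models share one record per animal:

    y   = X b   + (Z_s + Z_d) u   + Q c   + e        (mean)
    psi = X_v b_v + (Z_s + Z_d) u_v + Q c_v + e_v    (dispersion)

with `psi_i = log(s2_i) + (e_i^2/(1 - h_i) - s2_i)/s2_i` the linearized
working response for the log residual variance (`s2_i` the fitted
per-observation residual variance, `h_i` the leverage of the mean model's
full fixed-plus-random projection).  Genetic pairs `(u, u_v)` have
covariance `Sigma_u (x) K` with K = A or H over the genetic ids; under the
sire-dam parameterization `Sigma_u` is a quarter of the additive
(co)variance and the Mendelian-sampling half of the additive variance stays
in the residual.  Common-environment pairs `(c, c_v)` are iid over full-sib
families.  Residuals are independent between sub-models and weighted by
`W = diag(1/s2_i)` and `W_v = diag((1 - h_i)/2)`, each with a scaled
variance expected to be 1 — a converged, well-specified fit reports both
near 1, which the tests assert.

Fitting alternates (i) a bivariate Henderson solve, (ii) EM-REML updates of
all (co)variance blocks (conditional-expectation form, so the restricted
likelihood never decreases within an inner cycle), and (iii) a refresh of
psi and the weights.  The first outer pass runs up to 25 EM steps; later
passes run 3, tracking the drift of the working response.  Aitken
delta-squared extrapolation is applied both inside the EM cycle (accepted
only if the likelihood improves) and across outer refreshes (accepted on
boundedness: the outer fixed point moves slowly and monotonically, and the
next EM steps correct overshoot).  Iteration stops when the restricted
log-likelihood changes by < 1e-6 across a refresh or when every
(co)variance component moves by < 1e-4 in absolute value between refreshes;
on standardized responses this resolves components far beyond their
sampling precision (their standard errors on this design are two to three
orders larger).  Components are floored at 1e-8 and the 2x2 blocks are
projected to the positive semi-definite cone with correlations capped at
0.999.  Initialization: mean-model components from a homoscedastic
univariate EM-REML fit, dispersion variances at 0.05, covariances at 0.

The coefficient matrix (a few hundred to ~1000 equations at the sizes this
package targets) is assembled sparse and factorised dense; one Cholesky
factorisation per EM step yields the inverse (for the trace corrections and
leverages), the log-determinant, and the solutions.

Variance estimation uses the sire-dam parameterization throughout.  The
animal-model DHGLM is provided, but when it is asked to *estimate*
components the feedback between an animal's own effect and its own squared
residual can collapse the genetic variance or stall the likelihood — the
documented reason the sire-dam form is the estimation model of choice for
this design; the fit is then returned with `converged=False` and its trace.
Animal-model BLUP *prediction* at fixed components is unaffected.

Downstream, the scalar baseline residual variance is the
observation-weighted mean of the fitted per-observation residual variances
times the scaled variance.

## Derived parameters

From sire-dam components: `sigma2_P = 2 sigma2_u + sigma2_c + sigma2_e`,
`h2 = sigma2_a / sigma2_P` (with `sigma2_a = 4 sigma2_u`),
`c2 = sigma2_c / sigma2_P`,
`h2_v = sigma2_av / (2 sigma2_P^2 + 3 (sigma2_av + sigma2_cv))` and `c2_v`
with the other numerator, `GCV = sqrt(sigma2_av_exp)`.  Exponential-scale
dispersion variances convert to the additive scale by the first-order
linearization `sigma2_av = sigma2_e^2 * sigma2_av_exp` (exact in the
small-variance limit; the tests check it against Monte-Carlo evaluation at
small variance).  Ratios are clipped to [0, 1] with a warning rather than
failing, since REML estimates sit near bounds routinely.

## Cross-validation

Adjusted phenotypes remove the fixed effects using the full-data sire-dam
fit: `y* = a + c + e`, `psi* = a_v + c_v + e_v` (identically, response minus
fitted fixed effects).  Folds are family-stratified: each family's members
are shuffled once and dealt round-robin, so every fold masks ~1/k of each
family and no animal is masked twice.  Each fold performs a single BLUP
solve at the full-fit components, carrying the full fit's working response
and weights for the unmasked records rather than re-iterating them — the
analogue of a no-reestimation BLUP pass on the masked data, and what keeps
a 4-model x 10-fold comparison affordable.  Predictive ability is the
correlation between adjusted phenotypes and predicted breeding values over
the masked animals that are genotyped: Pearson for weight; Pearson, Kendall
tau-b (tie-corrected — the shrunken dispersion EBVs produce near-ties) and
Spearman for uniformity, whose adjusted phenotype is strongly non-normal.
MSEP is scaled by the sample (n-1) variance of the fold's adjusted
phenotypes.  Model differences are summarised as `d +/- 1.96 SE_d` with
`SE_d = sqrt((SD1^2 + SD2^2)/k)`.

## Synthetic data

The generator emulates a salmon nucleus: 131 sires x 234 dams (each dam one
sire, 1-3 dams per sire), 234 full-sib families with lognormal sizes (mean
15.4, clipped to 4-54), ~3600 phenotyped offspring, 50 genotyped families
at 21-38 sibs each plus all parents, and a gene-dropped SNP panel (default
3000 markers — large enough for stable realized relationships while keeping
desk-scale runs light).  Phenotypes follow
`y = mu + beta*age + tank + year_class + a + c + e`,
`e ~ N(0, sigma2_e exp(a_v + c_v))`; default variance components reproduce
the structure of a standardized-weight analysis (h2 ~ 0.26-0.30, c2 ~ 0.11,
sigma2_av_exp = 0.23 so GCV ~ 0.48, mean-dispersion genetic correlation
0.95), and the `log_scale` preset reproduces the log-weight structure
(h2 ~ 0.33, GCV ~ 0.30, correlation ~ 0) with observed weight = exp(y) in
grams, which induces the strong raw-scale mean-variance coupling.

Two genetic architectures are available.  The default (`"marker"`) builds
each animal's breeding-value pair as the sum of its standardized
gene-dropped dosages times iid marker-effect pairs (`beta_j ~ N(0,
Sigma_g/L)`), so realized marker relationships carry the true
Mendelian-sampling deviations — the information channel single-step
evaluation exploits, without which genomic prediction could not beat
pedigree prediction even in principle.  The `"pedigree"` architecture draws
pairs by Gaussian parent-average plus Mendelian sampling (non-inbred 1/2
approximation, adequate for this shallow pedigree) with markers neutral;
it is the right tool for pure variance-component questions.  Neither
architecture models linkage, LD or major QTL, multi-generation selection,
genotyping error, or non-Gaussian residuals — so passing tests speak to the
statistical machinery under the assumed model, not to robustness against
those features of real data.

A note on what "recovery" means for the sire-dam DHGLM on these data: the
sire-dam mean model leaves the Mendelian-sampling half of the additive
variance in its residual, a homoscedastic floor under the heteroscedastic
animal-level noise.  With the strong mean-dispersion genetic correlation of
the default design the estimator recovers the generating
`sigma2_av_exp` on average; at low correlation the same estimator is
attenuated by the floor (roughly the squared ratio of environmental to
total residual variance).  The same mechanism operates on real data, where
the reported exponential-scale variance is likewise defined through the
sire-dam residual.

## Numerical and design choices

- Standardization uses the sample (n-1) variance; Box-Cox lambda is found
  by a coarse grid (step 0.1 on [-2, 2]) plus golden-section refinement on
  the profile likelihood of the fixed-effects-only model, with the lambda=0
  branch equal to the natural log.  The Box-Cox path is reported but, the
  estimate being near 0 on weight-like data, the log transform is the
  first-class scale-adjusted analysis.
- Fixed effects in both sub-models: intercept, centred age covariate, tank
  and year-class dummies (drop-first); factor levels with fewer than two
  records are merged into the reference level with a warning.
- Fold BLUP solves drop fixed-effect columns that lose all records under a
  mask, with a warning.
- Sire-dam animal-level EBV for validation is `u_s + u_d` — the only
  quantity that parameterization defines for an individual; it excludes
  Mendelian sampling, which is precisely why the animal model predicts
  uniformity better and why that comparison is part of the test suite.
- Selection gains are reported on the model scale; percent-of-mean uses the
  observed-scale phenotypic mean, with the exponential back-transform at
  the mean available for log-scale indices (a reporting convention, not an
  asserted result).
- The gene-dropping check of A uses dosage covariances at founder allele
  frequency 1/2 (`cov(x_i, x_j) = A_ij / 2` exactly), giving an unbiased
  Monte-Carlo estimate of every element, including inbred diagonals, in two
  matrix products.

## Problem sizes

The test-suite simulations use 20-60 families for unit-level checks, 200
families x 15 offspring for the parameter-recovery study (10 replicates
each for the positive and the null case), and 60 families x 12 with 30
genotyped families for the prediction comparisons — sizes at which each
DHGLM fit converges in under a minute and the recovery replicates resolve
the components' sampling distribution.

## Known limitations

- EM-REML is robust near zero variances but slow on ridges (near-singular
  genetic blocks at correlation ~1, or the dam-versus-family exchange
  inherent in a design where each dam has one family); runs that exhaust
  the iteration cap are returned flagged rather than raised.
- Because each dam nests exactly one full-sib family, the dam half of the
  genetic dispersion effect and the family common-environment dispersion
  effect share identical design columns; they are separated only through
  the sire links and the assumed covariance structures.  As a consequence
  the genetic dispersion variance is weakly identified at this design:
  under a true value of zero its estimate has a wide, positively shifted
  sampling distribution (replicate medians around 0.02-0.03 rather than
  0), which is a property of the design, not of the optimizer — long
  tight-tolerance runs and runs without any extrapolation reproduce the
  same per-replicate estimates.  Power to *detect* dispersion variance is
  correspondingly limited; treat small estimates at this design as
  order-of-magnitude statements.
- No standard errors for h2_v and GCV are reported (approximation formulas
  out of scope); replicate simulations serve that role here.
- No metafounders, unknown-parent groups, or large-scale approximations of
  H^-1; matrices are dense, appropriate for up to a few thousand animals.
- The exponential-to-additive conversion is first-order; at
  `sigma2_av_exp ~ 0.2` the higher-order terms it drops are a few percent.
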