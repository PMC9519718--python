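# Methods

## The model

`metfa` fits linear mixed models for plot-level phenotypes from
multi-environment trials (METs),

    y = X tau + Z u + Z_p u_p + e,

where `tau` holds a fixed mean per environment, `u` is the vp-vector of
additive genotype-by-environment (GE) effects for v genotypes in p
environments, `u_p` holds random replicate-block effects (one variance
component per environment), and `e` holds independent residuals with a
separate variance per environment.  The GE effects follow a genomic
(GBLUP-style) covariance

    var(u) = G_e (x) G_g,        G_g = M M' / m,

with `M` the column-centred marker scores of the v genotypes and `G_e` a
p x p between-environment genetic covariance from one of ten families:

| family | G_e | genetic parameters |
|---|---|---|
| `id` | s2 I | 1 |
| `diag` | diag(s2_j) | p |
| `comp` | s2_g J + s2 I | 2 |
| `mdiag` | s2_g J + diag(s2_j) | p + 1 |
| `FAMk` | s2_1 J + L D L' + Psi | p(k+1) − k(k−1)/2 + 1 |
| `FAk` | L D L' + Psi | p(k+1) − k(k−1)/2 |
| `rreg1` | s2_g J + s2_s S S' + Psi | p + 2 |
| `rreg2` | s2_g J + S diag(s2_si) S' + Psi | p + q + 1 |
| `FARk` | A L_a D L_a' A' + Psi, A = [1/sqrt(p), S] | p + k(2q − k + 3)/2 |
| `IFAk` | B L_b D L_b' B' + Psi, B = [S, Gamma] | p(k+1) − k(k−1)/2 |

`S` (p x q, q < p) holds known environmental covariates, each centred and
scaled to unit length; `Gamma` is an orthonormal basis of (a subspace of)
the orthogonal complement of col(S), so the integrated (IFA) family's
factors are joint linear combinations of known and latent environmental
covariates while remaining an exact reparameterisation of the conventional
factor analytic (FA) family whenever `B` is square and full rank.  The
reduced-rank integrated variant `IFAk-kr` zeroes the latent loading columns
beyond `k_r`, giving `qk + (p−q)k_r − k(k−1)/2 + p` parameters.

Scientifically the families differ in how they treat the two kinds of GEI:
heterogeneity of genetic scale across environments without rank changes
(non-crossover GEI, captured by a first factor with loadings of a single
sign) versus rank-changing (crossover) GEI in higher-order factors.  Known
covariates make the modelled GEI predictable for new environments; latent
factors make the model fit well.  The integrated family does both, and is
translationally invariant (adding a constant to all phenotypes changes only
the fixed means), unlike the simple random regressions `rreg1`/`rreg2`.

## Estimation

Variance parameters are estimated by average-information (AI) REML.  The
implementation assembles the mixed-model equations at the level of
genotype-by-environment cells: plot data enter only through per-environment
cross-products, so the coefficient matrix has dimension vp + p + (number of
blocks), with a dense `G_e^-1 (x) G_g^-1` genetic block.  Each iteration
factorises the (Jacobi-equilibrated) coefficient matrix once, computes the
REML score from standard mixed-model-inverse identities and the AI matrix
from working variates, and takes a damped AI step with:

* step-halving whenever a step would decrease the restricted likelihood
  (accepted steps never decrease it);
* a trust region on the relative step size (near-singular AI matrices
  propose unbounded steps along flat directions);
* an active set that freezes variance parameters pinned at their floor with
  an inward-pointing score for that iteration, with a diagonally
  preconditioned gradient step as fallback;
* convergence when the largest relative parameter change falls below
  `tol_param` (default 1e-6) and the relative likelihood change below
  `tol_loglik` (default 1e-8).

During estimation the factor-score covariance is fixed at `D = I_k` and the
upper-right triangle of the (stacked) loadings is zero; `rotate()` restores
the principal-axis form afterwards via the singular value decomposition
`B Lambda* = U D^{1/2} V'`, which leaves `G_e` and all fitted GE effects
unchanged.  Signs are fixed so the first factor's mean loading is positive
(a warning lists environments with negative first-factor loadings, which
legitimately occur when the first factor is dominated by centred known
covariates).

### Numerical choices

* **Relationship ridge.**  The centred genomic relationship matrix is
  singular (zero row sums).  Solves add a diagonal ridge of
  `1e-5 x mean(diag(G_g))` by default, recorded on the fit.  Smaller ridges
  make the precision-based likelihood identity lose accuracy (the package's
  tests require agreement with an explicit dense evaluation to 1e-6).
* **Variance floors.**  Specific, block and residual variances are floored
  at `1e-4 x` the mean per-environment phenotypic variance (0.01% of the
  data scale).  Collapsing components enter the equations through their
  reciprocals, so much smaller floors degrade the likelihood identity
  without changing the science.
* **Equilibration.**  The coefficient matrix is symmetrically rescaled by
  its diagonal before factorisation.
* **Starting values.**  Non-factor families start from per-environment
  moment splits.  Factor families first fit the `diag` family (on a subset
  of at most 100 genotypes, with loose tolerances — it only supplies
  variance scales), then seed loadings from the leading eigenvectors of a
  noise-corrected covariance matrix of genotype x environment cell means:
  the residual contribution is subtracted from the diagonal and the mean
  relationship diagonal divided out, which removes the attenuation that a
  raw sample correlation suffers.  Specific variances start at the part of
  each environment's genetic variance the leading factors leave
  unexplained (floored at 5%).  On strongly one-factor simulated data this
  start recovers ~98% of the likelihood gap between the diagonal and
  converged one-factor fits.  Starts are deterministic.
* **Ties and degenerate inputs.**  Rotation rejects numerically collapsed
  factors naming the factor index; mean-zero higher-order factors keep
  their sign; environments with zero known-covariate variance get NaN
  (never fabricated) correlation entries.

### AIC and model selection

`AIC = -2 loglik + 2 m`, with `m` counting estimated variance parameters
only (genetic + per-environment block + per-environment residual; fixed
effects excluded).  This is the convention that reproduces published AIC
values for this model family when the appropriate non-genetic count is
supplied.  Because this package replaces spatial residual models with
independent per-environment residual variances (see Limitations), its own
`m` is `n_genetic + 2p`, which it reports alongside the fit.

## Prediction and cross-validation

Families with known covariates (`rreg1`, `rreg2`, `FARk`, `IFAk`) predict
GE effects for an environment from its covariate row and the genotypes'
score EBLUPs.  For the integrated family

    u_j = (S_j Lambda_s + lambda_bar_r) f,

where `lambda_bar_r` is the column mean of the latent loadings (divisor
p over the training environments), so the latent contribution enters as a
generalised main effect.  Leave-one-environment-out cross-validation refits
everything on the p−1 training environments: covariates are re-centred and
re-scaled on the training set, the left-out row is transformed with the
stored training offsets, and the orthogonal complement is rebuilt, so no
information from the left-out environment reaches the training fit (the
test suite verifies this by perturbing the left-out data).  Accuracy is the
correlation between predicted GE effects and observed genotype mean yields
(plain arithmetic means of non-missing plots).  Future-environment
prediction applies the full-data fit to new covariates transformed with the
training centring/scaling.

## The synthetic trial generator

`simulate_met` draws data with exactly the covariance structure the models
assume.  Defaults emulate a late-stage cotton breeding programme: 204
genotypes in 24 environments with 3 trials of 2 replicate blocks each
(~9,700 plots), 18 correlated known covariates, 6.5% missing plots,
per-environment additive genetic variance ~0.03 (t/ha)^2 with 75% carried
by the common factors (score variances decaying geometrically with ratio
0.45, so a four-factor truth explains ~44/20/9/4% in turn), a 55% known-
covariate share of the composite loadings (the published analysis
attributes roughly this fraction of the factor variance to known
covariates), block variance 0.005, residual variance 0.025 (plot
heritability ~0.5) and environment means N(1.7, 0.4^2) t/ha.  Markers are
binomial draws at uniform allele frequencies; the relationship matrix can
also be supplied directly or set to the identity for unit tests (sampling
uses a symmetric factor of `G_g + eps I`).  A `structure_seed` lets
replicate datasets share one generating truth while redrawing scores,
deviations, blocks, residuals and the missing mask — used by the
Monte-Carlo moment checks.

What the generator does *not* emulate: spatial field trend within trials,
non-Gaussian residuals, genotype-specific missingness (e.g. discarded
entries), covariate measurement error, and multi-year genetic trend.
Passing recovery and cross-validation tests therefore demonstrate the
estimation machinery is correct under the stated model, not that the model
is adequate for any particular field dataset.

## Problem sizes used by the test suite

Oracle-equivalence checks run on tiny instances (p ≤ 6, v ≤ 40) where an
explicit dense covariance evaluation is exact and cheap.  The parameter
recovery suite fits the two-factor integrated model at v = 200, p = 16,
q = 4 with 2 blocks over 20 seeds and requires the total genetic variance
within 15% and the known-loading subspace within a 15-degree largest
principal angle on average; recovery fits use `tol_param = 1e-4`, which is
ample for structural recovery.  Null cross-validation calibration uses 200
replicates at v = 24, p = 4.

## Limitations

* Residuals are independent within environments; the two-dimensional
  spatial models used for field trials are out of scope, so absolute
  log-likelihoods are not comparable to analyses with spatial residuals.
* One block term per environment (blocks nested in trials share the
  environment's variance component); row/column field effects are not
  modelled.
* The optional fixed-effect covariate regression (overall mean, mean
  covariate response, residual environment effect) is implemented but off
  by default and lightly exercised.
* Estimation cost grows as (vp)^3 per iteration; the dense formulation is
  comfortable to a few thousand genotype-by-environment cells and is not
  intended for national-scale METs.
* Factor models have multimodal likelihoods; fits report the iteration
  trace and a convergence flag, and deterministic eigen-seeded starts make
  results reproducible, but global optimality is not guaranteed.
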