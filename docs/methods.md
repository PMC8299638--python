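# Methods

## Model

`factorlmm` fits the multivariate linear mixed model (MvLMM)

    Y = X B + Z U + E,   U_m ~ MN(0, K_m, G_m),   E ~ MN(0, I_n, R)

for an n x t trait matrix Y through an exact re-parameterization as a
two-level mixed-effect factor model:

    Y = F Λ + X1 B1 + X2 B2R + Σ_m Z_m U_Rm + E_R          (level 1)
    F = X2 B2F + Σ_m Z_m U_Fm + E_F                        (level 2)

    U_Rm ~ MN(0, K_m, Ψ_Rm)    U_Fm ~ MN(0, K_m, Ψ_Fm)
    E_R  ~ MN(0, I_n, Ψ_RE)    E_F  ~ MN(0, I_n, Ψ_FE)

with every Ψ diagonal (Ψ_Rm, Ψ_RE strictly positive; Ψ_Fm, Ψ_FE
non-negative).  The K columns of F are latent traits that carry all
covariance among observed traits; conditional on (F, Λ) the t traits — and
the K factors — decouple into independent univariate LMMs.  Integrating the
level-2 terms gives the assembly identities

    G_m = Ψ_Rm + Λ' Ψ_Fm Λ,      R = Ψ_RE + Λ' Ψ_FE Λ,

and with K >= t(M+1) linearly independent contributing rows of Λ any set of
positive-definite targets is representable exactly (verified constructively
in the test suite by stacking Cholesky transposes of the targets into Λ).
Fixed effects are split into X1 (flat priors; at least an intercept) and X2
(proper shrinkage priors).

Fitting to partially observed trait matrices is the basis of prediction and
imputation: traits to be predicted are entered as missing cells, and the
sampler imputes them each sweep, so genetic values for observed and masked
lines are estimated jointly in one fit.

## Variance-component parameterization

Each trait column j carries a sampled total scale sigma2_j and a vector of
variance *proportions* h_j = (h_1j, ..., h_Mj) on a discrete lattice:

    Ψ_Rm[j] = sigma2_j h_mj,     Ψ_RE[j] = sigma2_j (1 - Σ_m h_mj).

Each factor k has total variance fixed at 1 — the scale of (F, Λ) is not
separately identified, so Ψ_Fm[k] = h_mk and Ψ_FE[k] = 1 - Σ_m h_mk are set
entirely by the factor's grid point.  The lattice contains all M-vectors
with components in {0, step, 2 step, ...} and sum <= 1 - step (default step
0.1 for one random-effect term, 0.2 for several, bounding cache size).  For
every grid point the factorization of

    Σ(h) = Σ_m h_m Z_m K_m Z_m' + (1 - Σ_m h_m) I_n

is precomputed once: in the common single-term identity-incidence case the
eigenbasis of K diagonalizes every Σ(h), so the cache stores only n-vectors
of diagonal weights and the whole sampler runs vectorized in the rotated
basis; in the general case a Cholesky factor of Σ(h), the random-effect
cross-covariance block, and a symmetric square root of the joint
conditional covariance of the stacked random effects are cached per point
(memory ~ P(n^2 + r^2), checked against a configurable cap, default 2 GiB;
this is why models are refused above 10,000 observations or 4 random-effect
terms unless explicitly overridden).

## Priors

* **sigma2_j ~ InvGamma(shape 3, rate 2)** (mean 1, finite variance).
  Traits are standardized to unit variance by default before fitting (all
  posterior functionals are back-transformed through the recorded per-trait
  mean and scale), so this is weakly informative around the data scale.
  Standardization can be switched off for data already on a common scale.
* **Grid points: uniform prior weights** unless overridden.
* **Loadings: two-dimensional global-local shrinkage.**  Element (k, j) has
  lambda_kj ~ N(0, tau^2 gamma_k phi2_kj) with
  - *local scales* phi_kj ~ half-Cauchy(0, 1), implemented through the
    inverse-gamma auxiliary representation (phi2 | nu ~ IG(1/2, 1/nu),
    nu ~ IG(1, 1/2-style conditionals), keeping every update conjugate and
    tuning-free;
  - *factor scales* gamma_k = prod_{l<=k} delta_l^-1 with
    delta_1 ~ Gamma(2, 1) and delta_l ~ Gamma(3, 1) for l >= 2, a
    multiplicative sequence that makes shrinkage stochastically increase
    with the factor index.  Factors are thereby ordered from most to least
    important by the prior rather than by a hard constraint, so the choice
    of K only needs to be "large enough" (default K = min(n/4, t/2),
    clipped to at least 1), and surplus factors are shrunk away instead of
    over-fitting;
  - a *fixed global scale* tau calibrated to a target effective number of
    non-zero coefficients: with shrinkage weight
    kappa = 1/(1 + n tau^2 gamma_k phi^2) and phi half-Cauchy,
    E[1 - kappa] = sqrt(a)/(1 + sqrt(a)) with a = n tau^2 gamma_k, so tau
    solves t Σ_k E_gamma[sqrt(a_k)/(1+sqrt(a_k))] = p0 (the expectation
    over the delta sequence is averaged over a fixed Monte-Carlo panel and
    tau found by bisection).  Default target fraction p0/(K t) = 0.1.
  Proper-prior fixed-effect coefficients (B2R, B2F) carry analogous
  element-wise horseshoe scales (B2F columns additionally share the factor
  multipliers gamma_k).

The defaults above are this package's own calibration for unit-scale
traits; all are overridable through the `hyper` mapping and are echoed to
the log at fit time.

## The Gibbs sweep

Fixed order, one sweep =

1. **variance proportions** — for every trait and factor column
   independently, an exact draw from the discrete posterior over grid
   points proportional to prior weight x marginal likelihood with the
   random effects integrated out analytically (collapsed update; the
   integrated effects are redrawn in the next step, which keeps the sweep a
   valid partially collapsed Gibbs sampler).  Normalization happens in log
   space and the categorical draw uses the Gumbel-max trick, so underflow
   cannot occur.
2. **location effects** — per column, B is drawn from its Gaussian
   conditional with the random effects marginalized (flat priors on B1,
   shrinkage priors on B2), then the stacked random effects from their
   exact joint conditional given B, via the cached factorizations.
3. **factor scores** — all n rows of F share one K x K conditional
   precision Λ Ψ_RE^-1 Λ' + Ψ_FE^-1, so a single Cholesky serves every row.
4. **loadings** — per trait, a K-dimensional ridge-form conditional with
   element-wise prior precisions.
5. **shrinkage scales** — conjugate inverse-gamma updates of phi2 and nu,
   then Gamma updates of the multiplicative delta sequence.
6. **residual variances** — inverse-gamma update of sigma2_j combining the
   level-1 residual sum of squares with the random-effect quadratic forms
   u'(h_m K_m)^+ u over the positive spectrum of each K_m (pseudo-inverse,
   so PSD kinships with rank deficiency are handled exactly).
7. **missing values** — every masked cell is redrawn from
   N(model mean, Ψ_RE of its trait).  Plain data augmentation: all other
   steps then treat Y as complete.  This trades the per-dataset
   missing-data marginalizations that are possible for special patterns for
   correctness under arbitrary patterns; trait partitions by missingness
   pattern are still computed (and capped at 20, merging the smallest
   patterns under their union pattern) as bookkeeping for I/O and
   diagnostics.

No step forms or inverts a t x t matrix; the largest per-trait dense solve
has dimension max(K, b), which the sampler records at run time and the test
suite asserts.  Per-sweep cost is linear in t at fixed n and K.

(F, Λ) is sign/rotation non-identified; by default only rotation-invariant
functionals (G_m, R, genetic values U_Rm + U_Fm Λ, imputations
X1 B1 + F Λ + Z U_R) are stored, back-transformed to the original trait
scale.  Raw Λ storage is opt-in and warns.  Run lengths default to 7000
iterations, 5000 burn-in, thinning 2; one counter-based RNG stream per
chain, seed recorded in the output.  Optional factor pruning during burn-in
removes factors whose share of Σ_j lambda_kj^2 falls below a threshold
(never below one factor) and re-indexes survivors by importance.

A "getting-it-right" (successive-conditional/Geweke) test validates the
whole sweep: iterating {one sweep; redraw Y | parameters} must leave the
prior invariant, and the test compares ~36 monitored moments against direct
prior simulation at n=20, t=3, K=2.  Monitors are chosen light-tailed —
grid proportions, bounded transforms of sigma2 and phi2, the delta
sequence, B1, and loadings on the shrinkage-normalized scale
lambda/sqrt(prior variance), which is exactly standard normal under the
prior.  Raw horseshoe loadings are deliberately not monitored through their
moments: the mean of any tail-sensitive functional of a half-Cauchy-scaled
coefficient is dominated by rare, persistent excursions, so its
Monte-Carlo error cannot be estimated reliably at any feasible chain
length (this is a property of the monitor, not of the sampler).

## Predictions, summaries, diagnostics

* **Genetic values** per term: u_m = U_Rm + U_Fm Λ, per draw.
* **Imputed phenotypes**: X1 B1 (+ X2 B2R) + F Λ + Z U_R, per draw — the
  model's smoothed value, also defined at observed cells.
* **New (unphenotyped, un-fitted) lines**: conditional-Gaussian
  extrapolation u_new = K_no K_oo^-1 u_old per draw, with the K_oo inverse
  ridge-stabilized by 1e-8 tr(K_oo)/n_o (kinships from few markers can be
  near-singular).
* **Summaries**: posterior mean, SD, and highest-posterior-density
  intervals computed by the shortest-window scan over sorted draws.
  Genetic correlations should be reported as posterior means of per-draw
  correlations (not correlations of posterior means); both are computable
  from the stored G draws.
* **ESS**: rank-normalized split-chain bulk effective sample size
  (delegated to `arviz.ess`); constant chains are reported as undefined,
  and fit summaries flag elements below the conventional target of 1000.

## Kernels

VanRaden kinship K = WW'/(2 Σ p_j(1-p_j)) from column-centered 0/1/2
dosages (markers above 50% missing dropped, the rest mean-imputed,
monomorphic markers removed); a centered-IBS-style variant normalized so
the mean diagonal equals 1 (proportional to VanRaden up to the scalar);
secondary-trait kernels H = SS'/q from centered, standardized trait BLUEs;
and Gaussian kernels exp(-h D_ij / dbar) from a squared-distance matrix
standardized by its mean off-diagonal entry, with default bandwidths
{1/5, 1, 5} for kernel averaging via multiple random-effect terms.  The
distance standardization convention (mean off-diagonal) is documented here
because other conventions exist; users can rescale D to reproduce them.

## Baselines and the accuracy metric

`reml_univariate` maximizes the restricted likelihood of the single-kernel
LMM by bounded 1-D optimization over h2 in the eigenbasis of the observed
kinship block, with the total variance profiled out; h2 = 0 is a valid
boundary result, and a likelihood flat in h2 (e.g. K = I) is flagged
non-identifiable.  `multi_kernel_blup` extends this to several kernels by
Nelder-Mead over a softmax parameterization of the variance-proportion
simplex and forms out-of-sample predictions as Σ_m K_m,no K_m,oo^-1 û_m.

Prediction accuracy for genetic values is estimated as

    rho_g = cor_g(û, y) sqrt(h2(û)),

with h2(û) from a univariate REML fit of the predictor and cor_g estimated
in the testing lines only, via the pairwise variance decomposition of û, y,
and û + y (cov_g = [Vg(û+y) - Vg(û) - Vg(y)]/2).  Both series are
standardized within the testing block first, which makes the estimator
exactly invariant to affine rescaling of the predictor.  This pairwise-REML
convention is one defensible estimator of cor_g among several; Pearson's
correlation is also offered conceptually for designs where testing units
share no plots with secondary traits (no non-genetic correlation pathway),
as in multi-environment imputation, and is what the CV reports use there.
Degenerate cases (constant predictor, zero or non-identifiable
heritability, non-positive genetic variances in the test block) return
accuracy 0 with a warning rather than an error.

## Synthetic data

The generator produces data with exactly the structure the model assumes,
in two flavors:

* `simulate_from_covariances`: Y = U + E with U ~ MN(0, K, G),
  E ~ MN(0, I, R).  When G and R are supplied as correlation matrices they
  are converted to covariances by per-trait heritabilities drawn uniformly
  in [0.1, 0.8] (unit total variance per trait); a degenerate range such as
  (0.5, 0.5) pins heritability exactly.
* `simulate_factor_truth`: the generative direction of the factor model —
  sparse loadings (default half the entries exactly zero) with row scales
  decaying geometrically (factor k scaled 0.85^k), per-factor variance
  proportions drawn uniformly in [0.1, 0.8], idiosyncratic per-trait
  heritabilities likewise, and the implied G_m, R, genetic values, and
  loadings recorded as ground truth via the same assembly identities the
  model uses.

The default simulated kinship is the VanRaden matrix of 500 iid
Binomial(2, 0.3) markers, which gives realistic eigenvalue decay and
realistically weak relatedness contrast: at a few hundred lines,
single-trait heritability estimates on half-panels are highly variable and
can hit the h2 = 0 boundary, which is visible in the worked example and in
the spread of per-replicate CV2 accuracies.  Cross-validation scenarios
implement CV2 (focal trait partially masked, secondary traits complete) and
CV1 (testing units entirely unphenotyped).

What these simulations do *not* emulate: empirical covariance structure of
real expression panels or hyperspectral bands (exchangeable/block
correlations are stand-ins with the same role; user-supplied G and R are
accepted for realism), linkage disequilibrium and population structure in
the markers, spatial field trends, and non-Gaussian measurement error.
Passing the recovery and prediction checks therefore demonstrates
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

## Validation-study problem sizes

The shipped checks use desk-scale replicas of the method's operating
regime, chosen to exercise every code path while keeping a full validation
run in the minutes range: covariance assembly against 1e5 Monte-Carlo
draws; grid-posterior exactness at n = 40 (and a two-term grouped-incidence
instance); single-trait reduction at n = 200, h2 = 0.5 with a 0.02 grid and
30k sweeps, averaged over three data replicates; the joint-distribution
check at n = 20, t = 3, K = 2 with 40k sweeps against 5000 prior draws
(|z| < 4 on all monitors); covariance recovery at n = 300, t = 20,
K_true = 5; the CV2 comparison at n = 400 with 50 secondary traits at
genetic correlation 0.8 and h2 = 0.5, 20 replicates; and factor-count
robustness (K_true vs 2 K_true) over 6 paired replicates.

## Numerical choices and edge cases

* Eigenvalues of relationship matrices are clipped at zero within a
  tolerance of 1e-8 x max eigenvalue; anything below is a hard non-PSD
  error.
* Grid-point simplex sums stay <= 1 - step, so factor residual variances
  never vanish; trait-level residual variances are strictly positive by the
  inverse-gamma draw.
* The single-trait reduction check compares a posterior mean against a REML
  point estimate; the residual few-percent discrepancy is the genuine
  Bayes-vs-REML estimator difference at n = 200 (posterior-mean h2 vs the
  restricted-likelihood maximizer), not sampler error — against the exact
  numerically integrated posterior the sampler agrees to well under the
  grid discretization scale.
* Missing tokens in delimited phenotype files: empty string, "NA", "NaN"
  (case-insensitive).  Duplicate unit ids and non-numeric non-missing cells
  are errors; fully missing traits are retained with a warning.
* Standardization uses the observed cells only (ddof = 1) and refuses
  constant traits by name.

## Known limitations

Linear-Gaussian only; no environmental-covariate regression on loadings;
no marker-effect (Bayesian-alphabet) priors; single-chain diagnostics (ESS,
no cross-chain R-hat); memory grows quadratically in n and combinatorially
in the number of random-effect terms through the grid cache, hence the
default caps; and the factor representation is inefficient for covariance
structures that are not approximately low-rank (e.g. autoregressive bands).
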