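"""Blocked/collapsed Gibbs sampler for the mixed-effect factor model.

The model for an ``n x t`` trait matrix Y is

    Y = F Lambda + X1 B1 + X2 B2R + sum_m Z_m U_Rm + E_R
    F = X2 B2F + sum_m Z_m U_Fm + E_F

with ``U_Rm ~ MN(0, K_m, Psi_Rm)``, ``U_Fm ~ MN(0, K_m, Psi_Fm)``,
``E_R ~ MN(0, I, Psi_RE)``, ``E_F ~ MN(0, I, Psi_FE)``, all Psi diagonal.
Conditional on (F, Lambda) the t trait columns decouple into independent
univariate LMMs, and the K factor columns decouple likewise, so no step ever
forms or inverts a t x t matrix: the largest per-trait solve is of dimension
max(K, b) (plus O(n) diagonal or cached-Cholesky work for the
random-effect conditionals).

Variance components are parameterized as proportions on a discrete grid:
trait column j has a sampled total scale sigma2_j with
``Psi_Rm[j] = sigma2_j h_mj`` and ``Psi_RE[j] = sigma2_j (1 - sum_m h_mj)``;
factor k has total variance fixed at 1 (the F/Lambda scale is otherwise
unidentified) with ``Psi_Fm[k] = h_mk`` and ``Psi_FE[k] = 1 - sum_m h_mk``.
The grid update is collapsed: the discrete posterior over grid points is
computed with the random effects integrated out analytically, using the
cached factorizations, and the random effects are redrawn immediately
afterwards.

Missing cells are handled by data augmentation: every masked cell is redrawn
each sweep from its Gaussian conditional, so all other updates can treat Y
as complete.  The sweep order is fixed for reproducibility:

    variance proportions -> location effects -> factor scores -> loadings
    -> shrinkage scales -> residual variances -> missing values
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .data_model import ModelSpec, ScalingRecord, TraitMatrix, partition_traits, center_scale
from .posterior import PosteriorSamples
from . import priors
from .priors import (
    VarianceGrid,
    build_variance_grid,
    cache_grid_factorizations,
    default_grid_step,
    init_shrinkage_state,
    resolve_hypers,
    update_local_scales,
    update_delta,
)

__all__ = [
    "ModelState",
    "MCMCConfig",
    "initialize_state",
    "gibbs_sweep",
    "sample_variance_proportions",
    "sample_location_effects",
    "sample_factor_scores",
    "sample_loadings",
    "sample_shrinkage",
    "sample_residual_variances",
    "sample_missing_values",
    "prune_factors",
    "run_mcmc",
    "grid_log_posterior",
    "prior_draw_state",
    "draw_data",
]

#: refuse larger problems unless explicitly overridden: the grid cache's
#: memory grows quadratically in n and exponentially in the number of terms.
MAX_OBSERVATIONS = 10_000
MAX_TERMS = 4


@dataclass
class MCMCConfig:
    """Run-length and bookkeeping configuration for :func:`run_mcmc`."""

    iterations: int = 7000
    burnin: int = 5000
    thin: int = 2
    seed: int = 0
    functionals: tuple[str, ...] = ("G", "R", "genetic_values", "imputed")
    standardize: bool = True
    store_lambda: bool = False
    prune_threshold: float | None = None
    prune_every: int = 100
    allow_large: bool = False

    def n_stored(self) -> int:
        if self.iterations < self.burnin:
            raise ValueError("iterations must be >= burnin")
        return math.ceil((self.iterations - self.burnin) / self.thin)


@dataclass
class ModelState:
    """One Gibbs configuration of the mixed-effect factor model."""

    tm: TraitMatrix
    spec: ModelSpec
    grid: VarianceGrid
    Y_orig: np.ndarray  # n x t, original basis, masked cells hold current imputations
    Yw: np.ndarray  # n x t, working basis
    X1w: np.ndarray
    X2w: np.ndarray
    F: np.ndarray  # n x K (working basis)
    Lambda: np.ndarray  # K x t
    B1: np.ndarray  # b1 x t
    B2R: np.ndarray  # b2 x t
    B2F: np.ndarray  # b2 x K
    U_R: np.ndarray  # r_tot x t (working basis)
    U_F: np.ndarray  # r_tot x K (working basis)
    sigma2: np.ndarray  # (t,)
    gi_traits: np.ndarray  # (t,) grid-point indices
    gi_factors: np.ndarray  # (K,)
    shrinkage: priors.ShrinkagePriorState
    rng: np.random.Generator
    max_solve_dims: dict = field(default_factory=dict)

    # --- derived quantities ------------------------------------------------
    @property
    def cache(self):
        return self.grid.cache

    @property
    def n(self) -> int:
        return self.Yw.shape[0]

    @property
    def t(self) -> int:
        return self.Yw.shape[1]

    @property
    def K(self) -> int:
        return self.F.shape[1]

    @property
    def h_traits(self) -> np.ndarray:
        """(t, M) variance proportions per trait."""
        return self.grid.points[self.gi_traits]

    @property
    def h_factors(self) -> np.ndarray:
        """(K, M) variance proportions per factor."""
        return self.grid.points[self.gi_factors]

    @property
    def psi_RE(self) -> np.ndarray:
        """Level-1 residual variances, ``sigma2_j (1 - sum_m h_mj)``."""
        return self.sigma2 * (1.0 - self.h_traits.sum(axis=1))

    @property
    def psi_FE(self) -> np.ndarray:
        """Factor residual variances, ``1 - sum_m h_mk``."""
        return 1.0 - self.h_factors.sum(axis=1)

    def psi_R(self, m: int) -> np.ndarray:
        """Per-term trait random-effect variances, ``sigma2_j h_mj``."""
        return self.sigma2 * self.h_traits[:, m]

    def psi_F(self, m: int) -> np.ndarray:
        """Per-term factor random-effect variances, ``h_mk``."""
        return self.h_factors[:, m]

    def Zu_R(self) -> np.ndarray:
        """sum_m Z_m U_Rm mapped to the observation rows (working basis)."""
        return self.U_R if self.cache.is_spectral else self.cache.Zu(self.U_R)

    def Zu_F(self) -> np.ndarray:
        return self.U_F if self.cache.is_spectral else self.cache.Zu(self.U_F)

    def term_slices(self) -> list[slice]:
        offs = np.concatenate([[0], np.cumsum(self.cache.r_tots)])
        return [slice(offs[m], offs[m + 1]) for m in range(len(self.cache.r_tots))]

    def mean_w(self) -> np.ndarray:
        """Model mean of Y in the working basis (excluding E_R)."""
        out = self.X1w @ self.B1 + self.Zu_R()
        if self.K:
            out += self.F @ self.Lambda
        if self.spec.b2:
            out += self.X2w @ self.B2R
        return out

    def record_solve(self, block: str, dim: int) -> None:
        self.max_solve_dims[block] = max(self.max_solve_dims.get(block, 0), dim)

    @property
    def max_per_trait_solve(self) -> int:
        """Largest per-trait/per-factor dense solve performed so far."""
        keys = ("location_B", "loadings", "factor_scores")
        return max((self.max_solve_dims.get(k, 0) for k in keys), default=0)


def _assert_finite(arr: np.ndarray, block: str, iteration: int | None = None) -> None:
    if not np.all(np.isfinite(arr)):
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(f"non-finite state in block '{block}'{where}")


# ---------------------------------------------------------------------------
# initialization


def initialize_state(
    tm: TraitMatrix,
    spec: ModelSpec,
    seed: int | np.random.Generator = 0,
    grid: VarianceGrid | None = None,
    allow_large: bool = False,
) -> ModelState:
    """Deterministic starting configuration.

    F starts at the top-K principal components of the observed-data-imputed
    Y (so F Lambda equals the rank-K SVD truncation), variances at
    method-of-moments values, grid indices at the point closest to an even
    variance split, and shrinkage scales at their prior means.
    """
    n, t = tm.n, tm.t
    spec.resolve(n)
    if not allow_large and (n > MAX_OBSERVATIONS or spec.M > MAX_TERMS):
        raise ValueError(
            f"model with n={n}, M={spec.M} exceeds the default caps "
            f"(n <= {MAX_OBSERVATIONS}, M <= {MAX_TERMS}); pass allow_large=True "
            "to override"
        )
    K = spec.K
    if K > n:
        raise ValueError("K <= n required for initialization")
    hyper = resolve_hypers(spec.hyper)
    if grid is None:
        step = spec.hyper.get("grid_step") or default_grid_step(spec.M)
        grid = build_variance_grid(spec.M, step)
    if grid.cache is None:
        cache_grid_factorizations(grid, spec.terms, n)
    cache = grid.cache

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # observed-data imputation: masked cells at the trait's observed mean
    Y0 = np.array(tm.values, dtype=float)
    for j in range(t):
        obs = tm.mask[:, j]
        mu = float(Y0[obs, j].mean()) if obs.any() else 0.0
        Y0[~obs, j] = mu
    Yw = cache.to_working(Y0)
    X1w = cache.to_working(spec.X1)
    X2w = cache.to_working(spec.X2) if spec.b2 else np.zeros((n, 0))

    B1, *_ = np.linalg.lstsq(X1w, Yw, rcond=None)
    resid = Yw - X1w @ B1
    if K > 0:
        U_svd, s, Vt = np.linalg.svd(resid, full_matrices=False)
        F = U_svd[:, :K] * np.sqrt(n)
        Lambda = (s[:K, None] * Vt[:K]) / np.sqrt(n)
    else:
        F = np.zeros((n, 0))
        Lambda = np.zeros((0, t))
    resid2 = resid - F @ Lambda
    sigma2 = np.maximum(resid2.var(axis=0), 0.02)

    target = np.full(grid.M, 0.5 / grid.M)
    g0 = int(np.argmin(np.sum((grid.points - target) ** 2, axis=1)))
    r_tot = sum(cache.r_tots)

    state = ModelState(
        tm=tm,
        spec=spec,
        grid=grid,
        Y_orig=Y0,
        Yw=Yw,
        X1w=X1w,
        X2w=X2w,
        F=F,
        Lambda=Lambda,
        B1=B1,
        B2R=np.zeros((spec.b2, t)),
        B2F=np.zeros((spec.b2, K)),
        U_R=np.zeros((r_tot, t)),
        U_F=np.zeros((r_tot, K)),
        sigma2=sigma2,
        gi_traits=np.full(t, g0, dtype=int),
        gi_factors=np.full(K, g0, dtype=int),
        shrinkage=init_shrinkage_state(K, t, hyper, n_units=n, b2=spec.b2),
        rng=rng,
    )
    return state


# ---------------------------------------------------------------------------
# Gibbs steps


def grid_log_posterior(state: ModelState, kind: str = "traits") -> np.ndarray:
    """Normalized log posterior over grid points for each column.

    For traits the marginal likelihood integrates the random effects out of
    ``y_j - F lambda_j - X1 B1_j - X2 B2R_j ~ N(0, sigma2_j Sigma(h))``; for
    factors, of ``f_k - X2 B2F_k ~ N(0, Sigma(h))``.  Returns a (P, ncol)
    array of log probabilities summing (in exp) to 1 per column.
    """
    cache = state.cache
    if kind == "traits":
        R = state.Yw - state.X1w @ state.B1
        if state.K:
            R = R - state.F @ state.Lambda
        if state.spec.b2:
            R = R - state.X2w @ state.B2R
        scale = state.sigma2
    elif kind == "factors":
        if state.K == 0:
            return np.zeros((state.grid.P, 0))
        R = state.F - (state.X2w @ state.B2F if state.spec.b2 else 0.0)
        scale = np.ones(state.K)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    quad = cache.quad_all(R)  # (P, ncol)
    logdets = np.array([cache.logdet(g) for g in range(state.grid.P)])
    logw = (
        np.log(state.grid.prior_weights)[:, None]
        - 0.5 * logdets[:, None]
        - 0.5 * quad / scale[None, :]
    )
    return logw - _logsumexp0(logw)


def _logsumexp0(logw: np.ndarray) -> np.ndarray:
    m = logw.max(axis=0, keepdims=True)
    return m + np.log(np.exp(logw - m).sum(axis=0, keepdims=True))


def sample_variance_proportions(state: ModelState) -> ModelState:
    """Collapsed grid update: exact discrete posterior per trait and factor.

    Never errors on underflow: weights are normalized in log space and the
    categorical draw uses the Gumbel-max trick.
    """
    rng = state.rng
    logp = grid_log_posterior(state, "traits")
    gumb = rng.gumbel(size=logp.shape)
    state.gi_traits = np.argmax(logp + gumb, axis=0)
    if state.K:
        logp_f = grid_log_posterior(state, "factors")
        gumb_f = rng.gumbel(size=logp_f.shape)
        state.gi_factors = np.argmax(logp_f + gumb_f, axis=0)
    return state


def _draw_coefficients(
    state: ModelState,
    Xw: np.ndarray,
    T: np.ndarray,
    gidx: np.ndarray,
    scale: np.ndarray,
    prior_prec: np.ndarray,
    block: str,
) -> np.ndarray:
    """Joint Gaussian draw of regression coefficients per column, with the
    random effects integrated out (marginal covariance ``scale * Sigma(h)``)."""
    b = Xw.shape[1]
    ncol = T.shape[1]
    B = np.zeros((b, ncol))
    if b == 0:
        return B
    rng = state.rng
    for g in np.unique(gidx):
        cols = np.where(gidx == g)[0]
        SX = state.cache.solve_w(g, Xw)  # Sigma^-1 X
        XtSiX = Xw.T @ SX
        XtSiT = SX.T @ T[:, cols]
        for i, j in enumerate(cols):
            prec = XtSiX / scale[j] + np.diag(prior_prec[:, j])
            L = np.linalg.cholesky(prec)
            state.record_solve(block, b)
            mean = sla.cho_solve((L, True), XtSiT[:, i] / scale[j])
            z = rng.standard_normal(b)
            B[:, j] = mean + sla.solve_triangular(L, z, trans="T", lower=True)
    return B


def sample_location_effects(state: ModelState) -> ModelState:
    """Draw (B, U) jointly per trait column and per factor column.

    B is drawn from its conditional with the random effects integrated out
    (flat priors on B1 columns, shrinkage priors on B2 columns), then the
    stacked random effects from their exact joint conditional given B, using
    the cached factorization at each column's current grid point.
    """
    spec = state.spec
    rng = state.rng
    b1, b2 = spec.b1, spec.b2
    Xw = np.hstack([state.X1w, state.X2w]) if b2 else state.X1w
    T = state.Yw - (state.F @ state.Lambda if state.K else 0.0)
    vb = state.shrinkage.hyper["fixed_prior_variance"]
    prior_prec = np.zeros((b1 + b2, state.t))
    if np.isfinite(vb):
        prior_prec[:b1] = 1.0 / vb
    if b2:
        prior_prec[b1:] = 1.0 / state.shrinkage.b2r_prior_var()
    B = _draw_coefficients(state, Xw, T, state.gi_traits, state.sigma2, prior_prec, "location_B")
    state.B1 = B[:b1]
    if b2:
        state.B2R = B[b1:]
    resid = T - Xw @ B
    state.U_R = state.cache.sample_u_cols(resid, state.gi_traits, state.sigma2, rng)

    if state.K:
        ones = np.ones(state.K)
        if b2:
            prior_prec_f = 1.0 / state.shrinkage.b2f_prior_var()
            state.B2F = _draw_coefficients(
                state, state.X2w, state.F, state.gi_factors, ones, prior_prec_f, "location_B"
            )
            residF = state.F - state.X2w @ state.B2F
        else:
            residF = state.F
        state.U_F = state.cache.sample_u_cols(residF, state.gi_factors, ones, rng)
    return state


def sample_factor_scores(state: ModelState) -> ModelState:
    """Draw all rows of F from their shared-precision Gaussian conditional.

    Each row combines the data term (through Lambda and the per-trait
    residual precisions) with the row's level-2 prior mean
    ``(X2 B2F + Z U_F)_i`` and residual precision ``1/Psi_FE``; the K x K
    conditional precision is the same for every row, so one Cholesky serves
    all n rows.
    """
    if state.K == 0:
        return state
    rng = state.rng
    psi_RE = state.psi_RE
    pvF = state.psi_FE
    Mprior = state.Zu_F() + (state.X2w @ state.B2F if state.spec.b2 else 0.0)
    R = state.Yw - state.X1w @ state.B1 - state.Zu_R()
    if state.spec.b2:
        R = R - state.X2w @ state.B2R
    P = (state.Lambda / psi_RE[None, :]) @ state.Lambda.T + np.diag(1.0 / pvF)
    L = np.linalg.cholesky(P)
    state.record_solve("factor_scores", state.K)
    RHS = (R / psi_RE[None, :]) @ state.Lambda.T + Mprior / pvF[None, :]
    mean = sla.cho_solve((L, True), RHS.T).T
    z = rng.standard_normal((state.n, state.K))
    state.F = mean + sla.solve_triangular(L, z.T, trans="T", lower=True).T
    return state


def sample_loadings(state: ModelState) -> ModelState:
    """Draw each trait's loading column from its ridge-form conditional.

    Conditional mean is ``(F'F + Psi_RE_j P_j)^-1 F' y*_j`` with per-element
    prior precisions ``P_j`` from the shrinkage state.
    """
    if state.K == 0:
        return state
    rng = state.rng
    psi_RE = state.psi_RE
    W = state.Yw - state.X1w @ state.B1 - state.Zu_R()
    if state.spec.b2:
        W = W - state.X2w @ state.B2R
    FtF = state.F.T @ state.F
    FtW = state.F.T @ W
    pv = state.shrinkage.lambda_prior_var()
    Lambda = np.empty_like(state.Lambda)
    for j in range(state.t):
        prec = FtF / psi_RE[j] + np.diag(1.0 / pv[:, j])
        if not np.all(np.isfinite(prec)):
            raise FloatingPointError("singular/non-finite loading conditional precision")
        L = np.linalg.cholesky(prec)
        state.record_solve("loadings", state.K)
        mean = sla.cho_solve((L, True), FtW[:, j] / psi_RE[j])
        z = rng.standard_normal(state.K)
        Lambda[:, j] = mean + sla.solve_triangular(L, z, trans="T", lower=True)
    state.Lambda = Lambda
    return state


def sample_shrinkage(state: ModelState) -> ModelState:
    """Conjugate updates of local scales, auxiliaries, and factor multipliers."""
    sh = state.shrinkage
    rng = state.rng
    if state.K:
        nonlocal_var = sh.tau2_lambda * sh.gamma[:, None]
        sh.lam_phi2, sh.lam_nu = update_local_scales(
            sh.lam_phi2, sh.lam_nu, state.Lambda, nonlocal_var, rng
        )
    if state.spec.b2:
        sh.b2r_phi2, sh.b2r_nu = update_local_scales(
            sh.b2r_phi2, sh.b2r_nu, state.B2R, sh.tau2_b2, rng
        )
        if state.K:
            sh.b2f_phi2, sh.b2f_nu = update_local_scales(
                sh.b2f_phi2, sh.b2f_nu, state.B2F, sh.tau2_b2 * sh.gamma[None, :], rng
            )
    if state.K:
        update_delta(sh, state.Lambda, rng, state.B2F if state.spec.b2 else None)
    return state


def sample_residual_variances(state: ModelState) -> ModelState:
    """Inverse-gamma update of each trait's total variance scale sigma2_j.

    The conditional combines the level-1 residual sum of squares (precision
    ``1/(sigma2 (1 - sum h))``) with the random-effect quadratic forms
    ``u' (h_m K_m)^+ u / sigma2`` over the positive spectrum of each K_m;
    positivity is automatic.
    """
    hyper = state.shrinkage.hyper
    a0, b0 = hyper["sigma2_shape"], hyper["sigma2_rate"]
    resid = state.Yw - state.mean_w()
    SSe = np.sum(resid**2, axis=0)
    resid_prop = 1.0 - state.h_traits.sum(axis=1)
    quad_u, dof = state.cache.u_quad_dof(state.U_R, state.gi_traits)
    shape = a0 + 0.5 * (state.n + dof)
    rate = b0 + 0.5 * (SSe / resid_prop + quad_u)
    state.sigma2 = rate / state.rng.gamma(shape, 1.0)
    return state


def sample_missing_values(state: ModelState) -> TraitMatrix:
    """Redraw every masked cell from N(model mean, Psi_RE of its trait)."""
    mask = state.tm.mask
    if mask.all():
        return state.tm
    miss = ~mask
    mean_orig = state.cache.from_working(state.mean_w())
    sd = np.sqrt(state.psi_RE)
    noise = state.rng.standard_normal(int(miss.sum()))
    rows, cols = np.where(miss)
    state.Y_orig[rows, cols] = mean_orig[rows, cols] + sd[cols] * noise
    state.Yw = state.cache.to_working(state.Y_orig)
    state.tm.values[rows, cols] = state.Y_orig[rows, cols]
    return state.tm


def prune_factors(state: ModelState, threshold: float = 0.005) -> ModelState:
    """Drop factors contributing a negligible share of explained variance.

    A factor's share is ``sum_j lambda_kj^2`` over the total across factors
    (factor variances are fixed at 1).  Intended for the burn-in phase; at
    least one factor is kept while any remains, and survivors are re-indexed
    by decreasing share.
    """
    if state.K == 0:
        return state
    v = np.sum(state.Lambda**2, axis=1)
    total = v.sum()
    if total <= 0:
        keep = np.array([0])
    else:
        share = v / total
        keep = np.where(share >= threshold)[0]
        if len(keep) == 0:
            keep = np.array([int(np.argmax(share))])
        keep = keep[np.argsort(-share[keep], kind="stable")]
    if len(keep) == state.K and np.array_equal(keep, np.arange(state.K)):
        return state
    sh = state.shrinkage
    gamma_kept = sh.gamma[keep]
    state.F = state.F[:, keep]
    state.Lambda = state.Lambda[keep]
    state.U_F = state.U_F[:, keep]
    state.B2F = state.B2F[:, keep] if state.spec.b2 else np.zeros((0, len(keep)))
    state.gi_factors = state.gi_factors[keep]
    sh.lam_phi2 = sh.lam_phi2[keep]
    sh.lam_nu = sh.lam_nu[keep]
    if sh.b2f_phi2 is not None:
        sh.b2f_phi2 = sh.b2f_phi2[:, keep]
        sh.b2f_nu = sh.b2f_nu[:, keep]
    # rebuild the multiplicative sequence so gamma values carry over
    new_delta = np.empty(len(keep))
    prev = 1.0
    for i, g in enumerate(gamma_kept):
        new_delta[i] = prev / g
        prev = g
    sh.delta = new_delta
    sh.K = len(keep)
    state.spec.K = len(keep)
    return state


def gibbs_sweep(state: ModelState, iteration: int | None = None) -> ModelState:
    """One full sweep in the documented fixed order."""
    sample_variance_proportions(state)
    sample_location_effects(state)
    _assert_finite(state.U_R, "location_effects", iteration)
    sample_factor_scores(state)
    _assert_finite(state.F, "factor_scores", iteration)
    sample_loadings(state)
    _assert_finite(state.Lambda, "loadings", iteration)
    sample_shrinkage(state)
    sample_residual_variances(state)
    _assert_finite(state.sigma2, "residual_variances", iteration)
    sample_missing_values(state)
    return state


# ---------------------------------------------------------------------------
# functionals and the main loop


def _genetic_values_draw(state: ModelState, m: int = 0) -> np.ndarray:
    """Per-draw genetic values for term m, in the original (line) basis."""
    sl = state.term_slices()[m]
    U = state.U_R[sl] + state.U_F[sl] @ state.Lambda if state.K else state.U_R[sl]
    if state.cache.is_spectral:
        U = state.cache.from_working(U)
    return U


def _G_draw(state: ModelState, m: int) -> np.ndarray:
    from .posterior import assemble_genetic_covariance

    return assemble_genetic_covariance(state, m)


def _R_draw(state: ModelState) -> np.ndarray:
    from .posterior import assemble_residual_covariance

    return assemble_residual_covariance(state)


def _imputed_draw(state: ModelState) -> np.ndarray:
    from .posterior import impute_phenotypes

    return impute_phenotypes(state)


def run_mcmc(tm: TraitMatrix, spec: ModelSpec, config: MCMCConfig) -> PosteriorSamples:
    """Fit the model by Gibbs sampling and collect posterior functionals.

    Deterministic given ``config.seed``; stores exactly
    ``ceil((iterations - burnin)/thin)`` thinned draws of each requested
    functional, back-transformed to the original trait scale when the data
    were standardized.
    """
    n_stored = config.n_stored()
    if config.standardize:
        tm_fit, scaling = center_scale(tm)
    else:
        tm_fit, scaling = tm.copy(), ScalingRecord.identity(tm.trait_ids)
    if not tm_fit.partitions:
        tm_fit = partition_traits(tm_fit)
    if spec.K is None:
        spec.K = priors.default_num_factors(tm.n, tm.t)
    state = initialize_state(tm_fit, spec, seed=config.seed, allow_large=config.allow_large)

    known = {"G", "R", "genetic_values", "imputed", "sigma2", "h_traits", "Lambda"}
    req = list(config.functionals)
    if config.store_lambda and "Lambda" not in req:
        req.append("Lambda")
    unknown = set(req) - known
    if unknown:
        raise ValueError(f"unknown functionals: {sorted(unknown)}; known: {sorted(known)}")
    if "Lambda" in req:
        import warnings

        warnings.warn(
            "raw loadings are stored; (F, Lambda) is sign/rotation non-identified, "
            "prefer rotation-invariant functionals (G, R, genetic values, imputations)"
        )

    draws: dict[str, list] = {name: [] for name in req}
    stored = 0
    for it in range(config.iterations):
        gibbs_sweep(state, iteration=it)
        if (
            config.prune_threshold is not None
            and it < config.burnin
            and it > 0
            and it % config.prune_every == 0
        ):
            prune_factors(state, config.prune_threshold)
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            for name in req:
                if name == "G":
                    val = np.stack(
                        [scaling.inverse_covariance(_G_draw(state, m)) for m in range(spec.M)]
                    )
                elif name == "R":
                    val = scaling.inverse_covariance(_R_draw(state))
                elif name == "genetic_values":
                    val = scaling.inverse_spread(_genetic_values_draw(state, 0))
                elif name == "imputed":
                    val = scaling.inverse_values(_imputed_draw(state))
                elif name == "sigma2":
                    val = state.sigma2.copy()
                elif name == "h_traits":
                    val = state.h_traits.copy()
                elif name == "Lambda":
                    val = state.Lambda.copy()
                draws[name].append(val)
            stored += 1
    assert stored == n_stored, "stored draw count mismatch"
    arrays = {
        k: (np.stack(v) if v else np.zeros((0,))) for k, v in draws.items()
    }
    return PosteriorSamples(
        draws=arrays,
        unit_ids=list(tm.unit_ids),
        trait_ids=list(tm.trait_ids),
        scaling=scaling,
        seed=config.seed,
        config={
            "iterations": config.iterations,
            "burnin": config.burnin,
            "thin": config.thin,
            "K": spec.K,
            "M": spec.M,
            "grid_step": float(state.grid.step),
            "standardize": config.standardize,
            "sweep": "grid>location>factors>loadings>shrinkage>variances>missing/v1",
        },
        final_state=state,
    )


# ---------------------------------------------------------------------------
# prior simulation (sampler validation)


def prior_draw_state(
    tm: TraitMatrix, spec: ModelSpec, seed: int | np.random.Generator = 0,
    grid: VarianceGrid | None = None,
) -> ModelState:
    """Draw a full model configuration and data set from the prior.

    Requires a finite ``fixed_prior_variance`` hyperparameter (the default
    flat prior cannot be forward-simulated).  Used for joint-distribution
    ("successive-conditional") validation of the Gibbs sweep.
    """
    state = initialize_state(tm, spec, seed=seed, grid=grid)
    hyper = state.shrinkage.hyper
    vb = hyper["fixed_prior_variance"]
    if not np.isfinite(vb):
        raise ValueError("prior simulation requires finite fixed_prior_variance")
    rng = state.rng
    n, t, K = state.n, state.t, state.K
    grid = state.grid
    cache = state.cache

    state.shrinkage = priors.draw_prior_shrinkage(K, t, hyper, n, rng, b2=spec.b2)
    pv = state.shrinkage.lambda_prior_var()
    state.Lambda = rng.standard_normal((K, t)) * np.sqrt(pv)
    state.gi_traits = rng.choice(grid.P, size=t, p=grid.prior_weights)
    state.gi_factors = rng.choice(grid.P, size=K, p=grid.prior_weights)
    state.sigma2 = hyper["sigma2_rate"] / rng.gamma(hyper["sigma2_shape"], 1.0, size=t)
    state.B1 = rng.standard_normal((spec.b1, t)) * np.sqrt(vb)
    if spec.b2:
        state.B2R = rng.standard_normal((spec.b2, t)) * np.sqrt(state.shrinkage.b2r_prior_var())
        state.B2F = rng.standard_normal((spec.b2, K)) * np.sqrt(state.shrinkage.b2f_prior_var())
    state.U_F = cache.draw_u_prior(state.gi_factors, np.ones(K), rng)
    state.U_R = cache.draw_u_prior(state.gi_traits, state.sigma2, rng)
    EF = rng.standard_normal((n, K)) * np.sqrt(state.psi_FE)[None, :]
    state.F = (state.X2w @ state.B2F if spec.b2 else 0.0) + state.Zu_F() + EF
    draw_data(state)
    return state


def draw_data(state: ModelState) -> ModelState:
    """Redraw Y from its sampling distribution given the current state."""
    E = state.rng.standard_normal((state.n, state.t)) * np.sqrt(state.psi_RE)[None, :]
    state.Yw = state.mean_w() + E
    state.Y_orig = state.cache.from_working(state.Yw)
    state.tm.values[...] = state.Y_orig
    return state
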