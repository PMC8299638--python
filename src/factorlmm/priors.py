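"""Regularization devices: the discrete variance-proportion grid and the
factor-ordered global-local shrinkage prior.

Two priors do the statistical heavy lifting in this package:

1. A *discrete grid prior* on variance proportions.  Each trait column (and
   each latent factor) assigns a proportion ``h_m`` of its variance to every
   random-effect term, with the residual proportion ``1 - sum_m h_m``.  The
   proportions live on a finite lattice, so the expensive matrix
   factorizations of ``Sigma(h) = sum_m h_m Z_m K_m Z_m' + (1 - sum h) I``
   can be computed once per grid point and cached, making the collapsed
   variance-component update an exact discrete posterior draw.

2. A *two-dimensional global-local shrinkage prior* on the factor loadings
   (and on proper-prior regression coefficients): horseshoe-type half-Cauchy
   local scales per element (via the inverse-gamma auxiliary representation,
   which keeps every update conjugate), a multiplicative-gamma sequence of
   factor-specific scales that orders factors from most to least important,
   and a fixed global scale parameterized by the target effective number of
   non-zero coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import brentq

from .data_model import RandomEffectTerm

__all__ = [
    "DEFAULT_HYPERS",
    "VarianceGrid",
    "ShrinkagePriorState",
    "default_num_factors",
    "build_variance_grid",
    "cache_grid_factorizations",
    "init_shrinkage_state",
    "shrinkage_global_scale",
    "expected_nonzero_fraction",
]

DEFAULT_HYPERS: dict[str, float] = {
    # inverse-gamma prior on the per-trait total variance scale sigma2_j
    "sigma2_shape": 3.0,
    "sigma2_rate": 2.0,
    # target fraction of effectively non-zero loadings / coefficients
    "prop_nonzero_lambda": 0.1,
    "prop_nonzero_b2": 0.1,
    # multiplicative-gamma shapes for the factor-ordering sequence
    "delta_shape_1": 2.0,
    "delta_shape_2": 3.0,
    # prior variance of flat-prior fixed effects (inf = improper flat)
    "fixed_prior_variance": np.inf,
}

_EIG_TOL = 1e-10


def resolve_hypers(hyper: dict | None) -> dict:
    out = dict(DEFAULT_HYPERS)
    if hyper:
        unknown = set(hyper) - set(DEFAULT_HYPERS) - {"grid_step"}
        if unknown:
            raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")
        out.update(hyper)
    for k, v in out.items():
        if k == "grid_step":
            continue
        if not (v > 0):
            raise ValueError(f"hyperparameter {k} must be positive, got {v}")
    return out


def default_num_factors(n: int, p: int) -> int:
    """Default number of latent factors, ``floor(min(n/4, p/2))``, >= 1."""
    if n < 4 or p < 1:
        raise ValueError("need n >= 4 and p >= 1")
    return max(1, int(np.floor(min(n / 4.0, p / 2.0))))


# ---------------------------------------------------------------------------
# variance-proportion grid


@dataclass
class VarianceGrid:
    """Discrete lattice of variance proportions with optional cache."""

    points: np.ndarray  # (P, M)
    prior_weights: np.ndarray  # (P,)
    step: float
    cache: "object | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if not np.isclose(self.prior_weights.sum(), 1.0):
            raise ValueError("prior weights must sum to 1")
        if (self.points < 0).any() or (self.points.sum(axis=1) > 1.0 - 1e-9).any():
            raise ValueError("grid points must be >= 0 with sum <= 1 - step")

    @property
    def P(self) -> int:
        return self.points.shape[0]

    @property
    def M(self) -> int:
        return self.points.shape[1]

    @property
    def residual_proportions(self) -> np.ndarray:
        return 1.0 - self.points.sum(axis=1)


def build_variance_grid(
    M: int, step: float, prior_weights: np.ndarray | None = None
) -> VarianceGrid:
    """All M-vectors with components in {0, step, 2 step, ...}, sum <= 1 - step."""
    if not (0 < step <= 0.5):
        raise ValueError("step must be in (0, 0.5]")
    if M < 1:
        raise ValueError("M must be >= 1")
    max_units = int(np.floor((1.0 - step) / step + 1e-9))
    pts = [
        combo
        for combo in itertools.product(range(max_units + 1), repeat=M)
        if sum(combo) <= max_units
    ]
    if not pts:
        raise ValueError("step produces an empty lattice")
    points = np.array(sorted(pts), dtype=float) * step
    if prior_weights is None:
        prior_weights = np.full(len(points), 1.0 / len(points))
    return VarianceGrid(points, np.asarray(prior_weights, dtype=float), step)


def default_grid_step(M: int) -> float:
    """0.1 for a single random-effect term, 0.2 for several (bounds cache size)."""
    return 0.1 if M == 1 else 0.2


class SpectralGridCache:
    """Grid cache for the single-term, identity-incidence case.

    In the eigenbasis of ``K`` every ``Sigma(h)`` is diagonal, so the cache
    stores only per-point diagonal weights; all per-column operations are
    O(n) and fully vectorized across columns.  Sampler state lives in the
    rotated ("working") basis.
    """

    is_spectral = True

    def __init__(self, grid: VarianceGrid, term: RandomEffectTerm, n: int):
        if grid.M != 1:
            raise ValueError("spectral cache requires a single random-effect term")
        d, Q = term.Kmat.eigendecomposition()
        self.n = n
        self.d = d
        self.Q = Q
        self.grid = grid
        h = grid.points[:, 0]  # (P,)
        self.D = h[None, :] * d[:, None] + (1.0 - h)[None, :]  # (n, P)
        self.logdets = np.log(self.D).sum(axis=0)  # (P,)
        self.h = h
        dtol = _EIG_TOL * max(d.max(), 1.0)
        self.pos = d > dtol
        self.rank = int(self.pos.sum())
        # conditional moments of rotated u given the rotated residual column:
        #   mean_i = h d_i / D_i * r_i,  var_i = h d_i (1 - h) / D_i * sigma2
        self.u_coef = (h[None, :] * d[:, None]) / self.D  # (n, P)
        self.u_var = self.u_coef * (1.0 - h)[None, :]  # (n, P)
        self.r_tots = [n]

    # --- basis transforms -------------------------------------------------
    def to_working(self, A: np.ndarray) -> np.ndarray:
        return self.Q.T @ A

    def from_working(self, A: np.ndarray) -> np.ndarray:
        return self.Q @ A

    # --- per-point operations (original basis, for oracles) ---------------
    def solve(self, g: int, B: np.ndarray) -> np.ndarray:
        """Dense-equivalent solve ``Sigma(h_g)^-1 B`` in the original basis."""
        B2d = np.asarray(B, dtype=float).reshape(self.n, -1)
        out = self.Q @ ((self.Q.T @ B2d) / self.D[:, [g]])
        return out.reshape(np.shape(B))

    def logdet(self, g: int) -> float:
        return float(self.logdets[g])

    # --- vectorized working-basis operations ------------------------------
    def solve_w(self, g: int, A: np.ndarray) -> np.ndarray:
        """``Sigma(h_g)^-1 A`` in the working (rotated) basis."""
        return A / self.D[:, [g]]

    def quad_all(self, Rw: np.ndarray) -> np.ndarray:
        """(P, ncol) quadratic forms ``r' Sigma(h)^-1 r`` for every grid point."""
        return (1.0 / self.D).T @ (Rw * Rw)

    def solve_cols(self, Rw: np.ndarray, gidx: np.ndarray) -> np.ndarray:
        """Per-column ``Sigma^-1 r`` at each column's own grid point."""
        return Rw / self.D[:, gidx]

    def sample_u_cols(
        self, Rw: np.ndarray, gidx: np.ndarray, scale: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw rotated random-effect columns from their joint conditional.

        ``Rw`` holds the working-basis residuals (data minus all other
        terms), ``scale`` the per-column total variance sigma2 (1 for
        factors).
        """
        mean = self.u_coef[:, gidx] * Rw
        sd = np.sqrt(np.clip(self.u_var[:, gidx] * scale[None, :], 0.0, None))
        return mean + sd * rng.standard_normal(Rw.shape)

    def u_quad_dof(self, Uw: np.ndarray, gidx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-column ``u' (h K)^+ u`` and rank dof."""
        dpos = self.d[self.pos]
        quad = (Uw[self.pos] ** 2 / dpos[:, None]).sum(axis=0)
        h = self.h[gidx]
        active = h > 0
        out = np.zeros(Uw.shape[1])
        out[active] = quad[active] / h[active]
        dof = np.where(active, self.rank, 0)
        return out, dof

    def draw_u_prior(
        self, gidx: np.ndarray, scale: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Prior draw of the rotated random effects, ``u_i ~ N(0, scale h d_i)``."""
        var = self.h[gidx][None, :] * self.d[:, None] * scale[None, :]
        return np.sqrt(np.clip(var, 0.0, None)) * rng.standard_normal((self.n, len(gidx)))


class GeneralGridCache:
    """Grid cache for arbitrary incidence matrices and multiple terms.

    Per grid point it stores a Cholesky factor of
    ``Sigma(h) = sum_m h_m Z_m K_m Z_m' + (1 - sum h) I`` for O(n^2) solves
    and log-determinants, the cross-covariance block
    ``A = [h_1 K_1 Z_1'; ...]`` and a symmetric square root of the joint
    conditional covariance of the stacked random effects, so (B, U) draws
    never re-factorize during sampling.
    """

    is_spectral = False

    def __init__(
        self,
        grid: VarianceGrid,
        terms: list[RandomEffectTerm],
        n: int,
        memory_cap_bytes: float = 2.0 * 2**30,
    ):
        if grid.M != len(terms):
            raise ValueError("grid dimension must equal the number of terms")
        self.n = n
        self.grid = grid
        self.terms = terms
        self.Zs = [t.incidence(n) for t in terms]
        self.r_tots = [t.r for t in terms]
        self.r_tot = sum(self.r_tots)
        est = grid.P * 8.0 * (n * n + self.r_tot**2 + self.r_tot * n)
        if est > memory_cap_bytes:
            raise MemoryError(
                f"grid cache would need ~{est / 2**30:.2f} GiB "
                f"(cap {memory_cap_bytes / 2**30:.2f} GiB); use a coarser grid "
                "step or raise the cap"
            )
        self._eigs = [t.Kmat.eigendecomposition() for t in terms]
        self.ranks = [
            int((d > _EIG_TOL * max(d.max(), 1.0)).sum()) for d, _ in self._eigs
        ]
        ZKs = [Z @ t.Kmat.matrix for Z, t in zip(self.Zs, terms)]
        self._chos: list = []
        self._logdets = np.zeros(grid.P)
        self._As: list = []
        self._sqrtCs: list = []
        for g in range(grid.P):
            h = grid.points[g]
            Sigma = (1.0 - h.sum()) * np.eye(n)
            for m in range(len(terms)):
                if h[m] > 0:
                    Sigma += h[m] * ZKs[m] @ self.Zs[m].T
            cho = sla.cho_factor(Sigma, lower=True)
            self._chos.append(cho)
            self._logdets[g] = 2.0 * np.sum(np.log(np.diag(cho[0])))
            A = np.vstack([h[m] * ZKs[m].T for m in range(len(terms))])
            Cprior = sla.block_diag(*[h[m] * t.Kmat.matrix for m, t in enumerate(terms)])
            C = Cprior - A @ sla.cho_solve(cho, A.T)
            dC, qC = np.linalg.eigh((C + C.T) / 2.0)
            dC = np.clip(dC, 0.0, None)
            self._As.append(A)
            self._sqrtCs.append(qC * np.sqrt(dC))

    # --- basis transforms (identity: state kept in the original basis) ----
    def to_working(self, A: np.ndarray) -> np.ndarray:
        return A

    def from_working(self, A: np.ndarray) -> np.ndarray:
        return A

    def solve(self, g: int, B: np.ndarray) -> np.ndarray:
        return sla.cho_solve(self._chos[g], B)

    def solve_w(self, g: int, A: np.ndarray) -> np.ndarray:
        return sla.cho_solve(self._chos[g], A)

    def logdet(self, g: int) -> float:
        return float(self._logdets[g])

    def quad_all(self, Rw: np.ndarray) -> np.ndarray:
        out = np.zeros((self.grid.P, Rw.shape[1]))
        for g in range(self.grid.P):
            out[g] = np.sum(Rw * sla.cho_solve(self._chos[g], Rw), axis=0)
        return out

    def solve_cols(self, Rw: np.ndarray, gidx: np.ndarray) -> np.ndarray:
        out = np.empty_like(Rw)
        for g in np.unique(gidx):
            cols = gidx == g
            out[:, cols] = sla.cho_solve(self._chos[g], Rw[:, cols])
        return out

    def sample_u_cols(
        self, Rw: np.ndarray, gidx: np.ndarray, scale: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        out = np.zeros((self.r_tot, Rw.shape[1]))
        for g in np.unique(gidx):
            cols = np.where(gidx == g)[0]
            mean = self._As[g] @ sla.cho_solve(self._chos[g], Rw[:, cols])
            z = rng.standard_normal((self._sqrtCs[g].shape[1], len(cols)))
            out[:, cols] = mean + np.sqrt(scale[cols])[None, :] * (self._sqrtCs[g] @ z)
        return out

    def u_quad_dof(self, Uw: np.ndarray, gidx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ncol = Uw.shape[1]
        quad = np.zeros(ncol)
        dof = np.zeros(ncol, dtype=int)
        offs = np.concatenate([[0], np.cumsum(self.r_tots)])
        for m, (d, q) in enumerate(self._eigs):
            dtol = _EIG_TOL * max(d.max(), 1.0)
            pos = d > dtol
            dpos = d[pos]
            Um = Uw[offs[m] : offs[m + 1]]
            proj = q[:, pos].T @ Um
            qm = (proj**2 / dpos[:, None]).sum(axis=0)
            h = self.grid.points[gidx, m]
            active = h > 0
            quad[active] += qm[active] / h[active]
            dof[active] += self.ranks[m]
        return quad, dof

    def Zu(self, Uw: np.ndarray) -> np.ndarray:
        """Map stacked random effects to the observation scale, ``sum Z_m U_m``."""
        offs = np.concatenate([[0], np.cumsum(self.r_tots)])
        out = np.zeros((self.n, Uw.shape[1]))
        for m, Z in enumerate(self.Zs):
            out += Z @ Uw[offs[m] : offs[m + 1]]
        return out

    def draw_u_prior(
        self, gidx: np.ndarray, scale: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Prior draw of stacked random effects, ``u_m ~ N(0, scale h_m K_m)``."""
        ncol = len(gidx)
        out = np.zeros((self.r_tot, ncol))
        offs = np.concatenate([[0], np.cumsum(self.r_tots)])
        for m, (d, q) in enumerate(self._eigs):
            L = q * np.sqrt(np.clip(d, 0.0, None))
            h = self.grid.points[gidx, m]
            z = rng.standard_normal((L.shape[1], ncol))
            out[offs[m] : offs[m + 1]] = (L @ z) * np.sqrt(h * scale)[None, :]
        return out


def cache_grid_factorizations(
    grid: VarianceGrid,
    terms: list[RandomEffectTerm],
    n: int,
    memory_cap_bytes: float = 2.0 * 2**30,
) -> VarianceGrid:
    """Attach per-grid-point factorizations to a VarianceGrid.

    The single-term identity-incidence case stores only diagonal weights in
    the eigenbasis of ``K``; the general case precomputes per-point Cholesky
    factors (and joint conditional square roots for the random effects).
    """
    if grid.M == 1 and terms[0].is_identity(n):
        grid.cache = SpectralGridCache(grid, terms[0], n)
    else:
        grid.cache = GeneralGridCache(grid, terms, n, memory_cap_bytes)
    return grid


# ---------------------------------------------------------------------------
# global-local shrinkage prior


@dataclass
class ShrinkagePriorState:
    """Scales of the factor-ordered horseshoe-type prior.

    Element (k, j) of the loadings matrix has prior
    ``lambda_kj ~ N(0, tau2 * gamma_k * phi2_kj)`` with half-Cauchy local
    scales ``phi_kj`` (kept via the inverse-gamma auxiliary ``nu_kj``), a
    multiplicative-gamma factor sequence ``gamma_k = prod_{l<=k} 1/delta_l``
    that makes shrinkage stochastically increase with the factor index, and
    a fixed global scale ``tau`` calibrated to a target effective number of
    non-zero coefficients.  Analogous per-element arrays regularize the
    proper-prior fixed-effect coefficients B2R and B2F.
    """

    K: int
    t: int
    lam_phi2: np.ndarray  # (K, t)
    lam_nu: np.ndarray  # (K, t)
    delta: np.ndarray  # (K,)
    tau2_lambda: float
    hyper: dict
    b2r_phi2: np.ndarray | None = None  # (b2, t)
    b2r_nu: np.ndarray | None = None
    b2f_phi2: np.ndarray | None = None  # (b2, K)
    b2f_nu: np.ndarray | None = None
    tau2_b2: float = 1.0

    def __post_init__(self) -> None:
        for arr in (self.lam_phi2, self.lam_nu, self.delta):
            if np.asarray(arr).size and np.any(np.asarray(arr) <= 0):
                raise ValueError("all shrinkage scales must be positive")

    @property
    def gamma(self) -> np.ndarray:
        """Factor-specific prior variance multipliers, non-increasing in k."""
        if self.K == 0:
            return np.zeros(0)
        return np.cumprod(1.0 / self.delta)

    @property
    def factor_scales(self) -> np.ndarray:
        return self.gamma

    def lambda_prior_var(self) -> np.ndarray:
        """(K, t) prior variances of the loadings."""
        return self.tau2_lambda * self.gamma[:, None] * self.lam_phi2

    def b2r_prior_var(self) -> np.ndarray:
        return self.tau2_b2 * self.b2r_phi2

    def b2f_prior_var(self) -> np.ndarray:
        return self.tau2_b2 * self.gamma[None, :] * self.b2f_phi2


def _meff_one(sqrt_a: np.ndarray) -> np.ndarray:
    # E_phi[1 - kappa] for phi ~ C+(0,1): sqrt(a)/(1 + sqrt(a)), a = n tau^2 gamma
    return sqrt_a / (1.0 + sqrt_a)


def shrinkage_global_scale(
    K: int,
    t: int,
    n_units: int,
    prop_nonzero: float,
    delta_shape_1: float,
    delta_shape_2: float,
    n_mc: int = 2000,
    seed: int = 20_210_723,
) -> float:
    """Global scale tau from the target effective number of non-zeros.

    Uses the prior-expected-shrinkage-weight identity: with shrinkage weight
    kappa = 1 / (1 + n tau^2 gamma_k phi^2) and phi ~ C+(0,1),
    E[1 - kappa] = sqrt(a) / (1 + sqrt(a)) with a = n tau^2 gamma_k (unit
    residual scale), so the expected number of effectively non-zero loadings
    is t * sum_k E_gamma[sqrt(a_k) / (1 + sqrt(a_k))].  The expectation over
    the multiplicative-gamma sequence is averaged over a fixed Monte-Carlo
    panel of delta draws, and tau solved by bisection.
    """
    if not (0 < prop_nonzero < 1):
        raise ValueError("prop_nonzero must be in (0, 1)")
    if K == 0:
        return 1.0
    target = prop_nonzero * K * t
    rng = np.random.default_rng(seed)
    shapes = np.full(K, delta_shape_2)
    shapes[0] = delta_shape_1
    deltas = rng.gamma(shapes, 1.0, size=(n_mc, K))
    gammas = np.cumprod(1.0 / deltas, axis=1)  # (n_mc, K)

    def meff(log_tau: float) -> float:
        tau2 = np.exp(2.0 * log_tau)
        sqrt_a = np.sqrt(n_units * tau2 * gammas)
        return float(t * _meff_one(sqrt_a).sum(axis=1).mean()) - target

    lo, hi = -30.0, 30.0
    return float(np.exp(brentq(meff, lo, hi, xtol=1e-12)))


def expected_nonzero_fraction(state: ShrinkagePriorState, n_units: int) -> float:
    """Semi-analytic expected fraction of non-zero loadings at the current
    factor scales (local scales integrated out)."""
    if state.K == 0:
        return 0.0
    sqrt_a = np.sqrt(n_units * state.tau2_lambda * state.gamma)
    return float(_meff_one(sqrt_a).sum() * state.t / (state.K * state.t))


def init_shrinkage_state(
    K: int,
    t: int,
    hyper: dict | None = None,
    n_units: int = 100,
    b2: int = 0,
) -> ShrinkagePriorState:
    """Initialize all shrinkage scales at their prior means.

    The factor multipliers start strictly decreasing (delta at its prior
    mean, > 1), so prior variance is non-increasing in the factor index from
    the first sweep.
    """
    hyper = resolve_hypers(hyper)
    a1, a2 = hyper["delta_shape_1"], hyper["delta_shape_2"]
    delta = np.full(K, a2)
    if K:
        delta[0] = a1
    tau = shrinkage_global_scale(K, t, n_units, hyper["prop_nonzero_lambda"], a1, a2) if K else 1.0
    state = ShrinkagePriorState(
        K=K,
        t=t,
        lam_phi2=np.ones((K, t)),
        lam_nu=np.ones((K, t)),
        delta=delta,
        tau2_lambda=tau**2,
        hyper=hyper,
    )
    if b2 > 0:
        ncoef = b2 * (t + K)
        # effective-nonzero mapping with gamma = 1 has the closed form
        # sqrt(a)/(1+sqrt(a)) = p0/D  =>  tau = (p0/(D-p0)) / sqrt(n)
        p0 = hyper["prop_nonzero_b2"] * ncoef
        tau_b2 = (p0 / (ncoef - p0)) / np.sqrt(n_units)
        state.b2r_phi2 = np.ones((b2, t))
        state.b2r_nu = np.ones((b2, t))
        state.b2f_phi2 = np.ones((b2, K))
        state.b2f_nu = np.ones((b2, K))
        state.tau2_b2 = tau_b2**2
    return state


# --- conjugate updates (used by the Gibbs sweep and prior simulation) ------


def _invgamma(rng: np.random.Generator, shape, rate):
    """Draw from InvGamma(shape, rate): x = rate / Gamma(shape, 1)."""
    return np.asarray(rate) / rng.gamma(shape, 1.0, size=np.shape(rate))


def draw_prior_shrinkage(
    K: int, t: int, hyper: dict, n_units: int, rng: np.random.Generator, b2: int = 0
) -> ShrinkagePriorState:
    """Forward draw of all shrinkage scales from the prior."""
    state = init_shrinkage_state(K, t, hyper, n_units=n_units, b2=b2)
    shapes = np.full(K, state.hyper["delta_shape_2"])
    if K:
        shapes[0] = state.hyper["delta_shape_1"]
    state.delta = rng.gamma(shapes, 1.0)
    state.lam_nu = _invgamma(rng, 0.5, np.ones((K, t)))
    state.lam_phi2 = _invgamma(rng, 0.5, 1.0 / state.lam_nu)
    if b2 > 0:
        state.b2r_nu = _invgamma(rng, 0.5, np.ones((b2, t)))
        state.b2r_phi2 = _invgamma(rng, 0.5, 1.0 / state.b2r_nu)
        state.b2f_nu = _invgamma(rng, 0.5, np.ones((b2, K)))
        state.b2f_phi2 = _invgamma(rng, 0.5, 1.0 / state.b2f_nu)
    return state


def update_local_scales(
    phi2: np.ndarray, nu: np.ndarray, coef: np.ndarray, scale2: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate horseshoe updates of (phi2, nu) given coefficients.

    ``scale2`` is the non-local part of each element's prior variance
    (tau2 * gamma for loadings), broadcastable to the coefficient shape.
    """
    phi2_new = _invgamma(rng, 1.0, 1.0 / nu + coef**2 / (2.0 * scale2))
    nu_new = _invgamma(rng, 1.0, 1.0 + 1.0 / phi2_new)
    return phi2_new, nu_new


def update_delta(
    state: ShrinkagePriorState, Lambda: np.ndarray, rng: np.random.Generator,
    B2F: np.ndarray | None = None,
) -> None:
    """Multiplicative-gamma updates of the factor-ordering sequence.

    Conditional of each delta_h is Gamma with shape
    ``a_h + (count of elements in factors k >= h) / 2`` and rate
    ``1 + (1/2) sum_{k>=h} gamma_k^(-h) sum_j coef_kj^2 / (tau2 phi2_kj)``
    where ``gamma_k^(-h)`` omits delta_h from the product.
    """
    K = state.K
    if K == 0:
        return
    a1, a2 = state.hyper["delta_shape_1"], state.hyper["delta_shape_2"]
    # per-factor summed scaled squares: sum_j lambda^2 / (tau2 phi2)
    s = (Lambda**2 / (state.tau2_lambda * state.lam_phi2)).sum(axis=1)
    counts = np.full(K, state.t)
    if B2F is not None and state.b2f_phi2 is not None and B2F.size:
        s = s + (B2F**2 / (state.tau2_b2 * state.b2f_phi2)).sum(axis=0)
        counts = counts + B2F.shape[0]
    for h in range(K):
        shape = (a1 if h == 0 else a2) + 0.5 * counts[h:].sum()
        inv_gamma_wo_h = np.cumprod(state.delta)  # prod_{l<=k} delta_l
        # omit delta_h from the product for k >= h
        contrib = inv_gamma_wo_h[h:] / state.delta[h]
        rate = 1.0 + 0.5 * np.sum(contrib * s[h:])
        state.delta[h] = rng.gamma(shape, 1.0 / rate)
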