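"""Univariate and multi-kernel reference predictors, and the genetic-value
prediction-accuracy estimator.

Prediction accuracy for genetic values is estimated as

    rho_g = cor_g(u_hat, y) * sqrt(h2(u_hat))

where ``cor_g`` is the genetic correlation between predictor and phenotype
evaluated in the testing lines only and ``h2(u_hat)`` the heritability of
the predictor from a univariate REML LMM.  Unlike Pearson's correlation,
this discounts non-genetic correlation between secondary traits and the
focal trait when both were measured on the same plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data_model import RelationshipMatrix

__all__ = [
    "REMLResult",
    "MultiKernelResult",
    "reml_univariate",
    "multi_kernel_blup",
    "rho_g_accuracy",
    "cv_masks",
]


@dataclass
class REMLResult:
    h2: float
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    u: np.ndarray  # BLUPs for all lines (including unphenotyped)
    loglik: float
    identifiable: bool
    boundary: bool


def _observed(y: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    if mask is not None:
        obs &= np.asarray(mask, dtype=bool)
    return obs


def reml_univariate(
    y: np.ndarray,
    K: RelationshipMatrix,
    X: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> REMLResult:
    """Single-random-effect REML via 1-D optimization in the eigenbasis.

    The observed subvector is rotated by the eigenvectors of the observed
    kinship block, so each restricted-likelihood evaluation is O(n); the
    heritability maximizer is found by bounded scalar optimization with the
    total variance profiled out.  BLUPs are returned for every line,
    including unphenotyped ones.  A boundary solution (h2 = 0) is a valid
    result, not an error; a likelihood flat in h2 (e.g. K = I) is flagged
    non-identifiable.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.dim != n:
        raise ValueError("K dimension must match length of y")
    obs = _observed(y, mask)
    n_o = int(obs.sum())
    if n_o < 3:
        raise ValueError("need at least 3 observed values")
    y_o = y[obs]
    if np.allclose(y_o, y_o[0]):
        raise ValueError("constant phenotype: variance components undefined")
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    X_o = X[obs]
    b = X_o.shape[1]

    K_oo = K.matrix[np.ix_(obs, obs)]
    d, Q = np.linalg.eigh((K_oo + K_oo.T) / 2.0)
    d = np.clip(d, 0.0, None)
    yr = Q.T @ y_o
    Xr = Q.T @ X_o

    def negloglik(h2: float) -> float:
        D = h2 * d + (1.0 - h2)
        Dinv = 1.0 / D
        XtDX = Xr.T @ (Xr * Dinv[:, None])
        XtDy = Xr.T @ (yr * Dinv)
        beta = np.linalg.solve(XtDX, XtDy)
        r = yr - Xr @ beta
        rss = float(r @ (r * Dinv))
        s2 = rss / (n_o - b)
        _, ld_x = np.linalg.slogdet(XtDX)
        return 0.5 * (np.log(D).sum() + (n_o - b) * np.log(s2) + ld_x)

    # identifiability probe: a flat restricted likelihood means h2 is not
    # estimable from this kinship (e.g. K proportional to I)
    probe = [negloglik(h) for h in (0.01, 0.5, 0.99)]
    identifiable = (max(probe) - min(probe)) > 1e-8 * max(1.0, abs(probe[1]))

    res = optimize.minimize_scalar(
        negloglik, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    # snap to the boundary when the interior optimum hugs it
    for edge in (0.0, 1.0):
        cand = min(max(edge, 1e-12), 1.0 - 1e-12)
        if abs(h2 - edge) < 1e-6 and negloglik(cand) <= res.fun + 1e-10:
            h2 = edge
    boundary = h2 in (0.0, 1.0) or h2 < 1e-6 or h2 > 1.0 - 1e-6
    h2_eval = min(max(h2, 1e-12), 1.0 - 1e-12)

    D = h2_eval * d + (1.0 - h2_eval)
    Dinv = 1.0 / D
    XtDX = Xr.T @ (Xr * Dinv[:, None])
    beta = np.linalg.solve(XtDX, Xr.T @ (yr * Dinv))
    r_o = y_o - X_o @ beta
    Vinv_r = Q @ ((Q.T @ r_o) * Dinv)
    s2 = float((y_o - X_o @ beta) @ Vinv_r) / (n_o - b)
    u = h2 * (K.matrix[:, obs] @ Vinv_r)
    return REMLResult(
        h2=h2 if identifiable else float("nan"),
        sigma2_g=h2 * s2,
        sigma2_e=(1.0 - h2) * s2,
        beta=beta,
        u=u if identifiable else np.zeros(n),
        loglik=-float(res.fun),
        identifiable=identifiable,
        boundary=boundary,
    )


@dataclass
class MultiKernelResult:
    proportions: np.ndarray  # variance proportion per kernel
    sigma2: float
    beta: np.ndarray
    u_train: list[np.ndarray]  # per-kernel BLUPs on training lines
    predictions: np.ndarray  # per-line predictions (kernel-regression sum)
    loglik: float


def multi_kernel_blup(
    y: np.ndarray,
    kernels: list[RelationshipMatrix],
    X: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> MultiKernelResult:
    """REML fit with several kernel random effects; out-of-sample predictions.

    Variance proportions per kernel are estimated on the training lines by
    Nelder-Mead over a softmax parameterization of the simplex, and
    predictions for all lines are formed as the kernel-regression sum
    ``sum_m K_m,no K_m,oo^{-1} u_hat_m`` over the per-kernel BLUPs.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    y = np.asarray(y, dtype=float)
    n = len(y)
    obs = _observed(y, mask)
    n_o = int(obs.sum())
    if n_o < 3:
        raise ValueError("need at least 3 observed (training) values")
    y_o = y[obs]
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    X_o = X[obs]
    b = X_o.shape[1]
    M = len(kernels)
    K_oo = [K.matrix[np.ix_(obs, obs)] for K in kernels]

    def props(z: np.ndarray) -> np.ndarray:
        e = np.exp(z - z.max())
        return e / (e.sum() + np.exp(-z.max()))

    def negloglik(z: np.ndarray) -> float:
        h = props(z)
        V = (1.0 - h.sum()) * np.eye(n_o)
        for m in range(M):
            V += h[m] * K_oo[m]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Li_y = np.linalg.solve(L, y_o)
        Li_X = np.linalg.solve(L, X_o)
        XtVX = Li_X.T @ Li_X
        beta = np.linalg.solve(XtVX, Li_X.T @ Li_y)
        r = Li_y - Li_X @ beta
        s2 = float(r @ r) / (n_o - b)
        _, ld_x = np.linalg.slogdet(XtVX)
        return 0.5 * (2.0 * np.log(np.diag(L)).sum() + (n_o - b) * np.log(s2) + ld_x)

    res = optimize.minimize(
        negloglik, np.zeros(M), method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
    )
    h = props(res.x)
    V = (1.0 - h.sum()) * np.eye(n_o)
    for m in range(M):
        V += h[m] * K_oo[m]
    Vinv = np.linalg.inv(V)
    XtVX = X_o.T @ Vinv @ X_o
    beta = np.linalg.solve(XtVX, X_o.T @ (Vinv @ y_o))
    resid = y_o - X_o @ beta
    Vinv_r = Vinv @ resid
    s2 = float(resid @ Vinv_r) / (n_o - b)

    u_train = [h[m] * (K_oo[m] @ Vinv_r) for m in range(M)]
    pred = np.zeros(n)
    for m in range(M):
        Km = kernels[m].matrix
        ridge = 1e-8 * np.trace(K_oo[m]) / n_o
        try:
            coef = np.linalg.solve(K_oo[m] + ridge * np.eye(n_o), u_train[m])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"training block of kernel {m} singular even after ridge"
            ) from exc
        pred += Km[:, obs] @ coef
    return MultiKernelResult(
        proportions=h,
        sigma2=s2,
        beta=beta,
        u_train=u_train,
        predictions=pred,
        loglik=-float(res.fun),
    )


def _genetic_variance(v: np.ndarray, K: RelationshipMatrix) -> float:
    try:
        fit = reml_univariate(v, K)
    except ValueError:
        return float("nan")
    return float(fit.sigma2_g) if fit.identifiable else float("nan")


def rho_g_accuracy(
    u_hat: np.ndarray,
    y: np.ndarray,
    K: RelationshipMatrix,
    test_idx: np.ndarray,
) -> float:
    """Genetic-value prediction accuracy ``cor_g(u_hat, y) sqrt(h2(u_hat))``.

    ``cor_g`` is estimated in the testing lines only via the pairwise
    variance decomposition of u_hat, y, and u_hat + y:
    ``cov_g = (Vg(u+y) - Vg(u) - Vg(y)) / 2``, each genetic variance from a
    univariate REML fit against the testing-block kinship.  The result is
    invariant to affine rescaling of the predictor.  If h2(u_hat) is zero
    (or not identifiable), accuracy 0 is returned with a warning.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    test_idx = np.asarray(test_idx)
    if test_idx.dtype == bool:
        test_idx = np.where(test_idx)[0]
    if len(test_idx) < 30:
        warnings.warn(f"only {len(test_idx)} testing lines; rho_g estimate is noisy")

    if np.std(u_hat) == 0:
        warnings.warn("constant predictor; rho_g = 0")
        return 0.0
    fit_u = reml_univariate(u_hat, K)
    if not fit_u.identifiable or not np.isfinite(fit_u.h2) or fit_u.h2 <= 0:
        warnings.warn("predictor has no estimable genetic signal; rho_g = 0")
        return 0.0

    sub = test_idx
    K_test = RelationshipMatrix(K.matrix[np.ix_(sub, sub)], label="K_test")
    u_t, y_t = u_hat[sub], y[sub]
    # standardize both series so the pairwise REML decomposition of the sum
    # is exactly invariant to affine rescaling of the predictor
    u_t = (u_t - u_t.mean()) / u_t.std(ddof=1)
    y_t = (y_t - y_t.mean()) / y_t.std(ddof=1)
    vg_u = _genetic_variance(u_t, K_test)
    vg_y = _genetic_variance(y_t, K_test)
    vg_s = _genetic_variance(u_t + y_t, K_test)
    if not np.isfinite([vg_u, vg_y, vg_s]).all() or vg_u <= 0 or vg_y <= 0:
        warnings.warn("degenerate genetic variances in testing lines; rho_g = 0")
        return 0.0
    cor_g = (vg_s - vg_u - vg_y) / (2.0 * np.sqrt(vg_u * vg_y))
    cor_g = float(np.clip(cor_g, -1.0, 1.0))
    return cor_g * float(np.sqrt(fit_u.h2))


def cv_masks(n: int, fraction: float, replicates: int, seed: int) -> list[np.ndarray]:
    """Random train/test masks: each replicate masks ``floor(fraction n)`` units.

    Returns boolean vectors with True marking masked (testing) units;
    deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = int(np.floor(fraction * n))
    if k == 0 or k == n:
        raise ValueError("fraction yields an empty training or testing set")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        out.append(mask)
    return out
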