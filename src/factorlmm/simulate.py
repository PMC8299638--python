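"""Synthetic-data generation with the statistical structure the model assumes.

Two generative routes are provided: directly from target genetic and
residual covariance matrices (``Y = U + E`` with ``U ~ MN(0, K, G)`` and
``E ~ MN(0, I, R)``), and through the factor parameterization itself (sparse
loadings with decreasing row scales, factors driven by level-2 LMMs).  When
correlation matrices are supplied they are converted to covariances by
drawing an independent heritability per trait uniformly in [0.1, 0.8], so
traits have unit total variance.  Cross-validation scenarios mirror the two
standard masking schemes: CV2 (focal trait partially masked, secondary
traits complete) and CV1 (testing units entirely unphenotyped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RelationshipMatrix, TraitMatrix
from .kernels import vanraden_kinship

__all__ = [
    "SyntheticTruth",
    "simulate_kinship",
    "simulate_from_covariances",
    "simulate_factor_truth",
    "make_cv_scenario",
    "exchangeable_correlation",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated TraitMatrix."""

    G_list: list[np.ndarray]
    R: np.ndarray
    U_true: np.ndarray  # n x t genetic values (first term)
    h2_true: np.ndarray
    seed: int
    F_true: np.ndarray | None = None
    Lambda_true: np.ndarray | None = None
    psi_F: np.ndarray | None = None  # (K_true, M) factor variance proportions
    psi_R_idio: np.ndarray | None = None  # (t,) idiosyncratic genetic variances

    def __post_init__(self) -> None:
        if np.any((self.h2_true <= 0) | (self.h2_true >= 1)):
            raise ValueError("true heritabilities must lie in (0, 1)")


def _psd_sqrt(A: np.ndarray) -> np.ndarray:
    d, q = np.linalg.eigh((A + A.T) / 2.0)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError("matrix is not positive semi-definite")
    return q * np.sqrt(np.clip(d, 0.0, None))


def _kinship_sqrt(K: RelationshipMatrix) -> np.ndarray:
    """Square root via the relationship matrix's cached spectrum."""
    d, q = K.eigendecomposition()
    return q * np.sqrt(d)


def _matrix_normal(
    rng: np.random.Generator, row_sqrt: np.ndarray, col_cov: np.ndarray
) -> np.ndarray:
    """Draw MN(0, row_sqrt row_sqrt', col_cov)."""
    col_sqrt = _psd_sqrt(col_cov)
    z = rng.standard_normal((row_sqrt.shape[1], col_sqrt.shape[1]))
    return row_sqrt @ z @ col_sqrt.T


def exchangeable_correlation(t: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix; PSD for rho in (-1/(t-1), 1)."""
    if t > 1 and not (-1.0 / (t - 1) < rho < 1.0):
        raise ValueError("rho outside the PSD range for this dimension")
    return (1.0 - rho) * np.eye(t) + rho * np.ones((t, t))


def simulate_kinship(
    n: int, n_markers: int = 500, maf: float = 0.3, seed: int = 0
) -> RelationshipMatrix:
    """Marker-derived kinship with realistic eigenvalue decay.

    Dosages are iid Binomial(2, maf) calls at ``n_markers`` loci, passed
    through the VanRaden kinship; this yields a dense, full-rank-ish K whose
    spectrum decays like real genotype panels rather than an identity
    matrix.
    """
    rng = np.random.default_rng(seed)
    markers = rng.binomial(2, maf, size=(n, n_markers)).astype(float)
    K = vanraden_kinship(markers, ids=[f"u{i:04d}" for i in range(n)])
    return K


def simulate_from_covariances(
    G: np.ndarray,
    R: np.ndarray,
    K: RelationshipMatrix,
    n: int,
    seed: int = 0,
    correlations: bool = False,
    h2_range: tuple[float, float] = (0.1, 0.8),
) -> tuple[TraitMatrix, SyntheticTruth]:
    """Simulate ``Y = U + E`` with ``U ~ MN(0, K, G)``, ``E ~ MN(0, I, R)``.

    With ``correlations=True``, G and R are treated as correlation matrices
    and rescaled to covariances by per-trait heritabilities drawn uniformly
    from ``h2_range`` (unit total variance per trait).
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    t = G.shape[0]
    if G.shape != (t, t) or R.shape != (t, t):
        raise ValueError("G and R must be square of the same dimension")
    if K.dim != n:
        raise ValueError("kinship dimension must equal n")
    rng = np.random.default_rng(seed)
    if correlations:
        h2 = rng.uniform(*h2_range, size=t)
        sg = np.sqrt(h2)
        sr = np.sqrt(1.0 - h2)
        G = G * np.outer(sg, sg)
        R = R * np.outer(sr, sr)
    dG = np.diag(G)
    dR = np.diag(R)
    if np.any(dR <= 0):
        raise ValueError("R must have a strictly positive diagonal")
    with np.errstate(invalid="ignore"):
        h2_true = np.where(dG + dR > 0, dG / (dG + dR), 0.5)
    h2_true = np.clip(h2_true, 1e-6, 1.0 - 1e-6)

    Ksqrt = _kinship_sqrt(K)
    U = _matrix_normal(rng, Ksqrt, G)
    E = rng.standard_normal((n, t)) @ _psd_sqrt(R).T
    Y = U + E
    unit_ids = K.ids if K.ids is not None else [f"u{i:04d}" for i in range(n)]
    tm = TraitMatrix(
        Y, np.ones_like(Y, dtype=bool), list(unit_ids), [f"trait{j:03d}" for j in range(t)]
    )
    truth = SyntheticTruth(G_list=[G], R=R, U_true=U, h2_true=h2_true, seed=seed)
    return tm, truth


def simulate_factor_truth(
    n: int,
    t: int,
    K_true: int,
    M: int = 1,
    h2_factor: np.ndarray | None = None,
    sparsity: float = 0.5,
    K_mats: list[RelationshipMatrix] | None = None,
    seed: int = 0,
    idio_h2_range: tuple[float, float] = (0.1, 0.8),
    row_scale_decay: float = 0.85,
) -> tuple[TraitMatrix, SyntheticTruth]:
    """Generate data through the factor parameterization with known truth.

    Loadings rows have the stated proportion of exact zeros and row scales
    decreasing geometrically in the factor index; each factor is driven by a
    level-2 LMM with the given per-factor variance proportions (drawn
    uniformly in [0.1, 0.8] when omitted).  Trait-specific (idiosyncratic)
    variance is split between the first random-effect term and the residual
    by per-trait heritabilities drawn from ``idio_h2_range``.
    """
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    if K_true > t:
        raise ValueError("K_true must be <= t")
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = np.random.default_rng(seed)
    if K_mats is None:
        K_mats = [simulate_kinship(n, seed=seed + 7919 * (m + 1)) for m in range(M)]
    if len(K_mats) != M:
        raise ValueError("need one relationship matrix per term")
    for Km in K_mats:
        if Km.dim != n:
            raise ValueError("all relationship matrices must be n x n")

    # sparse loadings, rows ordered most-to-least important
    scales = row_scale_decay ** np.arange(K_true)
    nz = rng.random((K_true, t)) >= sparsity
    for k in range(K_true):  # never an all-zero factor
        if not nz[k].any():
            nz[k, rng.integers(t)] = True
    Lambda = np.where(nz, rng.standard_normal((K_true, t)), 0.0) * scales[:, None]

    if h2_factor is None:
        # total heritable proportion per factor ~ U(0.1, 0.8), split across terms
        total = rng.uniform(0.1, 0.8, size=(K_true, 1))
        split = rng.dirichlet(np.ones(M), size=K_true) if M > 1 else np.ones((K_true, 1))
        h2_factor = total * split
    h2_factor = np.asarray(h2_factor, dtype=float).reshape(K_true, M)
    if np.any(h2_factor < 0) or np.any(h2_factor.sum(axis=1) >= 1):
        raise ValueError("factor variance proportions must be >= 0 with sum < 1")

    Ksqrts = [_kinship_sqrt(Km) for Km in K_mats]
    U_F = [
        Ksqrts[m] @ rng.standard_normal((n, K_true)) * np.sqrt(h2_factor[:, m])[None, :]
        for m in range(M)
    ]
    E_F = rng.standard_normal((n, K_true)) * np.sqrt(1.0 - h2_factor.sum(axis=1))[None, :]
    F = sum(U_F) + E_F

    h2_idio = rng.uniform(*idio_h2_range, size=t)
    U_R0 = Ksqrts[0] @ rng.standard_normal((n, t)) * np.sqrt(h2_idio)[None, :]
    E_R = rng.standard_normal((n, t)) * np.sqrt(1.0 - h2_idio)[None, :]
    Y = F @ Lambda + U_R0 + E_R

    # implied covariances via the assembly identity
    G_list = []
    for m in range(M):
        psi_R = h2_idio if m == 0 else np.zeros(t)
        G_list.append(np.diag(psi_R) + Lambda.T @ (h2_factor[:, m][:, None] * Lambda))
    R = np.diag(1.0 - h2_idio) + Lambda.T @ (
        (1.0 - h2_factor.sum(axis=1))[:, None] * Lambda
    )
    U_true = U_R0 + U_F[0] @ Lambda
    dG = np.diag(sum(G_list))
    h2_true = np.clip(dG / (dG + np.diag(R)), 1e-6, 1.0 - 1e-6)

    unit_ids = K_mats[0].ids if K_mats[0].ids is not None else [f"u{i:04d}" for i in range(n)]
    tm = TraitMatrix(
        Y, np.ones_like(Y, dtype=bool), list(unit_ids), [f"trait{j:03d}" for j in range(t)]
    )
    truth = SyntheticTruth(
        G_list=G_list,
        R=R,
        U_true=U_true,
        h2_true=h2_true,
        seed=seed,
        F_true=F,
        Lambda_true=Lambda,
        psi_F=h2_factor,
        psi_R_idio=h2_idio,
    )
    return tm, truth


def make_cv_scenario(
    tm: TraitMatrix,
    scenario: str,
    focal: str,
    fraction: float = 0.5,
    seed: int = 0,
) -> TraitMatrix:
    """Apply a CV1/CV2 masking scheme; testing units recorded on the result.

    ``CV2_focal`` masks the stated fraction of the focal trait only
    (secondary traits stay complete); ``CV1_all`` masks every trait for the
    testing units.  The testing-unit indices are stored in
    ``result.cv_test_units`` for scoring.
    """
    if focal not in tm.trait_ids:
        raise ValueError(f"focal trait {focal!r} not found")
    j = tm.trait_ids.index(focal)
    rng = np.random.default_rng(seed)
    candidates = np.where(tm.mask[:, j])[0]
    k = int(np.floor(fraction * len(candidates)))
    if len(candidates) - k < 3:
        raise ValueError("masking fraction leaves fewer than 3 observed focal values")
    test_units = np.sort(rng.choice(candidates, size=k, replace=False))
    out = tm.copy()
    if scenario == "CV2_focal":
        out.mask[test_units, j] = False
    elif scenario == "CV1_all":
        out.mask[test_units, :] = False
    else:
        raise ValueError(f"unknown scenario {scenario!r} (use CV2_focal or CV1_all)")
    out.values = np.where(out.mask, out.values, np.nan)
    out.partitions = []
    out.cv_test_units = test_units
    return out
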