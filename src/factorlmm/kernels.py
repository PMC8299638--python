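"""Relationship-matrix and kernel constructors.

Marker-based kinships (VanRaden and trace-normalized centered-IBS),
cross-product kernels from high-dimensional secondary traits (e.g.
hyperspectral reflectance), and Gaussian kernels for RKHS-style
kernel-averaging fits with multiple random effects.
"""

from __future__ import annotations

import numpy as np

from .data_model import RelationshipMatrix

__all__ = [
    "vanraden_kinship",
    "centered_ibs_kinship",
    "trait_kernel",
    "gaussian_kernels",
    "eigendecompose",
]

#: default bandwidth scaling factors for kernel averaging
DEFAULT_BANDWIDTHS = (1.0 / 5.0, 1.0, 5.0)


def _clean_markers(markers: np.ndarray, max_missing: float = 0.5) -> np.ndarray:
    """Drop over-missing and monomorphic markers; mean-impute the rest."""
    X = np.asarray(markers, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("markers must be an n x p matrix with p >= 1")
    finite = np.isfinite(X)
    keep = finite.mean(axis=0) >= (1.0 - max_missing)
    if not keep.any():
        raise ValueError(f"all markers exceed the {max_missing:.0%} missingness threshold")
    X = X[:, keep]
    col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    idx = np.where(~np.isfinite(X))
    if len(idx[0]):
        X = X.copy()
        X[idx] = col_mean[idx[1]]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    return X[:, poly]


def vanraden_kinship(markers: np.ndarray, ids: list[str] | None = None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    ``K = W W^T / c`` with ``W`` the column-centered dosage matrix
    (``w_ij = x_ij - 2 p_j``) and ``c = 2 sum_j p_j (1 - p_j)``.  Markers with
    more than 50% missing calls are dropped, remaining missing dosages are
    mean-imputed, and monomorphic markers are removed.
    """
    X = _clean_markers(markers)
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    K = W @ W.T / c
    return RelationshipMatrix((K + K.T) / 2.0, ids=ids, label="vanraden")


def centered_ibs_kinship(markers: np.ndarray, ids: list[str] | None = None) -> RelationshipMatrix:
    """Centered-IBS style kinship: centered cross-product, trace-normalized.

    The cross-product of centered dosages is rescaled so the mean diagonal
    element equals 1.  This differs from the VanRaden kinship only by the
    scalar normalizer (per-matrix instead of the expected-heterozygosity
    constant).
    """
    X = _clean_markers(markers)
    W = X - X.mean(axis=0)
    K = W @ W.T
    d = np.trace(K) / K.shape[0]
    if d <= 0:
        raise ValueError("degenerate marker matrix: zero variance after centering")
    K = K / d
    return RelationshipMatrix((K + K.T) / 2.0, ids=ids, label="centered_ibs")


def trait_kernel(S: np.ndarray, ids: list[str] | None = None, tol: float = 1e-6) -> RelationshipMatrix:
    """Secondary-trait kernel ``H = S S^T / q`` from standardized trait BLUEs.

    ``S`` must have centered, unit-SD columns (checked); duplicating columns
    leaves ``H`` unchanged because the normalizer scales with ``q``.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] < 1:
        raise ValueError("S must be an n x q matrix with q >= 1")
    if np.abs(S.mean(axis=0)).max() > tol:
        raise ValueError("columns of S must be centered (mean beyond tolerance)")
    q = S.shape[1]
    H = S @ S.T / q
    return RelationshipMatrix((H + H.T) / 2.0, ids=ids, label="trait_kernel")


def gaussian_kernels(
    D: np.ndarray,
    bandwidths: tuple[float, ...] = DEFAULT_BANDWIDTHS,
    ids: list[str] | None = None,
) -> list[RelationshipMatrix]:
    """Gaussian kernels ``exp(-h D_ij / dbar)`` for each bandwidth ``h``.

    ``D`` is a squared-distance matrix (symmetric, zero diagonal,
    non-negative) and ``dbar`` the mean off-diagonal entry, so the kernel
    argument is scale-free.  The default bandwidths {1/5, 1, 5} support
    kernel averaging by fitting one random-effect term per kernel.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8 * max(1.0, np.abs(D).max())):
        raise ValueError("D must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-12 * max(1.0, np.abs(D).max()):
        raise ValueError("D must have a zero diagonal")
    if D.min() < 0:
        raise ValueError("D must be non-negative")
    off = ~np.eye(n, dtype=bool)
    dbar = D[off].mean() if n > 1 else 1.0
    if dbar <= 0:
        raise ValueError("mean off-diagonal distance must be positive")
    out = []
    for h in bandwidths:
        if h <= 0:
            raise ValueError("bandwidths must be positive")
        K = np.exp(-h * D / dbar)
        np.fill_diagonal(K, 1.0)
        out.append(RelationshipMatrix((K + K.T) / 2.0, ids=ids, label=f"gaussian_h{h:g}"))
    return out


def eigendecompose(K: RelationshipMatrix) -> RelationshipMatrix:
    """Populate the spectral fields of a RelationshipMatrix (in place)."""
    K.eigendecomposition()
    return K
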