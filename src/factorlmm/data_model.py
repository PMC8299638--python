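"""Core domain types and phenotype/relationship-matrix I/O.

The central object is :class:`TraitMatrix`: an ``n x t`` matrix of phenotypic
observations for ``n`` observational units (plants, plots, lines, ...) and
``t`` traits, with an explicit boolean mask for missing cells.  Units are in
rows, traits in columns, matching the usual layout of breeding-program
phenotype tables.  A :class:`ModelSpec` collects the design of the mixed
model fitted to a TraitMatrix: fixed-effect covariates (split into columns
with flat priors and columns with proper shrinkage priors), one or more
random-effect terms, each defined by an incidence matrix and a positive
semi-definite relationship matrix, and the number of latent factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "TraitPartition",
    "RelationshipMatrix",
    "RandomEffectTerm",
    "ModelSpec",
    "ScalingRecord",
    "load_phenotypes",
    "write_phenotypes",
    "load_relationship_matrix",
    "write_relationship_matrix",
    "load_markers",
    "partition_traits",
    "center_scale",
]

#: tokens (lower-cased) interpreted as missing cells in delimited files;
#: covers both R- and Python-exported tables.
MISSING_TOKENS = {"", "na", "nan"}


def _infer_sep(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


@dataclass
class TraitPartition:
    """A group of traits sharing (or merged under) one missingness pattern.

    ``missing_pattern[i]`` is True when row ``i`` is missing for the member
    traits (the union pattern when patterns were merged under the partition
    cap).
    """

    trait_indices: np.ndarray
    missing_pattern: np.ndarray


@dataclass
class TraitMatrix:
    """An ``n x t`` phenotype matrix with missing-cell mask and partitions."""

    values: np.ndarray
    mask: np.ndarray  # True = observed
    unit_ids: list[str]
    trait_ids: list[str]
    partitions: list[TraitPartition] = field(default_factory=list)
    cv_test_units: np.ndarray | None = None  # set by cross-validation scenarios

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.unit_ids), len(self.trait_ids)):
            raise ValueError("values shape inconsistent with id lists")
        if self.partitions:
            self._check_partitions()

    def _check_partitions(self) -> None:
        seen = np.concatenate([p.trait_indices for p in self.partitions])
        if len(seen) != self.t or len(np.unique(seen)) != self.t:
            raise ValueError("partitions must be disjoint and cover all traits")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            self.values.copy(),
            self.mask.copy(),
            list(self.unit_ids),
            list(self.trait_ids),
            [TraitPartition(p.trait_indices.copy(), p.missing_pattern.copy()) for p in self.partitions],
            None if self.cv_test_units is None else self.cv_test_units.copy(),
        )

    def observed_values(self, j: int) -> np.ndarray:
        """Observed entries of trait column ``j``."""
        return self.values[self.mask[:, j], j]


@dataclass
class RelationshipMatrix:
    """A square symmetric PSD relationship/kernel matrix with spectral cache.

    The eigendecomposition is computed lazily (many operations in the sampler
    and the REML baselines run in the rotated basis where the matrix is
    diagonal) and eigenvalues within ``-tol`` of zero are clipped at zero.
    """

    matrix: np.ndarray
    ids: list[str] | None = None
    label: str = "K"
    _eigvals: np.ndarray | None = field(default=None, repr=False)
    _eigvecs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("relationship matrix must be symmetric")
        if self.ids is not None and len(self.ids) != m.shape[0]:
            raise ValueError("id list length does not match matrix dimension")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(eigenvalues, eigenvectors)``, clipping tiny negatives.

        Raises if an eigenvalue is below ``-tol`` (non-PSD input), with
        ``tol = 1e-10 * max eigenvalue`` (at least 1e-12 in absolute terms).
        """
        if self._eigvals is None:
            d, q = np.linalg.eigh((self.matrix + self.matrix.T) / 2.0)
            tol = max(1e-8 * max(1.0, d.max()), 1e-12)
            if d.min() < -tol:
                raise ValueError(
                    f"relationship matrix '{self.label}' is not PSD "
                    f"(min eigenvalue {d.min():.3e})"
                )
            self._eigvals = np.clip(d, 0.0, None)
            self._eigvecs = q
        return self._eigvals, self._eigvecs

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.eigendecomposition()[0]

    @property
    def eigenvectors(self) -> np.ndarray:
        return self.eigendecomposition()[1]


@dataclass
class RandomEffectTerm:
    """One random-effect term ``Z_m u_m`` with ``u_m ~ N(0, K_m, G_m)``.

    ``Z`` may be None for the common case of one observation per unit
    (identity incidence).
    """

    Kmat: RelationshipMatrix
    Z: np.ndarray | None = None
    label: str = ""

    def incidence(self, n: int) -> np.ndarray:
        if self.Z is None:
            if self.Kmat.dim != n:
                raise ValueError("identity incidence requires K dimension == n")
            return np.eye(n)
        return np.asarray(self.Z, dtype=float)

    def validate(self, n: int) -> None:
        if self.Z is not None:
            Z = np.asarray(self.Z)
            if Z.shape != (n, self.Kmat.dim):
                raise ValueError(
                    f"incidence matrix shape {Z.shape} incompatible with "
                    f"n={n} and K dimension {self.Kmat.dim}"
                )
        elif self.Kmat.dim != n:
            raise ValueError("identity incidence requires K dimension == n")

    @property
    def r(self) -> int:
        return self.Kmat.dim

    def is_identity(self, n: int) -> bool:
        if self.Z is None:
            return self.Kmat.dim == n
        Z = np.asarray(self.Z)
        return Z.shape[0] == Z.shape[1] == n and np.array_equal(Z, np.eye(n))


@dataclass
class ModelSpec:
    """Design of the mixed-effect factor model for one TraitMatrix."""

    terms: list[RandomEffectTerm]
    K: int | None  # None = choose min(n/4, t/2) at fit time
    X1: np.ndarray | None = None  # flat-prior covariates (defaults to intercept)
    X2: np.ndarray | None = None  # shrinkage-prior covariates
    hyper: dict = field(default_factory=dict)

    def resolve(self, n: int) -> None:
        """Fill defaults and validate against a data set with ``n`` rows."""
        if self.X1 is None:
            self.X1 = np.ones((n, 1))
        self.X1 = np.atleast_2d(np.asarray(self.X1, dtype=float))
        if self.X1.shape[0] != n:
            raise ValueError("X1 row count != n")
        if self.X1.shape[1] < 1:
            raise ValueError("X1 must have at least one column (intercept)")
        if np.linalg.matrix_rank(self.X1) < self.X1.shape[1]:
            raise ValueError("X1 must have full column rank")
        if self.X2 is None:
            self.X2 = np.zeros((n, 0))
        self.X2 = np.asarray(self.X2, dtype=float).reshape(n, -1)
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not self.terms:
            raise ValueError("at least one random-effect term is required")
        for term in self.terms:
            term.validate(n)

    @property
    def M(self) -> int:
        return len(self.terms)

    @property
    def b1(self) -> int:
        return self.X1.shape[1]

    @property
    def b2(self) -> int:
        return self.X2.shape[1]


@dataclass
class ScalingRecord:
    """Per-trait mean and scale used to standardize a TraitMatrix."""

    means: np.ndarray
    scales: np.ndarray
    trait_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.scales) <= 0):
            raise ValueError("all scales must be positive")

    def inverse_values(self, values: np.ndarray) -> np.ndarray:
        """Map standardized values back to the original trait scale."""
        return values * self.scales + self.means

    def inverse_spread(self, values: np.ndarray) -> np.ndarray:
        """Back-transform scale-equivariant quantities (genetic values)."""
        return values * self.scales

    def inverse_covariance(self, cov: np.ndarray) -> np.ndarray:
        """Back-transform a t x t covariance of standardized traits."""
        return cov * np.outer(self.scales, self.scales)

    @classmethod
    def identity(cls, trait_ids: list[str]) -> "ScalingRecord":
        t = len(trait_ids)
        return cls(np.zeros(t), np.ones(t), list(trait_ids))


# ---------------------------------------------------------------------------
# readers / writers


def load_phenotypes(path: str, sep: str | None = None) -> TraitMatrix:
    """Read a delimited phenotype table (units x traits) into a TraitMatrix.

    The file must have a header row of trait ids and a first column of unit
    ids.  Empty cells and the tokens NA/NaN (case-insensitive) mark missing
    values.  Duplicate unit ids and non-numeric non-missing cells are errors;
    a fully missing trait is retained with a warning.
    """
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    unit_ids = [str(u) for u in df.index]
    if len(set(unit_ids)) != len(unit_ids):
        dupes = sorted({u for u in unit_ids if unit_ids.count(u) > 1})
        raise ValueError(f"duplicate unit ids: {dupes}")
    trait_ids = [str(c) for c in df.columns]
    raw = df.to_numpy(dtype=object)
    n, t = raw.shape
    values = np.zeros((n, t))
    mask = np.ones((n, t), dtype=bool)
    for i in range(n):
        for j in range(t):
            tok = str(raw[i, j]).strip()
            if tok.lower() in MISSING_TOKENS:
                mask[i, j] = False
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"non-numeric cell at unit '{unit_ids[i]}', trait "
                        f"'{trait_ids[j]}': {tok!r}"
                    ) from exc
    for j in range(t):
        if not mask[:, j].any():
            warnings.warn(f"trait '{trait_ids[j]}' is fully missing; retained")
    return TraitMatrix(values, mask, unit_ids, trait_ids)


def write_phenotypes(tm: TraitMatrix, path: str, sep: str | None = None) -> None:
    sep = sep or _infer_sep(path)
    out = tm.values.astype(object).copy()
    out[~tm.mask] = "NA"
    df = pd.DataFrame(out, index=tm.unit_ids, columns=tm.trait_ids)
    df.to_csv(path, sep=sep, index_label="unit")


def load_relationship_matrix(path: str, sep: str | None = None, label: str = "K") -> RelationshipMatrix:
    """Read a square delimited relationship matrix with matching ids."""
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if ids != col_ids:
        raise ValueError("relationship matrix row and column ids differ")
    return RelationshipMatrix(df.to_numpy(dtype=float), ids=ids, label=label)


def write_relationship_matrix(K: RelationshipMatrix, path: str, sep: str | None = None) -> None:
    sep = sep or _infer_sep(path)
    ids = K.ids if K.ids is not None else [str(i) for i in range(K.dim)]
    pd.DataFrame(K.matrix, index=ids, columns=ids).to_csv(path, sep=sep, index_label="unit")


def load_markers(path: str, sep: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a 0/1/2 dosage matrix, ignoring non-dosage columns.

    Accepts PLINK ``.raw``-style tables: columns whose non-missing values are
    not all in {0, 1, 2} (e.g. FID/PAT/SEX) are dropped.  Returns the dosage
    matrix (with NaN for missing calls) and the unit ids.
    """
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    keep = []
    for c in df.columns:
        col = pd.to_numeric(df[c], errors="coerce")
        vals = col.dropna().unique()
        if len(vals) and np.all(np.isin(vals, [0.0, 1.0, 2.0])):
            keep.append(c)
    if not keep:
        raise ValueError("no dosage (0/1/2) columns found")
    markers = df[keep].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return markers, [str(i) for i in df.index]


# ---------------------------------------------------------------------------
# trait partitioning and standardization


def partition_traits(
    tm: TraitMatrix,
    strategy: str = "by_missing_pattern",
    user_groups: list[list[int]] | None = None,
    max_partitions: int = 20,
) -> TraitMatrix:
    """Group traits into partitions of shared missingness pattern.

    Under ``by_missing_pattern``, traits whose mask columns are identical
    share a partition.  If more than ``max_partitions`` distinct patterns
    exist, the smallest groups are merged into one partition carrying the
    union of their missing patterns, bounding the sampler's bookkeeping.
    Under ``user_groups``, the given index groups must be disjoint and cover
    all traits.
    """
    out = tm.copy()
    if strategy == "user_groups":
        if user_groups is None:
            raise ValueError("user_groups strategy requires explicit groups")
        seen: set[int] = set()
        parts = []
        for g in user_groups:
            idx = np.asarray(sorted(g), dtype=int)
            if seen & set(idx.tolist()):
                raise ValueError("user groups overlap")
            seen.update(idx.tolist())
            missing = ~np.all(tm.mask[:, idx], axis=1)
            parts.append(TraitPartition(idx, missing))
        if seen != set(range(tm.t)):
            raise ValueError("user groups do not cover all traits")
        out.partitions = parts
        return out
    if strategy != "by_missing_pattern":
        raise ValueError(f"unknown partitioning strategy: {strategy!r}")

    patterns: dict[bytes, list[int]] = {}
    for j in range(tm.t):
        patterns.setdefault(tm.mask[:, j].tobytes(), []).append(j)
    groups = sorted(patterns.values(), key=len, reverse=True)
    if len(groups) > max_partitions:
        head, tail = groups[: max_partitions - 1], groups[max_partitions - 1 :]
        merged = sorted(j for g in tail for j in g)
        groups = head + [merged]
    parts = []
    for g in groups:
        idx = np.asarray(g, dtype=int)
        missing = ~np.all(tm.mask[:, idx], axis=1)
        parts.append(TraitPartition(idx, missing))
    out.partitions = parts
    return out


def center_scale(tm: TraitMatrix) -> tuple[TraitMatrix, ScalingRecord]:
    """Standardize each trait to mean 0, unit SD over its observed cells.

    The shrinkage-prior defaults assume unit-scale traits, so this is applied
    by default before fitting; the returned :class:`ScalingRecord` supports
    exact back-transformation of posterior functionals.
    """
    means = np.zeros(tm.t)
    scales = np.zeros(tm.t)
    for j in range(tm.t):
        obs = tm.observed_values(j)
        if len(obs) < 2:
            raise ValueError(f"trait '{tm.trait_ids[j]}' has fewer than 2 observed values")
        sd = float(np.std(obs, ddof=1))
        if sd == 0.0:
            raise ValueError(f"trait '{tm.trait_ids[j]}' is constant; cannot standardize")
        means[j] = float(np.mean(obs))
        scales[j] = sd
    out = tm.copy()
    out.values = (tm.values - means) / scales
    out.values[~out.mask] = np.nan
    return out, ScalingRecord(means, scales, list(tm.trait_ids))
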