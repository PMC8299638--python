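"""Posterior functionals and chain summaries.

The factor parameterization implies closed-form trait covariance matrices
for every draw:

    G_m = Psi_Rm + Lambda' Psi_Fm Lambda      (genetic / term-m covariance)
    R   = Psi_RE + Lambda' Psi_FE Lambda      (residual covariance)

so covariances, genetic values ``u_m = U_Rm + U_Fm Lambda``, and imputed
phenotypes ``Y~ = X1 B1 + F Lambda + Z U_R`` are assembled per draw without
ever inverting a t x t matrix.  Predictions for lines absent from the fit
use the conditional-Gaussian (Schur-complement) extrapolation
``u_new = K_no K_oo^{-1} u_old`` applied draw by draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import RelationshipMatrix, ScalingRecord

__all__ = [
    "PosteriorSamples",
    "assemble_covariance",
    "assemble_genetic_covariance",
    "assemble_residual_covariance",
    "genetic_values",
    "impute_phenotypes",
    "predict_new_lines",
    "summarize",
    "summary_table",
    "hpd_interval",
    "effective_sample_size",
    "factor_representation",
]


@dataclass
class PosteriorSamples:
    """Thinned posterior draws of user-selected functionals."""

    draws: dict[str, np.ndarray]
    unit_ids: list[str]
    trait_ids: list[str]
    scaling: ScalingRecord
    seed: int
    config: dict
    final_state: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        counts = {k: v.shape[0] for k, v in self.draws.items() if v.ndim > 0}
        if len(set(counts.values())) > 1:
            raise ValueError(f"functionals disagree on sample count: {counts}")

    @property
    def n_samples(self) -> int:
        if not self.draws:
            return 0
        return next(iter(self.draws.values())).shape[0]

    def get(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"functional {name!r} not stored; have {sorted(self.draws)}")
        return self.draws[name]

    def mean(self, name: str) -> np.ndarray:
        return self.get(name).mean(axis=0)

    # --- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        """Write draws and metadata to one HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("draws")
            for k, v in self.draws.items():
                g.create_dataset(k, data=v)
            f.attrs["config"] = json.dumps(self.config)
            f.attrs["seed"] = self.seed
            f.create_dataset("unit_ids", data=np.array(self.unit_ids, dtype="S"))
            f.create_dataset("trait_ids", data=np.array(self.trait_ids, dtype="S"))
            sg = f.create_group("scaling")
            sg.create_dataset("means", data=self.scaling.means)
            sg.create_dataset("scales", data=self.scaling.scales)

    @classmethod
    def load(cls, path: str) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as f:
            draws = {k: f["draws"][k][...] for k in f["draws"]}
            unit_ids = [s.decode() for s in f["unit_ids"][...]]
            trait_ids = [s.decode() for s in f["trait_ids"][...]]
            scaling = ScalingRecord(
                f["scaling/means"][...], f["scaling/scales"][...], trait_ids
            )
            return cls(
                draws=draws,
                unit_ids=unit_ids,
                trait_ids=trait_ids,
                scaling=scaling,
                seed=int(f.attrs["seed"]),
                config=json.loads(f.attrs["config"]),
            )


# ---------------------------------------------------------------------------
# per-draw assemblies


def assemble_covariance(Lambda: np.ndarray, psi_factor: np.ndarray, psi_idio: np.ndarray) -> np.ndarray:
    """``diag(psi_idio) + Lambda' diag(psi_factor) Lambda`` (symmetrized)."""
    t = len(psi_idio)
    out = np.diag(np.asarray(psi_idio, dtype=float)).astype(float)
    if Lambda.size:
        out = out + Lambda.T @ (np.asarray(psi_factor)[:, None] * Lambda)
    return (out + out.T) / 2.0


def assemble_genetic_covariance(state, m: int = 0) -> np.ndarray:
    """Term-m trait covariance ``G_m = Psi_Rm + Lambda' Psi_Fm Lambda``."""
    if not 0 <= m < state.spec.M:
        raise IndexError(f"term index {m} out of range (M={state.spec.M})")
    return assemble_covariance(state.Lambda, state.psi_F(m), state.psi_R(m))


def assemble_residual_covariance(state) -> np.ndarray:
    """Residual trait covariance ``R = Psi_RE + Lambda' Psi_FE Lambda``."""
    return assemble_covariance(state.Lambda, state.psi_FE, state.psi_RE)


def genetic_values(state, m: int = 0, scaling: ScalingRecord | None = None) -> np.ndarray:
    """Per-draw genetic values for term m: ``U_Rm + U_Fm Lambda`` (line basis)."""
    if not 0 <= m < state.spec.M:
        raise IndexError(f"term index {m} out of range (M={state.spec.M})")
    sl = state.term_slices()[m]
    U = state.U_R[sl].copy()
    if state.K:
        U = U + state.U_F[sl] @ state.Lambda
    if state.cache.is_spectral:
        U = state.cache.from_working(U)
    if scaling is not None:
        U = scaling.inverse_spread(U)
    return U


def impute_phenotypes(state, scaling: ScalingRecord | None = None) -> np.ndarray:
    """Model-smoothed phenotype surface ``X1 B1 (+X2 B2R) + F Lambda + Z U_R``.

    Observed cells may differ from the data: this is the model's mean value
    for every cell, not the datum.
    """
    out = state.cache.from_working(state.mean_w())
    if scaling is not None:
        out = scaling.inverse_values(out)
    return out


def factor_representation(G_list: list[np.ndarray], R: np.ndarray) -> dict:
    """Constructive parameters reproducing arbitrary PD targets exactly.

    With ``K = t (M + 1)`` loadings rows, stacking the Cholesky transposes of
    each G_m and of R into Lambda and switching each block on in exactly one
    Psi matrix reproduces any set of positive-definite targets:
    ``G_m = Lambda' Psi_Fm Lambda`` with ``Psi_Rm = 0`` (and likewise for R).
    """
    t = R.shape[0]
    M = len(G_list)
    blocks = [np.linalg.cholesky(G).T for G in G_list] + [np.linalg.cholesky(R).T]
    Lambda = np.vstack(blocks)  # (t(M+1), t)
    K = Lambda.shape[0]
    psi_F = []
    for m in range(M):
        v = np.zeros(K)
        v[m * t : (m + 1) * t] = 1.0
        psi_F.append(v)
    psi_FE = np.zeros(K)
    psi_FE[M * t :] = 1.0
    return {
        "Lambda": Lambda,
        "psi_F": psi_F,
        "psi_FE": psi_FE,
        "psi_R": [np.zeros(t) for _ in range(M)],
        "psi_RE": np.zeros(t),
    }


# ---------------------------------------------------------------------------
# predictions for unphenotyped lines


def predict_new_lines(
    K_joint: RelationshipMatrix,
    samples: PosteriorSamples,
    functional: str = "genetic_values",
    prob: float = 0.95,
) -> dict:
    """Schur-complement extrapolation of genetic values to new lines.

    For each posterior draw, ``u_new = K_no K_oo^{-1} u_old`` using the
    kinship blocks between the fitted ("old") lines and the new ones; the
    ``K_oo`` inverse is ridge-stabilized with ``1e-8 tr(K_oo)/n_o``.
    Returns the posterior mean and HPD bounds per new line and trait.
    """
    if K_joint.ids is None:
        raise ValueError("K_joint must carry line ids")
    ids = list(K_joint.ids)
    pos = {u: i for i, u in enumerate(ids)}
    missing = [u for u in samples.unit_ids if u not in pos]
    if missing:
        raise ValueError(f"fitted lines absent from K_joint: {missing[:5]}")
    old_idx = np.array([pos[u] for u in samples.unit_ids])
    new_ids = [u for u in ids if u not in set(samples.unit_ids)]
    if not new_ids:
        raise ValueError("K_joint contains no new lines")
    new_idx = np.array([pos[u] for u in new_ids])
    K = K_joint.matrix
    K_oo = K[np.ix_(old_idx, old_idx)]
    K_no = K[np.ix_(new_idx, old_idx)]
    n_o = len(old_idx)
    ridge = 1e-8 * np.trace(K_oo) / n_o
    K_oo_r = K_oo + ridge * np.eye(n_o)
    try:
        coef = np.linalg.solve(K_oo_r, K_no.T)  # (n_o, n_new)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("K_oo numerically singular after ridge") from exc
    u_old = samples.get(functional)  # (S, n_o, t)
    u_new = np.einsum("on,sot->snt", coef, u_old)
    lo, hi = hpd_interval(u_new, prob=prob, axis=0)
    return {
        "new_ids": new_ids,
        "mean": u_new.mean(axis=0),
        "hpd_lo": lo,
        "hpd_hi": hi,
        "draws": u_new,
    }


# ---------------------------------------------------------------------------
# summaries


def hpd_interval(x: np.ndarray, prob: float = 0.95, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shortest interval containing ``prob`` posterior mass, elementwise.

    Computed by scanning windows of fixed mass over the sorted draws.
    """
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, 0)
    S = x.shape[0]
    if S < 2:
        raise ValueError("need at least 2 draws")
    m = max(1, int(np.ceil(prob * S)))
    if m >= S:
        m = S - 1
    xs = np.sort(x, axis=0)
    widths = xs[m:] - xs[: S - m]
    best = np.argmin(widths, axis=0)
    lo = np.take_along_axis(xs, best[None], axis=0)[0]
    hi = np.take_along_axis(xs, (best + m)[None], axis=0)[0]
    return lo, hi


def summarize(samples: PosteriorSamples, functional: str, prob: float = 0.95) -> dict:
    """Elementwise posterior mean, sd, and HPD interval of one functional."""
    x = samples.get(functional)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 draws to summarize")
    lo, hi = hpd_interval(x, prob=prob, axis=0)
    return {
        "mean": x.mean(axis=0),
        "sd": x.std(axis=0, ddof=1),
        "hpd_lo": lo,
        "hpd_hi": hi,
    }


def summary_table(samples: PosteriorSamples, functional: str, prob: float = 0.95) -> pd.DataFrame:
    """Tidy table: one row per element with mean, sd, HPD bounds, and ESS."""
    x = samples.get(functional)
    s = summarize(samples, functional, prob=prob)
    flat = x.reshape(x.shape[0], -1)
    ess = np.array([effective_sample_size(flat[:, i]) for i in range(flat.shape[1])])
    idx = [
        "/".join(map(str, np.unravel_index(i, x.shape[1:])))
        for i in range(flat.shape[1])
    ]
    return pd.DataFrame(
        {
            "functional": functional,
            "element": idx,
            "mean": s["mean"].ravel(),
            "sd": s["sd"].ravel(),
            "hpd_lo": s["hpd_lo"].ravel(),
            "hpd_hi": s["hpd_hi"].ravel(),
            "ess": ess,
        }
    )


def effective_sample_size(chain: np.ndarray) -> float:
    """Rank-normalized split-chain bulk effective sample size.

    Returns NaN (undefined) for constant chains; requires length >= 4.
    Convergence monitoring flags elements with ESS below the usual target of
    1000 for reliable posterior summaries.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("chain must have length >= 4")
    if np.allclose(x, x[0]):
        return float("nan")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz

        return float(arviz.ess(x[None, :], method="bulk"))
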