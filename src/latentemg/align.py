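"""CCA alignment of latent neural signals across subjects or sessions.

Given two sets of latent signals S (source) and T (target) with one-to-one
time correspondence — obtained by ordering trials by target direction and
concatenating — canonical correlation analysis finds transforms C_S, C_T that
maximize the correlation between C_S-transformed S and C_T-transformed T.
Because both sets are transformed, the target signals are then mapped back
into the source coordinate frame through the inverse of the source transform:

    T_aligned = C_T(T) @ C_S^{-1} (+ source mean)

so that a decoder fitted in source coordinates can consume them directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CCAAligner", "fit_cca", "apply_alignment", "identity_aligner",
           "similarity_r2"]

_COND_LIMIT = 1e8


@dataclass
class CCAAligner:
    mean_S: np.ndarray
    mean_T: np.ndarray
    C_S: np.ndarray                     # (p, p); (S - mean_S) @ C_S = source variates
    C_T: np.ndarray                     # (p, p)
    C_S_inverse: np.ndarray             # (p, p)
    canonical_correlations: np.ndarray  # (p,), non-increasing

    @property
    def p(self) -> int:
        return self.C_S.shape[0]


def _whitener(cov: np.ndarray, side: str) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 0 or w[0] < w[-1] * 1e-12:
        raise np.linalg.LinAlgError(
            f"rank-deficient covariance on the {side} side of CCA")
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def fit_cca(S: np.ndarray, T: np.ndarray) -> CCAAligner:
    """Fit centered CCA between equally sampled latent matrices S and T.

    Solved by whitening each block and taking the SVD of the whitened
    cross-covariance; canonical variates have unit variance (ddof=1
    convention) and maximal pairwise correlation.  Sign convention: the
    first nonzero source weight of each variate pair is positive.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape[0] != T.shape[0]:
        raise ValueError(f"sample counts differ: {S.shape[0]} vs {T.shape[0]}")
    m, p = S.shape
    if m <= max(p, T.shape[1]):
        raise ValueError("need more samples than latent dimensions")
    mean_S, mean_T = S.mean(axis=0), T.mean(axis=0)
    Sc, Tc = S - mean_S, T - mean_T
    n1 = m - 1
    Css = Sc.T @ Sc / n1
    Ctt = Tc.T @ Tc / n1
    Cst = Sc.T @ Tc / n1
    Ks = _whitener(Css, "S")
    Kt = _whitener(Ctt, "T")
    U, d, Vt = np.linalg.svd(Ks @ Cst @ Kt)
    C_S = Ks @ U
    C_T = Kt @ Vt.T
    for j in range(C_S.shape[1]):
        nz = np.nonzero(np.abs(C_S[:, j]) > 1e-12)[0]
        if len(nz) and C_S[nz[0], j] < 0:
            C_S[:, j] = -C_S[:, j]
            C_T[:, j] = -C_T[:, j]
    if np.linalg.cond(C_S) > _COND_LIMIT:
        raise np.linalg.LinAlgError("source CCA transform is ill-conditioned")
    C_S_inv = np.linalg.solve(C_S, np.eye(C_S.shape[0]))
    return CCAAligner(mean_S, mean_T, C_S, C_T, C_S_inv,
                      np.clip(d, 0.0, 1.0))


def apply_alignment(aligner: CCAAligner, T: np.ndarray) -> np.ndarray:
    """Express target latents in the source coordinate frame.

    T_aligned = ((T - mean_T) @ C_T) @ C_S^{-1} + mean_S.  The source mean is
    re-added because the downstream decoder's intercept was fitted in source
    coordinates.
    """
    T = np.asarray(T, dtype=float)
    if T.shape[1] != aligner.p:
        raise ValueError(f"latent dimension {T.shape[1]} does not match "
                         f"aligner p={aligner.p}")
    return ((T - aligner.mean_T) @ aligner.C_T) @ aligner.C_S_inverse + aligner.mean_S


def identity_aligner(p: int) -> CCAAligner:
    """A no-op aligner (used as the ablation control for alignment)."""
    eye = np.eye(p)
    z = np.zeros(p)
    return CCAAligner(z, z, eye, eye, eye, np.ones(p))


def similarity_r2(S: np.ndarray, X: np.ndarray) -> float:
    """Variance-weighted coefficient of determination of X against S.

    Per-dimension R^2 = 1 - SSE/SST with S as the reference, averaged with
    weights proportional to each source dimension's variance.  Can be
    negative; zero-variance source dimensions are excluded with a warning.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    if S.shape != X.shape:
        raise ValueError("shape mismatch")
    sst = ((S - S.mean(axis=0)) ** 2).sum(axis=0)
    keep = sst > 0
    if not keep.all():
        warnings.warn("zero-variance source dimensions excluded from similarity")
    if not keep.any():
        raise ValueError("all source dimensions have zero variance")
    sse = ((S - X) ** 2).sum(axis=0)
    r2 = 1.0 - sse[keep] / sst[keep]
    w = sst[keep]
    return float(np.sum(w * r2) / np.sum(w))
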