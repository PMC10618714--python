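"""Latent-space estimation: PCA manifolds and Parallel Analysis.

Population firing rates are projected onto a low-dimensional neural manifold
with PCA; the manifold dimensionality used throughout the pipeline defaults
to 13, an upper bound on the linear dimensionality of motor-cortical
recordings in the isometric wrist task as estimated by Parallel Analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RateMatrix

__all__ = ["PCAModel", "LatentMatrix", "fit_pca", "project", "parallel_analysis"]

#: default manifold dimensionality
DEFAULT_P = 13


@dataclass
class PCAModel:
    mean: np.ndarray          # (n_channels,)
    components: np.ndarray    # (p, n_channels), orthonormal rows
    eigenvalues: np.ndarray   # (p,), non-increasing

    @property
    def p(self) -> int:
        return self.components.shape[0]


# A LatentMatrix is simply an (samples, p) ndarray; the alias documents intent.
LatentMatrix = np.ndarray


def _as_array(rates) -> np.ndarray:
    if isinstance(rates, RateMatrix):
        return rates.values
    return np.asarray(rates, dtype=float)


def fit_pca(rates, p: int = DEFAULT_P) -> PCAModel:
    """Centered PCA of time x channel rates via the sample covariance.

    Deterministic: eigendecomposition with a fixed sign convention (the
    largest-magnitude loading of each component is positive).
    """
    x = _as_array(rates)
    n, c = x.shape
    if p > c:
        raise ValueError(f"p={p} exceeds channel count {c}")
    if n <= p:
        raise ValueError(f"need more than p={p} samples, got {n}")
    mean = x.mean(axis=0)
    cov = np.cov(x - mean, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    idx = np.argsort(w)[::-1][:p]
    eig = np.maximum(w[idx], 0.0)
    comps = v[:, idx].T
    for i in range(p):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(mean, comps, eig)


def project(model: PCAModel, rates) -> LatentMatrix:
    """Project rates into the manifold: (rates - mean) @ components.T."""
    x = _as_array(rates)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(f"channel count {x.shape[1]} does not match model "
                         f"({model.mean.shape[0]})")
    return (x - model.mean) @ model.components.T


def parallel_analysis(rates, n_shuffles: int = 100, percentile: float = 95.0,
                      seed: int | None = None) -> int:
    """Horn-style Parallel Analysis estimate of linear dimensionality.

    Counts the leading covariance eigenvalues that exceed the given
    percentile of eigenvalues obtained from surrogate data in which each
    channel is independently permuted across time (destroying cross-channel
    correlation while preserving marginals).  The count stops at the first
    eigenvalue that fails the comparison.
    """
    x = _as_array(rates)
    n, c = x.shape
    if c < 2:
        raise ValueError("need at least 2 channels")
    if n < 100:
        raise ValueError("need at least 100 samples")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        return 0
    real = np.sort(np.linalg.eigvalsh(np.cov(xc, rowvar=False, ddof=1)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, c))
    shuf = xc.copy()
    for s in range(n_shuffles):
        for ch in range(c):
            rng.shuffle(shuf[:, ch])
        null[s] = np.sort(np.linalg.eigvalsh(np.cov(shuf, rowvar=False, ddof=1)))[::-1]
    thresh = np.percentile(null, percentile, axis=0)
    above = real > thresh
    k = 0
    while k < c and above[k]:
        k += 1
    return k
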