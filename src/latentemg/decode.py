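"""Wiener-filter EMG decoding from lagged latent neural signals.

The decoder is a linear regression from the latent signals over a short
history (5 bins = 100 ms by default) to the EMG envelope at the current bin,
followed by rectification to match the nonnegative statistics of EMG
envelopes.  Three configurations are supported:

* within-subject — latents and EMG from the same subject/session;
* direct — target-subject latents regressed onto source-subject EMG over
  trials matched by target direction;
* transfer — a fixed source-subject decoder applied to the target subject's
  CCA-aligned latents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import CCAAligner, apply_alignment
from .preprocess import EMGEnvelope

__all__ = [
    "WienerDecoder",
    "trial_bounds_for",
    "build_lagged_design",
    "fit_wiener",
    "predict",
    "train_direct",
    "transfer_decode",
]


@dataclass
class WienerDecoder:
    weights: np.ndarray       # (p*n_lags + 1, n_muscles), intercept row first
    n_lags: int
    bin_width: float = 0.02
    muscle_names: list[str] | None = None

    @property
    def p(self) -> int:
        return (self.weights.shape[0] - 1) // self.n_lags

    @property
    def history_span(self) -> float:
        """Temporal span of the filter history in seconds (default 100 ms)."""
        return self.n_lags * self.bin_width


def trial_bounds_for(n_trials: int, trial_len: int) -> list[tuple[int, int]]:
    """(start, stop) row ranges for equal-length concatenated trials."""
    return [(i * trial_len, (i + 1) * trial_len) for i in range(n_trials)]


def build_lagged_design(latents: np.ndarray, trial_bounds: list[tuple[int, int]],
                        n_lags: int = 5) -> np.ndarray:
    """Design matrix with an intercept and taps at lags 0 .. n_lags-1.

    Row t holds [1, L(t), L(t-1), ..., L(t-n_lags+1)].  The history never
    crosses a trial boundary: within each trial the first samples are padded
    by replicating the trial's first sample, which keeps the row count equal
    to the input row count (required for the cross-subject correspondence).
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    L = np.asarray(latents, dtype=float)
    n, p = L.shape
    design = np.empty((n, p * n_lags + 1))
    design[:, 0] = 1.0
    for start, stop in trial_bounds:
        seg = L[start:stop]
        for lag in range(n_lags):
            shifted = np.vstack([np.repeat(seg[:1], min(lag, len(seg)), axis=0),
                                 seg[: max(len(seg) - lag, 0)]])
            design[start:stop, 1 + lag * p: 1 + (lag + 1) * p] = shifted
    return design


def fit_wiener(design: np.ndarray, emg, n_lags: int = 5, bin_width: float = 0.02,
               ridge: float = 0.0, muscle_names: list[str] | None = None) -> WienerDecoder:
    """Ordinary least squares per muscle (optionally ridge-stabilized).

    Raises on a rank-deficient design when ``ridge`` is zero, reporting the
    rank found versus the column count.
    """
    X = np.asarray(design, dtype=float)
    if isinstance(emg, EMGEnvelope):
        Y = emg.values
        muscle_names = muscle_names or emg.muscle_names
    else:
        Y = np.asarray(emg, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and EMG row counts differ")
    if ridge > 0:
        penalty = ridge * np.eye(X.shape[1])
        penalty[0, 0] = 0.0  # never penalize the intercept
        w = np.linalg.solve(X.T @ X + penalty, X.T @ Y)
    else:
        w, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design: rank {rank} < {X.shape[1]} columns")
    return WienerDecoder(w, n_lags, bin_width, muscle_names)


def predict(decoder: WienerDecoder, latents: np.ndarray,
            trial_bounds: list[tuple[int, int]]) -> np.ndarray:
    """Apply the linear filter and rectify the output at zero."""
    L = np.asarray(latents, dtype=float)
    if L.shape[1] != decoder.p:
        raise ValueError(f"latent dimension {L.shape[1]} does not match "
                         f"decoder p={decoder.p}")
    X = build_lagged_design(L, trial_bounds, decoder.n_lags)
    return np.maximum(X @ decoder.weights, 0.0)


def train_direct(target_latents: np.ndarray, source_emg,
                 trial_bounds: list[tuple[int, int]], n_lags: int = 5,
                 bin_width: float = 0.02, ridge: float = 0.0) -> WienerDecoder:
    """Fit a decoder from target-subject latents to source-subject EMG.

    Caller guarantees that target trials were matched one-to-one to source
    trials of the same (possibly mirrored) direction and concatenated in the
    same order; ``trial_bounds`` describes that shared layout.
    """
    X = build_lagged_design(target_latents, trial_bounds, n_lags)
    return fit_wiener(X, source_emg, n_lags, bin_width, ridge)


def transfer_decode(source_decoder: WienerDecoder, aligner: CCAAligner,
                    target_latents: np.ndarray,
                    trial_bounds: list[tuple[int, int]]) -> np.ndarray:
    """Run a fixed source decoder on CCA-aligned target latents."""
    aligned = apply_alignment(aligner, target_latents)
    return predict(source_decoder, aligned, trial_bounds)
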