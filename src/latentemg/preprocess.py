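"""Signal conditioning: spike smoothing, EMG envelopes, trial segmentation.

Spike counts in 20 ms non-overlapping bins are smoothed with a centered
Gaussian kernel (sd 100 ms by default) and scaled to Hz.  Raw EMG at 2 kHz is
rectified, low-passed (4-pole Butterworth, 10 Hz), downsampled to the 50 Hz
bin grid, clipped at mean + 6 sd, baseline-corrected by its 2nd percentile and
normalized by its 90th percentile — all statistics taken over the whole
session, per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, lfilter

__all__ = [
    "RateMatrix",
    "EMGEnvelope",
    "TrialTensor",
    "smooth_rates",
    "emg_envelope",
    "segment_trials",
    "order_concat",
    "mirror_labels",
]


@dataclass
class RateMatrix:
    """Smoothed firing rates, time x channel, in Hz on the bin grid."""

    values: np.ndarray
    bin_width: float = 0.02

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rates must be finite")
        if (self.values < 0).any():
            raise ValueError("rates must be nonnegative")


@dataclass
class EMGEnvelope:
    """Normalized EMG envelopes, time x muscle, at the 50 Hz bin rate."""

    values: np.ndarray
    sample_rate: float = 50.0
    muscle_names: list[str] | None = None
    excluded: list[str] | None = None


@dataclass
class TrialTensor:
    """Fixed-length trial windows: (trials, time, feature) plus labels."""

    data: np.ndarray
    labels: np.ndarray          # target direction in degrees, per trial
    start_offset: float         # window start relative to the anchor, s
    length: float               # window length, s
    bin_width: float = 0.02

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


def smooth_rates(spike_counts: np.ndarray, bin_width: float = 0.02,
                 sigma: float = 0.1) -> RateMatrix:
    """Gaussian-smooth binned spike counts and convert to Hz.

    The kernel has unit area and is truncated at +/-4 sigma; near the
    recording edges it is renormalized per sample so that constant input
    maps to constant rate everywhere.
    """
    counts = np.asarray(spike_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if (counts < 0).any():
        raise ValueError("spike counts must be nonnegative")
    sd_bins = sigma / bin_width
    half = int(np.ceil(4.0 * sd_bins))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
    kernel /= kernel.sum()
    n = counts.shape[0]
    smoothed = np.empty_like(counts)
    norm = np.convolve(np.ones(n), kernel, mode="same")
    for c in range(counts.shape[1]):
        smoothed[:, c] = np.convolve(counts[:, c], kernel, mode="same") / norm
    return RateMatrix(smoothed / bin_width, bin_width)


def emg_envelope(raw_emg: np.ndarray, fs: float = 2000.0, out_rate: float = 50.0,
                 lowpass_hz: float = 10.0, order: int = 4, clip_sds: float = 6.0,
                 baseline_pct: float = 2.0, norm_pct: float = 90.0,
                 muscle_names: list[str] | None = None,
                 zero_phase: bool = False) -> EMGEnvelope:
    """Extract normalized EMG envelopes from raw multichannel EMG.

    Per channel: full-wave rectify -> Butterworth lowpass -> downsample to
    ``out_rate`` -> clamp samples above mean + ``clip_sds``*sd -> subtract the
    ``baseline_pct`` percentile -> clip negatives at zero -> divide by the
    ``norm_pct`` percentile.  A channel whose normalization percentile is not
    positive is excluded with a warning.
    """
    raw = np.asarray(raw_emg, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw EMG must be finite")
    step = fs / out_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs must be an integer multiple of out_rate")
    step = int(round(step))
    names = muscle_names or [f"m{i}" for i in range(raw.shape[1])]

    b, a = butter(order, lowpass_hz, btype="low", fs=fs)
    rect = np.abs(raw)
    low = filtfilt(b, a, rect, axis=0) if zero_phase else lfilter(b, a, rect, axis=0)
    env = low[::step]

    keep, dropped, cols = [], [], []
    for i in range(env.shape[1]):
        ch = env[:, i]
        thr = ch.mean() + clip_sds * ch.std()
        ch = np.minimum(ch, thr)
        ch = ch - np.percentile(ch, baseline_pct)
        ch = np.maximum(ch, 0.0)
        p90 = np.percentile(ch, norm_pct)
        if p90 <= 0:
            warnings.warn(f"EMG channel {names[i]!r} is degenerate "
                          "(non-positive normalization percentile); excluded")
            dropped.append(names[i])
            continue
        cols.append(ch / p90)
        keep.append(names[i])
    values = np.stack(cols, axis=1) if cols else np.empty((env.shape[0], 0))
    return EMGEnvelope(values, out_rate, keep, dropped)


def segment_trials(values: np.ndarray, bin_width: float,
                   trial_table: pd.DataFrame, anchor: str = "onset",
                   start_offset: float = -0.5, length: float = 1.5) -> TrialTensor:
    """Cut fixed-length windows around per-trial anchors.

    ``anchor`` is ``"onset"`` (movement onset; default window -0.5 s to
    +1.0 s) or ``"go_cue"`` with a caller-supplied ``start_offset``.
    """
    if anchor not in ("onset", "go_cue"):
        raise ValueError("anchor must be 'onset' or 'go_cue'")
    col = "onset_s" if anchor == "onset" else "go_cue_s"
    arr = np.asarray(values, dtype=float)
    n_bins = int(round(length / bin_width))
    starts = np.round((trial_table[col].to_numpy() + start_offset) / bin_width).astype(int)
    bad = trial_table.loc[(starts < 0) | (starts + n_bins > arr.shape[0]), "trial_id"]
    if len(bad):
        raise ValueError(f"trial windows out of recording range for trials: "
                         f"{bad.tolist()}")
    data = np.stack([arr[s:s + n_bins] for s in starts], axis=0)
    labels = trial_table["target_deg"].to_numpy(dtype=float)
    return TrialTensor(data, labels, start_offset, length, bin_width)


def order_concat(trials: TrialTensor) -> tuple[np.ndarray, list[tuple[float, int, int]]]:
    """Sort trials by target direction (stable) and concatenate along time.

    Returns the (trials*time, feature) matrix and the label runs as
    ``(label, start_row, stop_row)`` tuples.  Ordering both subjects' trials
    this way establishes the one-to-one time correspondence that CCA needs.
    """
    order = np.argsort(trials.labels, kind="stable")
    data = trials.data[order]
    labels = trials.labels[order]
    nb = trials.n_bins
    mat = data.reshape(-1, data.shape[2])
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((float(labels[i]), i * nb, j * nb))
        i = j
    return mat, runs


def mirror_labels(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Reflect target directions about the vertical axis: theta -> (180 - theta).

    Up/down directions are fixed points; left and right swap.  Used when one
    subject's implant is in the opposite hemisphere.
    """
    out = trial_table.copy()
    out["target_deg"] = (180.0 - out["target_deg"].to_numpy()) % 360.0
    return out
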