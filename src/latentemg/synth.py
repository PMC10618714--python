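"""Synthetic multi-subject, multi-session neural/EMG recordings.

The generator emulates an eight-direction isometric wrist task: a shared
low-dimensional latent command signal drives both ~96-channel motor-cortical
populations (through subject-specific linear embeddings and a positive link,
with Poisson spiking) and direction-tuned EMG envelopes (through a cosine-tuned
linear readout).  Because every subject's population activity is an invertible
linear mixture of the *same* latent trajectories, cross-subject alignment and
decoding have a known ceiling, which is what makes the downstream pipeline
testable without real recordings.

Two acquisition modes are supported:

* ``monkey`` — stereotyped timing (fixed reaction time after the go cue) and
  raw 2 kHz EMG recorded alongside the spikes.
* ``human`` — emulates an iBCI user with paralysis: no recordable EMG,
  anticipatory neural onset preceding the go cue, per-trial timing jitter and
  per-trial response-gain variability, and (optionally) target labels mirrored
  about the vertical axis to account for an opposite-hemisphere implant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "Session",
    "generate_world",
    "generate_session",
]

# timeline layout (seconds); chosen so every probed segmentation window stays
# inside the recording for offsets in [-1.2, +0.3] around the go cue
_PRE_PAD = 1.0
_POST_PAD = 0.5
_REACTION = 0.25          # monkey movement onset lag after the go cue
_HUMAN_GO_IN_BLOCK = 1.5  # human go-cue position within its trial block
_TAIL_PAD = 2.0


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the simulated task and recording apparatus.

    ``anticipation_lead`` is the mean lead, in seconds, of the human
    subject's 1.5 s neural response window before the go cue; with zero
    jitter the decodable pattern occupies ``[go_cue - lead, go_cue - lead
    + trial_window]``.  ``timing_jitter_sd`` and ``trial_gain_sd`` add
    per-trial onset jitter and log-normal response-gain variability, and
    apply only to human-mode sessions; monkey-mode timing is stereotyped.
    """

    n_targets: int = 8
    latent_dim_true: int = 5
    n_channels: int = 96
    n_muscles: int = 5
    bin_width: float = 0.02
    trial_window: float = 1.5
    rate_scale: float = 50.0        # peak firing rate, Hz
    rate_median: float = 10.0       # median firing rate, Hz
    emg_noise_sd: float = 0.05      # envelope-relative amplitude noise
    timing_jitter_sd: float = 0.0   # s, human mode
    anticipation_lead: float = 0.0  # s, human mode
    trial_gain_sd: float = 0.0      # log-normal sigma, human mode
    mirror: bool = False            # mirror human target labels about vertical
    n_subjects: int = 3
    drift_rotation: float = 0.0     # rad of latent rotation per session step
    drift_gain_sd: float = 0.0      # log-gain sd per session step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if not (1 <= self.latent_dim_true <= self.n_channels):
            raise ValueError("latent_dim_true must be in [1, n_channels]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n = self.trial_window / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_window must be an integer multiple of bin_width")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def window_bins(self) -> int:
        return int(round(self.trial_window / self.bin_width))

    @property
    def target_angles(self) -> np.ndarray:
        return np.arange(self.n_targets) * (360.0 / self.n_targets)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorldConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class _SubjectModel:
    mixing: np.ndarray        # (d, d) invertible latent mixing
    embedding: np.ndarray     # (d, n_channels)
    offsets: np.ndarray       # (n_channels,)
    link_gain: float          # affine softplus calibration: rate = sp(a u + b)
    link_offset: float
    drift_plane: np.ndarray   # (d, 2) orthonormal axes of the drift rotation


@dataclass(frozen=True)
class SyntheticWorld:
    """Frozen ground truth shared by all sessions drawn from one config."""

    config: WorldConfig
    latent_templates: np.ndarray   # (n_targets, window_bins, d)
    muscle_readout: np.ndarray     # (d, n_muscles)
    muscle_pref_deg: np.ndarray    # (n_muscles,)
    subjects: tuple[_SubjectModel, ...] = field(repr=False, default=())

    def subject(self, subject_id: int) -> _SubjectModel:
        if not (0 <= int(subject_id) < len(self.subjects)):
            raise LookupError(f"unknown subject_id {subject_id!r}; "
                              f"world has {len(self.subjects)} subjects")
        return self.subjects[int(subject_id)]

    def session_drift(self, subject_id: int, session_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(d x d rotation, per-channel gains) for a given session index.

        Drift accumulates linearly with the session index: rotation by
        ``session_id * drift_rotation`` radians in a fixed subject-specific
        latent plane, and log-normal channel gains with sd
        ``session_id * drift_gain_sd``.  Session 0 is drift-free.
        """
        cfg = self.config
        sub = self.subject(subject_id)
        d = cfg.latent_dim_true
        angle = cfg.drift_rotation * int(session_id)
        rot = np.eye(d)
        if d >= 2 and angle != 0.0:
            u, v = sub.drift_plane[:, 0], sub.drift_plane[:, 1]
            c, s = np.cos(angle), np.sin(angle)
            # rotation in span(u, v), identity on the orthogonal complement
            rot = (np.eye(d)
                   + (c - 1.0) * (np.outer(u, u) + np.outer(v, v))
                   + s * (np.outer(v, u) - np.outer(u, v)))
        gain_sd = cfg.drift_gain_sd * int(session_id)
        rng = np.random.default_rng([cfg.seed % (2**31), int(subject_id),
                                     int(session_id), 211])
        gains = np.exp(rng.normal(0.0, gain_sd, cfg.n_channels)) if gain_sd > 0 \
            else np.ones(cfg.n_channels)
        return rot, gains

    def channel_rates(self, subject_id: int, latents: np.ndarray,
                      session_id: int = 0) -> np.ndarray:
        """Noise-free firing rates (Hz) for latent trajectories ``latents``."""
        sub = self.subject(subject_id)
        rot, gains = self.session_drift(subject_id, session_id)
        z = latents @ sub.mixing @ rot
        u = (z @ sub.embedding) * gains + sub.offsets
        return _softplus(sub.link_gain * u + sub.link_offset)

    def emg_truth(self, latents: np.ndarray) -> np.ndarray:
        """Noise-free EMG envelopes (time x muscle) from latent trajectories."""
        return np.maximum(latents @ self.muscle_readout, 0.0)


@dataclass
class Session:
    """One recorded session: binned spikes, optional raw EMG, trial table."""

    subject_id: int
    session_id: int
    mode: str
    bin_width: float
    spikes: np.ndarray                 # (n_bins, n_channels) int
    raw_emg: np.ndarray | None         # (n_samples, n_muscles) at emg_rate, or None
    emg_rate: float
    envelope_truth: np.ndarray         # (n_bins, n_muscles) noise-free ground truth
    rate_truth: np.ndarray             # (n_bins, n_channels) underlying rates, Hz
    latent_truth: np.ndarray           # (n_bins, latent_dim_true) world-frame latents
    trial_table: pd.DataFrame          # trial_id, target_deg, native_deg, go_cue_s, onset_s
    config: WorldConfig

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[0]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: float) -> float:
    # log(exp(y) - 1), stable for y >> 0
    return float(y + np.log1p(-np.exp(-y)))


def _direction_features(angles_deg: np.ndarray, d: int) -> np.ndarray:
    """Per-target latent endpoints: cos/sin harmonics plus a shared go signal.

    Dimension order: cos(t), sin(t), cos(2t), sin(2t), constant, cos(3t), ...
    The leading cos/sin pair carries the cosine tuning that the EMG readout
    consumes; the constant dimension is a condition-independent component.
    """
    th = np.deg2rad(angles_deg)
    cols = []
    amps = []
    harmonic = 1
    while len(cols) < d:
        if len(cols) == 4:
            cols.append(np.full_like(th, 1.0))
            amps.append(0.8)
            continue
        amp = 1.0 if harmonic == 1 else 0.6 / harmonic
        cols.append(np.cos(harmonic * th))
        amps.append(amp)
        if len(cols) < d:
            cols.append(np.sin(harmonic * th))
            amps.append(amp)
        harmonic += 1
    feats = np.stack(cols[:d], axis=1) * np.asarray(amps[:d])
    return feats


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw the frozen ground truth for one simulated experiment.

    Deterministic in ``config.seed``.  Latent templates are smooth ramps that
    sit at baseline for the first 0.5 s of the trial window and then rise
    toward a target-dependent fixed point; each latent dimension has its own
    onset delay and rise time so the trajectories are not rank-one in time.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed % (2**31), 101])
    d = cfg.latent_dim_true
    nb = cfg.window_bins

    # time axis relative to movement onset (onset at +0.5 s into the window).
    # Each dimension ramps to a tonic plateau with a phasic onset burst on
    # top — the burst-plus-hold shape typical of EMG in step force tasks,
    # and the feature that makes trial timing identifiable from the signals.
    t = np.arange(nb) * cfg.bin_width - 0.5
    delays = 0.10 + 0.20 * rng.random(d)
    taus = 0.08 + 0.07 * rng.random(d)
    ramp = 0.5 * (1.0 + np.tanh((t[:, None] - delays) / taus))
    burst = 0.6 * np.exp(-0.5 * ((t[:, None] - delays - 0.08) / 0.06) ** 2)
    profiles = ramp + burst  # (nb, d)

    feats = _direction_features(cfg.target_angles, d)               # (K, d)
    templates = profiles[None, :, :] * feats[:, None, :]            # (K, nb, d)

    # cosine-tuned muscle readout on the leading cos/sin pair, with a weak
    # condition-independent co-activation term when that dimension exists
    pref = (np.arange(cfg.n_muscles) * 360.0 / cfg.n_muscles
            + rng.uniform(0.0, 360.0 / cfg.n_muscles)) % 360.0
    readout = np.zeros((d, cfg.n_muscles))
    readout[0] = np.cos(np.deg2rad(pref))
    if d >= 2:
        readout[1] = np.sin(np.deg2rad(pref))
    if d >= 5:
        readout[4] = 0.4

    stacked = templates.reshape(-1, d)
    subjects = []
    for s in range(cfg.n_subjects):
        srng = np.random.default_rng([cfg.seed % (2**31), 113, s])
        mixing = _draw_invertible(srng, d, max_cond=50.0)
        emb = srng.normal(0.0, 1.0 / np.sqrt(d), (d, cfg.n_channels))
        offs = srng.normal(0.0, 0.3, cfg.n_channels)
        u = (stacked @ mixing) @ emb + offs
        med, hi = float(np.median(u)), float(np.max(u))
        a = (_softplus_inv(cfg.rate_scale) - _softplus_inv(cfg.rate_median)) / (hi - med)
        b = _softplus_inv(cfg.rate_median) - a * med
        plane = np.linalg.qr(srng.normal(size=(d, 2)))[0] if d >= 2 else np.zeros((d, 2))
        subjects.append(_SubjectModel(mixing, emb, offs, a, b, plane))

    return SyntheticWorld(cfg, templates, readout, pref, tuple(subjects))


def _draw_invertible(rng: np.random.Generator, d: int, max_cond: float) -> np.ndarray:
    for _ in range(100):
        m = rng.normal(size=(d, d))
        if np.linalg.cond(m) < max_cond:
            return m
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def generate_session(world: SyntheticWorld, subject_id: int, session_id: int,
                     trials_per_target: int, mode: str = "monkey") -> Session:
    """Simulate one recording session.

    Spike counts are Poisson per 20 ms bin with mean rate x bin width.  Raw
    EMG (monkey mode only) is the ground-truth envelope amplitude-modulating
    a 50-500 Hz band-limited Gaussian carrier sampled at 2 kHz.  Human mode
    drops the raw EMG, anticipates the go cue by ``anticipation_lead`` on
    average, jitters per-trial onsets, scales per-trial response gain, and —
    when ``config.mirror`` is set — stores target labels reflected about the
    vertical axis (theta -> (180 - theta) mod 360).
    """
    cfg = world.config
    if mode not in ("monkey", "human"):
        raise ValueError(f"mode must be 'monkey' or 'human', got {mode!r}")
    world.subject(subject_id)  # raises LookupError if unknown
    if trials_per_target < 1:
        raise ValueError("trials_per_target must be >= 1")

    rng = np.random.default_rng([cfg.seed % (2**31), int(subject_id),
                                 int(session_id), 307])
    bw = cfg.bin_width
    nb_win = cfg.window_bins
    block_s = _PRE_PAD + cfg.trial_window + _POST_PAD
    block_bins = int(round(block_s / bw))
    n_trials = cfg.n_targets * trials_per_target
    total_bins = n_trials * block_bins + int(round(_TAIL_PAD / bw))

    order = np.repeat(np.arange(cfg.n_targets), trials_per_target)
    rng.shuffle(order)

    human = mode == "human"
    latents = np.zeros((total_bins, cfg.latent_dim_true))
    rows = []
    for i, k in enumerate(order):
        b0 = i * block_bins
        if human:
            go_s = b0 * bw + _HUMAN_GO_IN_BLOCK
            jit = rng.normal(0.0, cfg.timing_jitter_sd) if cfg.timing_jitter_sd > 0 else 0.0
            pat_s = go_s - cfg.anticipation_lead + jit
            gain = np.exp(rng.normal(0.0, cfg.trial_gain_sd)) if cfg.trial_gain_sd > 0 else 1.0
        else:
            pat_s = b0 * bw + _PRE_PAD
            go_s = pat_s + 0.5 - _REACTION
            gain = 1.0
        p0 = int(round(pat_s / bw))
        onset_s = (p0 * bw) + 0.5  # attempted-movement onset, bin-aligned
        latents[p0:p0 + nb_win] += gain * world.latent_templates[k]
        native = cfg.target_angles[k]
        stored = (180.0 - native) % 360.0 if (human and cfg.mirror) else native
        rows.append((i, stored, native, go_s, onset_s))

    table = pd.DataFrame(rows, columns=["trial_id", "target_deg", "native_deg",
                                        "go_cue_s", "onset_s"])

    rates = world.channel_rates(subject_id, latents, session_id)
    spikes = rng.poisson(rates * bw).astype(np.int64)

    env = world.emg_truth(latents)
    raw = None
    emg_rate = 2000.0
    if not human:
        raw = _modulated_carrier(rng, env, bw, emg_rate, cfg.emg_noise_sd)

    return Session(int(subject_id), int(session_id), mode, bw, spikes, raw,
                   emg_rate, env, rates, latents, table, cfg)


def _modulated_carrier(rng: np.random.Generator, envelope: np.ndarray,
                       bin_width: float, fs: float, noise_sd: float) -> np.ndarray:
    """Raw EMG: envelope (+ floor, + log-normal amplitude noise) x band noise."""
    from scipy.signal import butter, lfilter

    up = int(round(fs * bin_width))
    floor = 0.05 * max(float(envelope.max()), 1e-12)
    amp = envelope + floor
    if noise_sd > 0:
        amp = amp * np.exp(rng.normal(0.0, noise_sd, envelope.shape))
    amp = np.repeat(amp, up, axis=0)
    carrier = rng.standard_normal(amp.shape)
    b, a = butter(4, [50.0, 500.0], btype="bandpass", fs=fs)
    carrier = lfilter(b, a, carrier, axis=0)
    carrier /= max(float(carrier.std()), 1e-12)
    return amp * carrier
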