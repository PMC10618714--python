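# Methods

This note documents the models, parameter choices, and numerical decisions
behind `latentemg`, and what the synthetic benchmark does and does not
establish about real recordings.

## Pipeline model and assumptions

The pipeline assumes that motor-cortical population activity during a
stereotyped motor task is well described by a low-dimensional latent signal
embedded linearly (up to a pointwise positive link) in the recorded channels,
and that different subjects performing the same task share latent dynamics up
to an invertible linear transformation. Under these assumptions a static
linear alignment (CCA with inverse transfer into the source frame) suffices
to reuse a source-trained decoder on a target subject, and the same machinery
absorbs within-subject recording drift across sessions.

Stages and defaults:

- **Spike smoothing** — Gaussian kernel, σ = 100 ms, on 20 ms bins, scaled to
  Hz. The kernel is centered (non-causal), appropriate for offline analysis;
  at the recording edges it is renormalized per sample so constant input maps
  to constant rate.
- **EMG envelope** — full-wave rectification → 4-pole Butterworth low-pass at
  10 Hz (causal by default; `zero_phase=True` switches to filtfilt) →
  downsample to 50 Hz → clamp above mean + 6 sd → subtract the 2nd
  percentile → clip at zero → divide by the 90th percentile. All statistics
  are per channel over the whole session. Clipping is applied to the
  envelope before baseline subtraction (it targets artifact spikes);
  normalization comes last so 0 and 1 correspond to rest and strong
  activation. Negative post-baseline values are clipped to zero. A channel
  whose normalization percentile is not positive is excluded with a warning.
- **Manifold** — PCA via eigendecomposition of the sample covariance,
  deterministic sign convention (largest-magnitude loading positive),
  p = 13. p is a configuration parameter, not re-estimated per session; it
  is an upper bound on the linear dimensionality of this task as estimated
  by Parallel Analysis.
- **Parallel Analysis** — Horn-style: 100 surrogates in which each channel
  is independently permuted across time (destroying cross-channel
  correlation, preserving marginals), 95th-percentile threshold, counting
  leading eigenvalues until the first failure. Permutation surrogates retain
  per-channel variance, so a very anisotropic signal raises the null
  threshold; the estimator is consequently conservative about weak
  dimensions. Phase-randomized surrogates would be a reasonable alternative;
  the permutation scheme is the conventional default and is what we
  validate.
- **CCA alignment** — solved by whitening both blocks (eigendecomposition of
  each covariance) and taking the SVD of the whitened cross-covariance.
  Rank-deficient inputs raise an error naming the deficient side. All 13
  components are retained. The inverse source transform is computed by
  direct solve with a condition-number guard (>1e8 raises). Alignment is fit
  on centered data and re-adds the source mean, because the downstream
  decoder's intercept lives in source coordinates. CCA requires one-to-one
  time correspondence, established by ordering trials by target direction
  and concatenating; when per-target trial counts differ between sessions
  the larger side is subsampled with a seeded RNG.
- **Wiener decoder** — OLS per muscle from a lagged design with an intercept
  and taps at lags 0–4 (5 bins = 100 ms of history, the current bin
  included). Histories never cross trial boundaries; the first samples of
  each trial are padded by replicating the trial's first sample, keeping row
  counts equal across subjects as the CCA correspondence requires. Output is
  rectified at zero. Ridge regularization is available but defaults to 0.
- **Evaluation** — per-muscle R² on concatenated test windows, averaged with
  weights proportional to each recorded muscle's variance; reported per pair
  as the mean over folds (not pooled predictions). Folds are stratified by
  target direction. Source and target sessions are split into matched folds
  before PCA/decoder/aligner fitting; the one deliberate exception is the
  fixed source decoder used for transfer, which is trained on all available
  source data (the source subject's data are plentiful by assumption, and
  its EMG test segments are its own recordings, not the quantity being
  transferred).

## Synthetic benchmark

`synth` generates an eight-direction isometric wrist task. Per-target latent
templates are smooth ramps (per-dimension onset delays 0.10–0.30 s, rise
times 0.08–0.15 s) toward direction-dependent fixed points built from cosine
harmonics of the target angle plus one condition-independent component, each
with a phasic Gaussian onset burst (amplitude 0.6, sd 60 ms) superimposed —
the burst-plus-hold shape typical of EMG in step force tasks, and the
feature that makes trial timing identifiable at the 20 ms scale. EMG
envelopes read the leading cosine/sine pair through per-muscle preferred
directions (rectified linear readout), giving exact cosine tuning; rates
arise from subject-specific invertible latent mixing (condition number
< 50), a random linear embedding into 96 channels, and a softplus link
calibrated per subject so the median rate is ≈10 Hz and the maximum ≈50 Hz —
a realistic M1 range that keeps Poisson noise meaningful. Spikes are Poisson
per 20 ms bin; raw EMG is the envelope (plus a 5% noise floor and log-normal
amplitude noise, sd 0.05) modulating a 50–500 Hz band-passed Gaussian
carrier at 2 kHz.

Human-like sessions drop the raw EMG (paralysis; ground-truth envelopes are
retained internally for validation only), anticipate the go cue — the 1.5 s
response window leads the go cue by `anticipation_lead` (0.8 s in the
experiments) — and add per-trial onset jitter (sd 0.05 s) and log-normal
response-gain variability (sd 0.15). These values are not fitted to any
participant; they are plausible magnitudes, exposed as free parameters.
With an opposite-hemisphere implant, target labels are mirrored about the
vertical axis: θ → (180° − θ) mod 360°.

Session-to-session drift is a rotation of the latent embedding by
`drift_rotation` × session-index radians in a fixed subject-specific plane
plus log-normal per-channel gains (sd `drift_gain_sd` × session-index).
Drift accumulates linearly with session index and session 0 is drift-free.

What the generator does *not* emulate: spiking dynamics beyond inhomogeneous
Poisson, non-stationarity within a session, electrode cross-talk, EMG
cross-talk or biophysics, behavioral learning, and any nonlinearity in the
subject-to-subject latent correspondence beyond the softplus observation
link. Passing tests therefore demonstrate correctness of the pipeline and
its behavior under the stated generative assumptions, not performance on
real recordings.

## Experiment harnesses and problem sizes

The experiment drivers use sessions of 8 trials per target (64 trials) for
the multi-world medians and 16 per target (128 trials) where the standard
4-fold bookkeeping (96 train / 32 test) is itself the point; human-like
sessions use 9 trials per target with 3 folds, mirroring the sparse-human
protocol. Stochastic claims (ceiling recovery, ablation, generalization
ordering, day-k stabilization, Parallel Analysis recovery) are medians or
fractions over 10–20 independently seeded worlds.

The offset search sweeps window offsets from −1.2 s to +0.3 s relative to
the go cue in 20 ms steps and reports the R²-maximizing offset. Transfer
decoding is the discriminating method here: its source decoder is fixed, and
a static latent-space map cannot absorb a time shift, so the R² curve peaks
sharply at the true lead. A *retrained* direct decoder on heavily smoothed
latents is nearly shift-invariant over ±80 ms (lagged taps plus the σ=100 ms
kernel can synthesize small shifts), which flattens its curve; this is a
genuine property of the estimator, not an implementation artifact.

The generalization harness takes explicit train/test direction sets
(interpolation: cardinals → diagonals; extrapolation: lower half → upper
half), since both orientations of the extrapolation split are meaningful.
Extrapolation fails in the synthetic world for the same reasons expected in
real data: muscles silent during training (rectified cosine tuning) carry no
gradient, and PCA fitted on half the workspace underrepresents the missing
directions.

## Numerical choices and degenerate inputs

- PCA requires more samples than components and p ≤ channel count; constant
  data yield dimensionality 0 from Parallel Analysis.
- OLS raises on rank-deficient designs rather than silently pseudo-inverting;
  ridge (off by default) is the sanctioned escape hatch.
- Zero-variance muscles/latent dimensions are excluded from weighted
  averages with warnings; all-zero inputs raise.
- CCA canonical correlations are clipped to [0, 1]; sign convention fixes
  the first nonzero source weight of each variate pair positive.
- All stochastic stages (world generation, Poisson draws, fold assignment,
  subsampling, surrogates) are driven by explicit seeds; identical seeds
  give bit-identical outputs.

## Known limitations

- The fixed source decoder for transfer sees its full session, including
  windows later used to score predictions; target-side fitting is strictly
  cross-validated. This mirrors the intended deployment (the source decoder
  is built once from all surrogate data) but slightly flatters transfer
  relative to a fully held-out protocol.
- The day-k aligner is fitted on the same day-k trials it then decodes, as
  in recalibration practice; a prospective split would lower the aligned
  numbers somewhat.
- Weighted R² with few test trials per fold is noisy; medians over seeds are
  the unit of inference in all stochastic claims.
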