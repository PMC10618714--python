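"""Metrics, cross-validation, and cross-subject decoding experiments.

Decoding accuracy is the coefficient of determination R^2 computed per muscle
on concatenated test-trial windows and averaged across muscles with weights
proportional to each recorded muscle's variance.  Cross-validation is
stratified by target direction (4 folds by default; 3 for sparse human-like
sessions); source and target sessions are split into matched folds *before*
any PCA, decoder, or aligner is fitted, except that the fixed source decoder
used for transfer decoding is trained on all available source data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decode as dec
from .align import (CCAAligner, apply_alignment, fit_cca, identity_aligner,
                    similarity_r2)
from .latent import DEFAULT_P, fit_pca, project
from .preprocess import (EMGEnvelope, TrialTensor, emg_envelope, order_concat,
                         segment_trials, smooth_rates)
from .synth import Session

__all__ = [
    "EvalResult",
    "PairResult",
    "PairMatrix",
    "PreparedSession",
    "weighted_r2",
    "make_folds",
    "prepare_session",
    "decode_pair",
    "run_pair_experiment",
    "offset_search",
    "generalization_experiment",
    "dayk_experiment",
]

MONKEY_WINDOW = ("onset", -0.5, 1.5)


@dataclass
class EvalResult:
    per_muscle_r2: dict[str, float]
    weights: dict[str, float]
    weighted_r2: float


@dataclass
class PairResult:
    method: str
    r2: float                       # mean weighted R^2 over folds
    fold_r2: list[float]
    fold_results: list[EvalResult] = field(repr=False, default_factory=list)
    alignment_r2: float | None = None   # latent similarity after alignment


@dataclass
class PairMatrix:
    values: np.ndarray              # (n_sessions, n_sessions)
    session_keys: list[str]
    method: str                     # off-diagonal method; diagonal is within

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.session_keys,
                            columns=self.session_keys)


def weighted_r2(pred: np.ndarray, actual) -> EvalResult:
    """Variance-weighted multi-muscle R^2 of predictions against recordings."""
    names = None
    if isinstance(actual, EMGEnvelope):
        names = actual.muscle_names
        actual = actual.values
    y = np.asarray(actual, dtype=float)
    yh = np.asarray(pred, dtype=float)
    if y.ndim == 1:
        y, yh = y[:, None], yh[:, None]
    if y.shape != yh.shape:
        raise ValueError("shape mismatch between predictions and recordings")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    names = names or [f"m{i}" for i in range(y.shape[1])]
    var = y.var(axis=0, ddof=1)
    per, w = {}, {}
    for i, nm in enumerate(names):
        if var[i] <= 0:
            warnings.warn(f"zero-variance muscle {nm!r} excluded from R^2")
            continue
        sse = float(((y[:, i] - yh[:, i]) ** 2).sum())
        sst = float(((y[:, i] - y[:, i].mean()) ** 2).sum())
        per[nm] = 1.0 - sse / sst
        w[nm] = float(var[i])
    if not per:
        raise ValueError("all muscles have zero variance")
    tot = sum(w.values())
    wavg = sum(w[nm] * per[nm] for nm in per) / tot
    return EvalResult(per, w, float(wavg))


def make_folds(trial_table: pd.DataFrame, k: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (one id per trial), deterministic in seed."""
    rng = np.random.default_rng(seed)
    folds = np.full(len(trial_table), -1, dtype=int)
    labels = trial_table["target_deg"].to_numpy()
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if k > len(idx):
            raise ValueError(f"k={k} exceeds trial count {len(idx)} "
                             f"for target {lab}")
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


def _matched_folds(ta: pd.DataFrame, tb: pd.DataFrame, k: int,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint stratified folds with equal per-(target, fold) counts.

    When per-target trial counts differ between the two sessions the larger
    side is subsampled (seeded); unused trials get fold id -1.
    """
    rng = np.random.default_rng(seed)
    la = ta["target_deg"].to_numpy()
    lb = tb["target_deg"].to_numpy()
    if set(np.unique(la)) != set(np.unique(lb)):
        raise ValueError("sessions do not share a target-direction set")
    fa = np.full(len(ta), -1, dtype=int)
    fb = np.full(len(tb), -1, dtype=int)
    for lab in np.unique(la):
        ia = np.flatnonzero(la == lab)
        ib = np.flatnonzero(lb == lab)
        n = min(len(ia), len(ib))
        if k > n:
            raise ValueError(f"k={k} exceeds matched trial count {n} "
                             f"for target {lab}")
        pa = rng.permutation(len(ia))[:n]
        pb = pa if ta is tb else rng.permutation(len(ib))[:n]
        pos = np.arange(n) % k
        fa[ia[pa]] = pos
        fb[ib[pb]] = pos
    return fa, fb


@dataclass
class PreparedSession:
    """A session after signal conditioning: rates in Hz, normalized envelopes."""

    session: Session
    rates: np.ndarray               # (n_bins, n_channels)
    env: np.ndarray | None          # (n_bins, n_muscles) or None (human)
    muscle_names: list[str] | None
    table: pd.DataFrame
    bin_width: float


def prepare_session(session: Session, sigma: float = 0.1) -> PreparedSession:
    """Smooth spikes to rates and extract normalized EMG envelopes."""
    rates = smooth_rates(session.spikes, session.bin_width, sigma).values
    env = names = None
    if session.raw_emg is not None:
        e = emg_envelope(session.raw_emg, fs=session.emg_rate,
                         out_rate=1.0 / session.bin_width)
        env, names = e.values, e.muscle_names
    return PreparedSession(session, rates, env, names, session.trial_table,
                           session.bin_width)


def _prep(s, sigma: float) -> PreparedSession:
    return s if isinstance(s, PreparedSession) else prepare_session(s, sigma)


def _subset(t: TrialTensor, mask: np.ndarray) -> TrialTensor:
    return TrialTensor(t.data[mask], t.labels[mask], t.start_offset, t.length,
                       t.bin_width)


def _windows(prep: PreparedSession, values: np.ndarray,
             window: tuple[str, float, float]) -> TrialTensor:
    anchor, off, length = window
    return segment_trials(values, prep.bin_width, prep.table, anchor, off, length)


def decode_pair(source, target=None, method: str = "within", k: int = 4,
                seed: int = 0, p: int = DEFAULT_P, n_lags: int = 5,
                window_source: tuple[str, float, float] = MONKEY_WINDOW,
                window_target: tuple[str, float, float] | None = None,
                sigma: float = 0.1, align: str = "cca",
                ridge: float = 0.0) -> PairResult:
    """Cross-validated decoding accuracy for one (source, target) pair.

    ``method`` is ``within`` (source decodes its own EMG), ``direct``
    (target latents regressed onto source EMG), or ``transfer`` (fixed
    source decoder fed CCA-aligned target latents).  ``align="identity"``
    replaces the fitted aligner with the identity map (ablation control).
    """
    src = _prep(source, sigma)
    if src.env is None:
        raise ValueError("source session has no recordable EMG")
    if method == "within" or target is None:
        method = "within"
        tgt = src
    elif target is source:
        tgt = src
    else:
        tgt = _prep(target, sigma)
    wt = window_target or window_source

    src_rates = _windows(src, src.rates, window_source)
    src_env = _windows(src, src.env, window_source)
    tgt_rates = src_rates if tgt is src else _windows(tgt, tgt.rates, wt)

    fs, ft = _matched_folds(src.table, tgt.table, k, seed)
    nb = src_rates.n_bins
    if tgt_rates.n_bins != nb:
        raise ValueError("source and target windows have different lengths")

    # fixed source decoder for transfer: all available (matched) source data
    src_dec = None
    if method == "transfer":
        m_all = fs >= 0
        mat_all, _ = order_concat(_subset(src_rates, m_all))
        env_all, _ = order_concat(_subset(src_env, m_all))
        pca_src_all = fit_pca(mat_all, p)
        lat_all = project(pca_src_all, mat_all)
        bounds = dec.trial_bounds_for(int(m_all.sum()), nb)
        X = dec.build_lagged_design(lat_all, bounds, n_lags)
        src_dec = dec.fit_wiener(X, env_all, n_lags, src.bin_width, ridge,
                                 src.muscle_names)

    fold_r2: list[float] = []
    fold_results: list[EvalResult] = []
    align_scores: list[float] = []
    for f in range(k):
        str_m, ste_m = (fs >= 0) & (fs != f), fs == f
        ttr_m, tte_m = (ft >= 0) & (ft != f), ft == f
        s_env_tr, _ = order_concat(_subset(src_env, str_m))
        s_env_te, _ = order_concat(_subset(src_env, ste_m))
        te_bounds = dec.trial_bounds_for(int(ste_m.sum()), nb)
        tr_bounds = dec.trial_bounds_for(int(str_m.sum()), nb)

        if method == "within":
            s_tr, _ = order_concat(_subset(src_rates, str_m))
            s_te, _ = order_concat(_subset(src_rates, ste_m))
            pca = fit_pca(s_tr, p)
            X = dec.build_lagged_design(project(pca, s_tr), tr_bounds, n_lags)
            d = dec.fit_wiener(X, s_env_tr, n_lags, src.bin_width, ridge,
                               src.muscle_names)
            pred = dec.predict(d, project(pca, s_te), te_bounds)
        elif method == "direct":
            t_tr, _ = order_concat(_subset(tgt_rates, ttr_m))
            t_te, _ = order_concat(_subset(tgt_rates, tte_m))
            pca_t = fit_pca(t_tr, p)
            d = dec.train_direct(project(pca_t, t_tr), s_env_tr, tr_bounds,
                                 n_lags, src.bin_width, ridge)
            pred = dec.predict(d, project(pca_t, t_te), te_bounds)
        elif method == "transfer":
            s_tr, _ = order_concat(_subset(src_rates, str_m))
            s_te, _ = order_concat(_subset(src_rates, ste_m))
            t_tr, _ = order_concat(_subset(tgt_rates, ttr_m))
            t_te, _ = order_concat(_subset(tgt_rates, tte_m))
            pca_t = fit_pca(t_tr, p)
            lat_s_tr = project(pca_src_all, s_tr)
            lat_t_tr = project(pca_t, t_tr)
            if align == "identity":
                aligner: CCAAligner = identity_aligner(p)
            else:
                aligner = fit_cca(lat_s_tr, lat_t_tr)
            lat_t_te = project(pca_t, t_te)
            pred = dec.transfer_decode(src_dec, aligner, lat_t_te, te_bounds)
            align_scores.append(similarity_r2(project(pca_src_all, s_te),
                                              apply_alignment(aligner, lat_t_te)))
        else:
            raise ValueError(f"unknown method {method!r}")
        res = weighted_r2(pred, s_env_te)
        fold_r2.append(res.weighted_r2)
        fold_results.append(res)
    return PairResult(method, float(np.mean(fold_r2)), fold_r2, fold_results,
                      float(np.mean(align_scores)) if align_scores else None)


def run_pair_experiment(sessions: list, method: str = "transfer", k: int = 4,
                        seed: int = 0, p: int = DEFAULT_P, n_lags: int = 5,
                        sigma: float = 0.1, align: str = "cca") -> PairMatrix:
    """All-pairs decoding matrix; diagonal entries are within-session CV."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    preps = [_prep(s, sigma) for s in sessions]
    keys = [f"s{pr.session.subject_id}d{pr.session.session_id}" for pr in preps]
    n = len(preps)
    vals = np.full((n, n), np.nan)
    for i, src in enumerate(preps):
        for j, tgt in enumerate(preps):
            m = "within" if i == j else method
            vals[i, j] = decode_pair(src, tgt, m, k, seed, p, n_lags,
                                     align=align).r2
    return PairMatrix(vals, keys, method)


def offset_search(human_session, source_session, offsets,
                  method: str = "direct", k: int = 3, seed: int = 0,
                  p: int = DEFAULT_P, n_lags: int = 5, sigma: float = 0.1,
                  length: float = 1.5) -> tuple[np.ndarray, float]:
    """Sweep the human segmentation offset relative to the go cue.

    For each offset the human trials are cut as ``length``-second windows
    starting at go_cue + offset and the full method is cross-validated
    against the source session; returns the R^2 curve and the best offset.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("empty offset grid")
    src = _prep(source_session, sigma)
    hum = _prep(human_session, sigma)
    curve = np.empty(offsets.shape)
    for i, off in enumerate(offsets):
        curve[i] = decode_pair(src, hum, method, k, seed, p, n_lags,
                               window_source=("onset", -0.5, length),
                               window_target=("go_cue", float(off), length)).r2
    return curve, float(offsets[int(np.argmax(curve))])


def _dir_subset(prep: PreparedSession, dirs) -> PreparedSession:
    mask = prep.table["target_deg"].isin(dirs).to_numpy()
    return PreparedSession(prep.session, prep.rates, prep.env,
                           prep.muscle_names, prep.table[mask].reset_index(drop=True),
                           prep.bin_width)


def generalization_experiment(source, target, train_dirs, test_dirs,
                              method: str = "direct", seed: int = 0,
                              p: int = DEFAULT_P, n_lags: int = 5,
                              sigma: float = 0.1,
                              window: tuple[str, float, float] = MONKEY_WINDOW,
                              ridge: float = 0.0) -> EvalResult:
    """Train every fitted stage on one direction set, test on a disjoint one.

    Probes interpolation (e.g. train on cardinal directions, test on
    diagonals) and extrapolation (train on one half of the workspace, test
    on the other).
    """
    train_dirs, test_dirs = list(train_dirs), list(test_dirs)
    if not train_dirs or not test_dirs:
        raise ValueError("direction sets must be non-empty")
    src = _prep(source, sigma)
    tgt = _prep(target, sigma) if target is not None else src

    # matched per-target counts between the two sessions
    all_dirs = train_dirs + test_dirs
    src_m = _dir_subset(src, all_dirs)
    tgt_m = _dir_subset(tgt, all_dirs)
    fs, ft = _matched_folds(src_m.table, tgt_m.table, 1, seed)
    src_m.table = src_m.table[fs >= 0].reset_index(drop=True)
    tgt_m.table = tgt_m.table[ft >= 0].reset_index(drop=True)

    def _block(prep, values, dirs):
        sub = _dir_subset(prep, dirs)
        tens = segment_trials(values, sub.bin_width, sub.table, *window)
        mat, _ = order_concat(tens)
        return mat, dec.trial_bounds_for(tens.n_trials, tens.n_bins)

    s_rates_tr, b_tr = _block(src_m, src_m.rates, train_dirs)
    s_rates_te, b_te = _block(src_m, src_m.rates, test_dirs)
    s_env_tr, _ = _block(src_m, src_m.env, train_dirs)
    s_env_te, _ = _block(src_m, src_m.env, test_dirs)
    t_rates_tr, _ = _block(tgt_m, tgt_m.rates, train_dirs)
    t_rates_te, _ = _block(tgt_m, tgt_m.rates, test_dirs)

    if method == "within":
        pca = fit_pca(s_rates_tr, p)
        X = dec.build_lagged_design(project(pca, s_rates_tr), b_tr, n_lags)
        d = dec.fit_wiener(X, s_env_tr, n_lags, src.bin_width, ridge)
        pred = dec.predict(d, project(pca, s_rates_te), b_te)
    elif method == "direct":
        pca_t = fit_pca(t_rates_tr, p)
        d = dec.train_direct(project(pca_t, t_rates_tr), s_env_tr, b_tr,
                             n_lags, src.bin_width, ridge)
        pred = dec.predict(d, project(pca_t, t_rates_te), b_te)
    elif method == "transfer":
        pca_s = fit_pca(s_rates_tr, p)
        X = dec.build_lagged_design(project(pca_s, s_rates_tr), b_tr, n_lags)
        d = dec.fit_wiener(X, s_env_tr, n_lags, src.bin_width, ridge)
        pca_t = fit_pca(t_rates_tr, p)
        aligner = fit_cca(project(pca_s, s_rates_tr), project(pca_t, t_rates_tr))
        pred = dec.transfer_decode(d, aligner, project(pca_t, t_rates_te), b_te)
    else:
        raise ValueError(f"unknown method {method!r}")
    return weighted_r2(pred, s_env_te)


def dayk_experiment(source_session, target_sessions: list, seed: int = 0,
                    p: int = DEFAULT_P, n_lags: int = 5,
                    sigma: float = 0.1) -> pd.DataFrame:
    """Stability of a fixed day-0 direct decoder over drifting sessions.

    The direct decoder is fitted once between the target subject's day-0
    latents and the source EMG.  Each later session is then decoded three
    ways: projecting its rates through the day-0 manifold into the fixed
    decoder (``r2_fixed``), CCA-aligning its own latents to the day-0
    latents first (``r2_aligned``), and full transfer decoding from the
    source session (``r2_transfer``).  Row 0 reports day-0 performance.
    """
    src = _prep(source_session, sigma)
    days = [_prep(s, sigma) for s in target_sessions]
    day0 = days[0]

    fs, f0 = _matched_folds(src.table, day0.table, 1, seed)
    s_env = _windows(src, src.env, MONKEY_WINDOW)
    s_env_m, _ = order_concat(_subset(s_env, fs >= 0))
    s_rates = _windows(src, src.rates, MONKEY_WINDOW)
    s_rates_m, _ = order_concat(_subset(s_rates, fs >= 0))
    d0_rates = _windows(day0, day0.rates, MONKEY_WINDOW)
    d0_m, _ = order_concat(_subset(d0_rates, f0 >= 0))
    nb = s_env.n_bins
    n_tr = int((fs >= 0).sum())
    bounds = dec.trial_bounds_for(n_tr, nb)

    pca0 = fit_pca(d0_m, p)
    lat0 = project(pca0, d0_m)
    direct0 = dec.train_direct(lat0, s_env_m, bounds, n_lags, src.bin_width)

    pca_s = fit_pca(s_rates_m, p)
    lat_s = project(pca_s, s_rates_m)
    Xs = dec.build_lagged_design(lat_s, bounds, n_lags)
    src_dec = dec.fit_wiener(Xs, s_env_m, n_lags, src.bin_width,
                             muscle_names=src.muscle_names)

    rows = []
    for prep in days:
        fsx, fk = _matched_folds(src.table, prep.table, 1, seed)
        env_m, _ = order_concat(_subset(s_env, fsx >= 0))
        k_rates = _windows(prep, prep.rates, MONKEY_WINDOW)
        k_m, _ = order_concat(_subset(k_rates, fk >= 0))
        bnd = dec.trial_bounds_for(int((fk >= 0).sum()), nb)

        pred_fixed = dec.predict(direct0, project(pca0, k_m), bnd)
        r2_fixed = weighted_r2(pred_fixed, env_m).weighted_r2

        pcak = fit_pca(k_m, p)
        latk = project(pcak, k_m)
        al = fit_cca(lat0[: latk.shape[0]], latk)
        pred_al = dec.predict(direct0, apply_alignment(al, latk), bnd)
        r2_al = weighted_r2(pred_al, env_m).weighted_r2

        al_s = fit_cca(lat_s[: latk.shape[0]], latk)
        pred_tr = dec.transfer_decode(src_dec, al_s, latk, bnd)
        r2_tr = weighted_r2(pred_tr, env_m).weighted_r2

        rows.append((prep.session.session_id, r2_fixed, r2_al, r2_tr))
    return pd.DataFrame(rows, columns=["session_id", "r2_fixed", "r2_aligned",
                                       "r2_transfer"])
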