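"""On-disk formats: HDF5 arrays, CSV trial tables, JSON sidecars.

One session is written as three files sharing a stem: ``<stem>.h5`` with
datasets ``spikes`` (int, time x channel), optionally ``emg_raw`` and
``envelope_truth``; ``<stem>.trials.csv`` with the trial table; and
``<stem>.json`` recording the world configuration.  Fitted models (PCA,
CCA aligner, Wiener decoder) are stored as flat HDF5 files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .align import CCAAligner
from .decode import WienerDecoder
from .latent import PCAModel
from .synth import Session, WorldConfig

__all__ = [
    "session_stem",
    "save_session",
    "load_session",
    "save_pca",
    "load_pca",
    "save_aligner",
    "load_aligner",
    "save_decoder",
    "load_decoder",
]


def session_stem(out_dir, subject_id: int, session_id: int) -> Path:
    return Path(out_dir) / f"subject{subject_id}_session{session_id}"


def save_session(session: Session, out_dir) -> dict[str, str]:
    """Write one session; returns a manifest of the files created."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = session_stem(out_dir, session.subject_id, session.session_id)
    h5path = stem.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        f.attrs["subject_id"] = session.subject_id
        f.attrs["session_id"] = session.session_id
        f.attrs["mode"] = session.mode
        f.attrs["bin_width"] = session.bin_width
        f.attrs["emg_rate"] = session.emg_rate
        f.create_dataset("spikes", data=session.spikes, compression="gzip")
        f.create_dataset("envelope_truth", data=session.envelope_truth,
                         compression="gzip")
        if session.raw_emg is not None:
            f.create_dataset("emg_raw", data=session.raw_emg, compression="gzip")
    csvpath = Path(str(stem) + ".trials.csv")
    session.trial_table.to_csv(csvpath, index=False)
    jsonpath = stem.with_suffix(".json")
    jsonpath.write_text(session.config.to_json())
    return {"h5": str(h5path), "trials": str(csvpath), "config": str(jsonpath)}


def load_session(out_dir, subject_id: int, session_id: int) -> Session:
    stem = session_stem(out_dir, subject_id, session_id)
    h5path = stem.with_suffix(".h5")
    if not h5path.exists():
        raise FileNotFoundError(f"missing session file {h5path}")
    with h5py.File(h5path, "r") as f:
        spikes = f["spikes"][()]
        env = f["envelope_truth"][()]
        raw = f["emg_raw"][()] if "emg_raw" in f else None
        mode = f.attrs["mode"]
        bw = float(f.attrs["bin_width"])
        emg_rate = float(f.attrs["emg_rate"])
    table = pd.read_csv(str(stem) + ".trials.csv")
    config = WorldConfig.from_json(stem.with_suffix(".json").read_text())
    # ground-truth rate/latent traces are not serialized; loaders get arrays
    # of the right shape filled with NaN so downstream code fails loudly if
    # it tries to consume them
    nan_rates = np.full(spikes.shape, np.nan)
    nan_lat = np.full((spikes.shape[0], config.latent_dim_true), np.nan)
    return Session(int(subject_id), int(session_id), str(mode), bw, spikes,
                   raw, emg_rate, env, nan_rates, nan_lat, table, config)


def save_pca(model: PCAModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["p"] = model.p
        f.create_dataset("mean", data=model.mean)
        f.create_dataset("components", data=model.components)
        f.create_dataset("eigenvalues", data=model.eigenvalues)


def load_pca(path) -> PCAModel:
    with h5py.File(path, "r") as f:
        return PCAModel(f["mean"][()], f["components"][()], f["eigenvalues"][()])


def save_aligner(aligner: CCAAligner, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("mean_S", "mean_T", "C_S", "C_T", "C_S_inverse",
                     "canonical_correlations"):
            f.create_dataset(name, data=getattr(aligner, name))


def load_aligner(path) -> CCAAligner:
    with h5py.File(path, "r") as f:
        return CCAAligner(*(f[name][()] for name in
                            ("mean_S", "mean_T", "C_S", "C_T", "C_S_inverse",
                             "canonical_correlations")))


def save_decoder(decoder: WienerDecoder, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_lags"] = decoder.n_lags
        f.attrs["bin_width"] = decoder.bin_width
        if decoder.muscle_names:
            f.attrs["muscle_names"] = json.dumps(decoder.muscle_names)
        f.create_dataset("weights", data=decoder.weights)


def load_decoder(path) -> WienerDecoder:
    with h5py.File(path, "r") as f:
        names = json.loads(f.attrs["muscle_names"]) if "muscle_names" in f.attrs else None
        return WienerDecoder(f["weights"][()], int(f.attrs["n_lags"]),
                             float(f.attrs["bin_width"]), names)
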