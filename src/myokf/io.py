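"""Session persistence: HDF5 and an equivalent delimited-text layout.

HDF5 layout: datasets ``features``, ``kinematics``, ``labels`` plus attrs
``rate_hz``, ``channel_names``, ``axis_names``.  The delimited-text layout
is one row per sample: ``time_s, label, kin_<axis>..., ch_<name>...``.
Both round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import SessionRecording

__all__ = ["write_session_h5", "read_session_h5", "write_session_csv", "read_session_csv"]


def write_session_h5(session: SessionRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=session.features)
        f.create_dataset("kinematics", data=session.kinematics)
        f.create_dataset("labels", data=np.array([s.encode() for s in session.labels]))
        f.attrs["rate_hz"] = session.rate_hz
        f.attrs["channel_names"] = [s.encode() for s in session.channel_names]
        f.attrs["axis_names"] = [s.encode() for s in session.axis_names]


def read_session_h5(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        return SessionRecording(
            features=f["features"][:],
            kinematics=f["kinematics"][:],
            labels=np.array([s.decode() for s in f["labels"][:]], dtype=object),
            rate_hz=float(f.attrs["rate_hz"]),
            channel_names=[_dec(s) for s in f.attrs["channel_names"]],
            axis_names=[_dec(s) for s in f.attrs["axis_names"]],
        )


def _dec(s) -> str:
    return s.decode() if isinstance(s, bytes) else str(s)


def write_session_csv(session: SessionRecording, path) -> None:
    t = np.arange(session.features.shape[0]) / session.rate_hz
    df = pd.DataFrame({"time_s": t, "label": session.labels})
    for i, axis in enumerate(session.axis_names):
        df[f"kin_{axis}"] = session.kinematics[:, i]
    for i, name in enumerate(session.channel_names):
        df[f"ch_{name}"] = session.features[:, i]
    # 17 significant digits keep the round-trip lossless for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_session_csv(path) -> SessionRecording:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    kin_cols = [c for c in df.columns if c.startswith("kin_")]
    ch_cols = [c for c in df.columns if c.startswith("ch_")]
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 30.0
    return SessionRecording(
        features=df[ch_cols].to_numpy(dtype=float),
        kinematics=df[kin_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
        rate_hz=float(round(rate, 6)),
        channel_names=[c[len("ch_") :] for c in ch_cols],
        axis_names=[c[len("kin_") :] for c in kin_cols],
    )
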