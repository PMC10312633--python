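"""HDF5 session container and plain-text exports.

A session lives in one HDF5 file with groups ``/lfp``, ``/calibration``,
``/movement``, ``/pose`` and ``/truth``, plus a JSON sidecar recording the
generating configuration and seed.  Interval/event tables are also written
as CSV for inspection, and pose tables in the standard pose-estimation CSV
layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .core import PoseTrack, Recording, StateLabels, as_event_table
from .synthgen import SimConfig, SimSession, config_record


def _write_recording(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("data", data=rec.data, compression="gzip")
    grp.attrs["fs"] = rec.fs
    grp.attrs["reference"] = rec.reference
    grp.create_dataset("channel_ids", data=rec.channel_ids)
    grp.create_dataset("segment_bounds", data=rec.segment_bounds)


def _read_recording(grp: h5py.Group) -> Recording:
    return Recording(
        data=grp["data"][()],
        fs=float(grp.attrs["fs"]),
        channel_ids=grp["channel_ids"][()],
        segment_bounds=grp["segment_bounds"][()],
        reference=str(grp.attrs["reference"]),
    )


def _write_table(grp: h5py.Group, name: str, df: pd.DataFrame) -> None:
    enc = df.copy()
    for col in enc.columns:
        if enc[col].dtype == object:
            enc[col] = enc[col].astype(str)
    rec = enc.to_records(index=False)
    # h5py needs fixed-width strings
    dt = [(n, "S64" if rec.dtype[n].kind in "OU" else rec.dtype[n])
          for n in rec.dtype.names]
    grp.create_dataset(name, data=rec.astype(dt))


def _read_table(grp: h5py.Group, name: str) -> pd.DataFrame:
    df = pd.DataFrame(grp[name][()])
    for col in df.columns:
        if len(df) and isinstance(df[col].iloc[0], bytes):
            df[col] = df[col].str.decode("utf-8")
    return df


def write_session(session: SimSession, out_dir) -> Path:
    """Write a session container + CSV exports + JSON sidecar; returns the
    HDF5 path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5path = out / "session.h5"
    with h5py.File(h5path, "w") as f:
        _write_recording(f.create_group("lfp"), session.recording)
        cal = f.create_group("calibration")
        _write_recording(cal, session.calibration)
        cal.create_dataset("stimulus_onsets_s", data=session.stimulus_onsets_s)
        mov = f.create_group("movement")
        mov.create_dataset("activity", data=session.movement_activity)
        mov.attrs["fps"] = session.config.fps_video
        pose = f.create_group("pose")
        pose.attrs["fps"] = session.pose.fps
        for part in session.pose.parts:
            g = pose.create_group(part)
            for coord in ("x", "y", "likelihood"):
                g.create_dataset(
                    coord, data=session.pose.table[(part, coord)].to_numpy()
                )
        truth = f.create_group("truth")
        _write_table(truth, "bouts", session.truth_bouts.intervals)
        _write_table(truth, "labels", session.truth_labels.intervals)
        _write_table(truth, "events", session.truth_events)
        truth.attrs["session_end_s"] = session.truth_labels.session_end_s
    session.truth_labels.to_csv(out / "labels.csv")
    as_event_table(session.truth_events).to_csv(out / "events.csv", index=False)
    session.pose.to_csv(out / "pose.csv")
    with open(out / "config.json", "w") as fh:
        json.dump(config_record(session.config), fh, indent=2)
    return h5path


def read_session(path) -> SimSession:
    """Read back a session container written by :func:`write_session`."""
    path = Path(path)
    h5path = path / "session.h5" if path.is_dir() else path
    with open(h5path.parent / "config.json") as fh:
        cfg_dict = json.load(fh)
    cfg_dict["theta_band"] = tuple(cfg_dict["theta_band"])
    cfg_dict["theta_channels"] = tuple(cfg_dict["theta_channels"])
    config = SimConfig(**cfg_dict)
    with h5py.File(h5path, "r") as f:
        recording = _read_recording(f["lfp"])
        calibration = _read_recording(f["calibration"])
        onsets = f["calibration/stimulus_onsets_s"][()]
        activity = f["movement/activity"][()]
        fps = float(f["pose"].attrs["fps"])
        cols = {}
        for part in f["pose"]:
            for coord in ("x", "y", "likelihood"):
                cols[(part, coord)] = f["pose"][part][coord][()]
        table = pd.DataFrame(cols)
        table.columns = pd.MultiIndex.from_tuples(
            table.columns, names=["bodyparts", "coords"]
        )
        end = float(f["truth"].attrs["session_end_s"])
        bouts = StateLabels(_read_table(f["truth"], "bouts"),
                            session_start_s=0.0, session_end_s=end)
        labels = StateLabels(_read_table(f["truth"], "labels"),
                             session_start_s=0.0, session_end_s=end)
        events = as_event_table(_read_table(f["truth"], "events"))
    return SimSession(
        recording=recording, calibration=calibration, stimulus_onsets_s=onsets,
        movement_activity=activity, pose=PoseTrack(table, fps=fps),
        truth_bouts=bouts, truth_labels=labels, truth_events=events,
        config=config,
    )


def write_spectra(spectra, path) -> None:
    """Persist a SpectraTable as HDF5 (with its epoch metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("power_db", data=spectra.power, compression="gzip")
        f.create_dataset("freqs_hz", data=spectra.freqs_hz)
        f.create_dataset("channel_ids", data=spectra.channel_ids)
        _write_table(f, "epochs", spectra.epochs)


def read_spectra(path):
    from .core import SpectraTable

    with h5py.File(path, "r") as f:
        epochs = _read_table(f, "epochs")
        return SpectraTable(
            power=f["power_db"][()], freqs_hz=f["freqs_hz"][()],
            channel_ids=f["channel_ids"][()], epochs=epochs,
        )
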