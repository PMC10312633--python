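"""Core data containers shared across the pipeline.

The pipeline's in-memory substrate is deliberately plain: numpy arrays for
continuous signals and spectra, pandas DataFrames for interval/event tables.
All interval times are half-open ``[start, end)`` in seconds; channel indices
are 1-based, with channel 1 the most central electrode and channel 16 the
most peripheral one (at the eye).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The five behavioral/electrophysiological states plus the two
#: evaluation-only flanking bins around each sleep bout.
SLEEP_STAGES = ("presleep", "earlysleep", "midsleep", "latesleep")
STATES = ("awake",) + SLEEP_STAGES
FLANK_BINS = ("pre2", "post2")
ALL_LABELS = STATES + FLANK_BINS

#: Relative-time bins used by the classifier-probability probe (minutes
#: relative to bout start ``0`` and bout end ``x``).
TIME_BINS = (
    "-4:-3", "-3:-2", "-2:-1", "-1:0", "0:+1", "+1:+2",
    "mid", "x-2:x-1", "x-1:x", "x:x+1", "x+1:x+2", "awake",
)

#: Labels whose epochs are never fed to any classifier during training.
NEVER_TRAIN_LABELS = frozenset(FLANK_BINS)

#: Behavioral state implied by each interval label (flanking bins are awake).
STATE_OF_LABEL = {**{s: s for s in STATES}, "pre2": "awake", "post2": "awake"}


@dataclass
class Recording:
    """Continuous multichannel voltage data.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage series in microvolts.
    fs : float
        Sampling rate in samples/s.
    channel_ids : ndarray of int
        1-based original electrode indices (1 = most central).
    segment_bounds : ndarray of int
        Sample indices where acquisition chunks (hour files) start; always
        includes 0.
    reference : str
        One of ``raw``, ``reversal`` or ``bipolar``.
    """

    data: np.ndarray
    fs: float
    channel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    segment_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.channel_ids is None:
            self.channel_ids = np.arange(1, self.data.shape[0] + 1)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length mismatch")
        if self.segment_bounds is None:
            self.segment_bounds = np.array([0])
        self.segment_bounds = np.asarray(self.segment_bounds, dtype=int)
        if self.reference not in ("raw", "reversal", "bipolar"):
            raise ValueError(f"unknown reference scheme {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def split_segments(self) -> list["Recording"]:
        """Split into the acquisition chunks recorded by ``segment_bounds``."""
        bounds = list(self.segment_bounds) + [self.n_samples]
        return [
            replace(self, data=self.data[:, a:b], segment_bounds=np.array([0]))
            for a, b in zip(bounds[:-1], bounds[1:])
            if b > a
        ]


LABEL_COLUMNS = ["start_s", "end_s", "label", "bout_id"]


@dataclass
class StateLabels:
    """Interval table assigning every instant of a session to a state label.

    ``intervals`` has columns ``start_s, end_s, label, bout_id``; intervals
    are non-overlapping and, for a fully-labeled session, tile it exactly.
    ``bout_id`` is -1 for intervals not derived from a sleep bout.
    """

    intervals: pd.DataFrame
    session_start_s: float = 0.0
    session_end_s: float | None = None

    def __post_init__(self):
        df = pd.DataFrame(self.intervals, columns=LABEL_COLUMNS).copy()
        df["start_s"] = df["start_s"].astype(float)
        df["end_s"] = df["end_s"].astype(float)
        df["bout_id"] = df["bout_id"].astype(int)
        df = df.sort_values("start_s", kind="stable").reset_index(drop=True)
        if (df["end_s"] <= df["start_s"]).any():
            raise ValueError("empty or inverted interval")
        if (df["start_s"].to_numpy()[1:] < df["end_s"].to_numpy()[:-1] - 1e-9).any():
            raise ValueError("overlapping intervals")
        self.intervals = df
        if self.session_end_s is None and len(df):
            self.session_end_s = float(df["end_s"].iloc[-1])

    def __len__(self) -> int:
        return len(self.intervals)

    def tiles_session(self, atol: float = 1e-6) -> bool:
        df = self.intervals
        if not len(df):
            return False
        contiguous = np.allclose(
            df["start_s"].to_numpy()[1:], df["end_s"].to_numpy()[:-1], atol=atol
        )
        return (
            contiguous
            and abs(df["start_s"].iloc[0] - self.session_start_s) < atol
            and abs(df["end_s"].iloc[-1] - self.session_end_s) < atol
        )

    def total_time(self) -> float:
        return float((self.intervals["end_s"] - self.intervals["start_s"]).sum())

    def label_at(self, t: float) -> str | None:
        df = self.intervals
        hit = df[(df["start_s"] <= t) & (t < df["end_s"])]
        return None if hit.empty else str(hit["label"].iloc[0])

    def of_labels(self, labels) -> pd.DataFrame:
        return self.intervals[self.intervals["label"].isin(labels)]

    def bouts(self) -> pd.DataFrame:
        """Per-bout start/end of the immobility period (earlysleep..latesleep)."""
        sleep = self.intervals[
            self.intervals["label"].isin(("earlysleep", "midsleep", "latesleep", "sleep"))
        ]
        if sleep.empty:
            return pd.DataFrame(columns=["bout_id", "start_s", "end_s"])
        g = sleep.groupby("bout_id")
        out = pd.DataFrame(
            {"start_s": g["start_s"].min(), "end_s": g["end_s"].max()}
        ).reset_index()
        return out.sort_values("start_s").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.intervals.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, session_start_s: float = 0.0,
                 session_end_s: float | None = None) -> "StateLabels":
        return cls(pd.read_csv(path), session_start_s, session_end_s)


#: Body parts tracked by the pose-estimation network.
POSE_PARTS = (
    "eye", "proboscis", "leg1_tip", "leg1_joint", "leg3_tip", "leg3_joint",
    "abdomen", "antenna_L_base", "antenna_L_tip", "antenna_R_base",
    "antenna_R_tip",
)


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates with tracking likelihoods.

    ``table`` has a two-level column index ``(bodypart, coord)`` with coords
    ``x`` (px), ``y`` (px) and ``likelihood`` in [0, 1].
    """

    table: pd.DataFrame
    fps: float

    def __post_init__(self):
        if not isinstance(self.table.columns, pd.MultiIndex):
            raise ValueError("pose table needs a (bodypart, coord) column index")
        lk = self.table.loc[:, (slice(None), "likelihood")].to_numpy()
        finite = lk[np.isfinite(lk)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.table)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def parts(self) -> list[str]:
        return list(self.table.columns.get_level_values(0).unique())

    def xy(self, part: str) -> np.ndarray:
        return self.table[part][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.table[(part, "likelihood")].to_numpy(dtype=float)

    def to_csv(self, path, scorer: str = "flysleep") -> None:
        """Write in the standard pose-estimation CSV layout (3 header rows)."""
        out = self.table.copy()
        out.columns = pd.MultiIndex.from_tuples(
            [(scorer, p, c) for p, c in out.columns],
            names=["scorer", "bodyparts", "coords"],
        )
        out.to_csv(path, index_label="frame")

    @classmethod
    def from_csv(cls, path, fps: float) -> "PoseTrack":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [(p, c) for _, p, c in df.columns], names=["bodyparts", "coords"]
        )
        return cls(df.reset_index(drop=True), fps=fps)


EVENT_COLUMNS = [
    "peak_frame", "peak_time_s", "state", "burst_id", "burst_length",
    "intra_burst_interval_s", "provenance",
]


def empty_events() -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    return df.astype({"peak_frame": int, "peak_time_s": float, "burst_id": int,
                      "burst_length": int, "intra_burst_interval_s": float})


def as_event_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a proboscis-extension event table (sorted, typed, defaulted)."""
    df = df.copy()
    for col, default in (
        ("state", ""), ("burst_id", -1), ("burst_length", 1),
        ("intra_burst_interval_s", np.nan), ("provenance", "unknown"),
    ):
        if col not in df.columns:
            df[col] = default
    df = df.sort_values("peak_time_s", kind="stable").reset_index(drop=True)
    df["peak_frame"] = df["peak_frame"].astype(int)
    df["burst_id"] = df["burst_id"].astype(int)
    df["burst_length"] = df["burst_length"].astype(int)
    extra = [c for c in df.columns if c not in EVENT_COLUMNS]
    return df[EVENT_COLUMNS + extra]


@dataclass
class SpectraTable:
    """Per-epoch channel x frequency power spectra in decibels.

    ``power`` has shape (n_epochs, n_channels, n_freqs); ``epochs`` carries
    one metadata row per epoch (``fly_id, state, time_bin, start_s, len_s,
    bout_id``).
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    channel_ids: np.ndarray
    epochs: pd.DataFrame

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.power.ndim != 3:
            raise ValueError("power must be (epochs, channels, freqs)")
        ne, nc, nf = self.power.shape
        if nc != len(self.channel_ids) or nf != len(self.freqs_hz):
            raise ValueError("power shape does not match channel/frequency grids")
        if len(self.epochs) != ne:
            raise ValueError("epoch metadata length mismatch")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("spectra contain non-finite cells")
        self.epochs = self.epochs.reset_index(drop=True)

    @property
    def shape(self):
        return self.power.shape

    def select(self, mask) -> "SpectraTable":
        mask = np.asarray(mask)
        return SpectraTable(
            self.power[mask], self.freqs_hz, self.channel_ids,
            self.epochs[mask].reset_index(drop=True),
        )

    def concat(self, other: "SpectraTable") -> "SpectraTable":
        if not np.allclose(self.freqs_hz, other.freqs_hz) or not np.array_equal(
            self.channel_ids, other.channel_ids
        ):
            raise ValueError("incompatible spectra grids")
        return SpectraTable(
            np.concatenate([self.power, other.power]),
            self.freqs_hz, self.channel_ids,
            pd.concat([self.epochs, other.epochs], ignore_index=True),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """CSV-friendly long format (fly, epoch, state, channel, freq, power)."""
        ne, nc, nf = self.power.shape
        meta = self.epochs
        idx = pd.MultiIndex.from_product(
            [range(ne), self.channel_ids, np.round(self.freqs_hz, 6)],
            names=["epoch", "channel", "freq_hz"],
        )
        df = pd.DataFrame({"power_db": self.power.ravel()}, index=idx).reset_index()
        df["fly_id"] = meta["fly_id"].to_numpy()[df["epoch"]]
        df["state"] = meta["state"].to_numpy()[df["epoch"]]
        return df[["fly_id", "epoch", "state", "channel", "freq_hz", "power_db"]]
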