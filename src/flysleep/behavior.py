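"""Movement quantification, sleep-bout detection and epoch labeling.

A fly is asleep when it has been completely immobile for more than five
minutes (the standard *Drosophila* sleep criterion).  Each sleep bout is then
partitioned into temporal stages: the 2 min of movement immediately before
immobility (``presleep``), the first 2 min of immobility (``earlysleep``),
the interior (``midsleep``) and the last 2 min (``latesleep``).  Two further
flanking bins — ``pre2`` (−4 to −2 min before bout start) and ``post2``
(the 2 min after waking) — are tagged for evaluation only and are never fed
to a classifier during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import dilation as binary_dilation

from .core import StateLabels

MIN_SLEEP_MIN = 5.0  # immobility must exceed this to count as sleep
STAGE_MIN = 2.0      # width (min) of presleep/early/late and flanking bins


@dataclass
class MovementFlags:
    """Per-frame moved/still flags with timestamps.

    ``moved`` is boolean per frame; ``areas`` optionally records the largest
    supra-threshold contour area per frame (px).
    """

    moved: np.ndarray
    fps: float
    timestamps: np.ndarray = None  # type: ignore[assignment]
    areas: np.ndarray | None = None

    def __post_init__(self):
        self.moved = np.asarray(self.moved, dtype=bool)
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.moved)) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.moved):
            raise ValueError("timestamps length mismatch")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.moved)


def _to_gray(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:  # color: mean over channels
        return frames.astype(np.float64).mean(axis=-1)
    return frames.astype(np.float64)


def quantify_movement(
    frames: np.ndarray,
    pixel_thresh: float,
    area_thresh: float,
    crop: tuple[int, int, int, int] | None = None,
    fps: float = 30.0,
    timestamps: np.ndarray | None = None,
    dilate_iterations: int = 2,
) -> MovementFlags:
    """Frame-differencing movement detector.

    Chain: crop -> grayscale -> absolute difference with the previous frame ->
    binarize at ``pixel_thresh`` -> dilate (3x3, ``dilate_iterations``) ->
    connected components -> frame is *moved* iff any component area >=
    ``area_thresh``.  Frame 0 is still by convention.
    """
    frames = np.asarray(frames)
    if frames.ndim not in (3, 4):
        raise ValueError("frames must be (n, h, w[, c])")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if pixel_thresh <= 0 or area_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if crop is not None:
        r0, r1, c0, c1 = crop
        frames = frames[:, r0:r1, c0:c1]
    gray = _to_gray(frames)
    delta = np.abs(np.diff(gray, axis=0))
    moved = np.zeros(len(frames), dtype=bool)
    areas = np.zeros(len(frames))
    footprint = np.ones((3, 3), dtype=bool)
    for i, d in enumerate(delta):
        binary = d > pixel_thresh
        if not binary.any():
            continue
        for _ in range(dilate_iterations):
            binary = binary_dilation(binary, footprint)
        labels = cc_label(binary, connectivity=2)
        if labels.max():
            sizes = np.bincount(labels.ravel())[1:]
            areas[i + 1] = sizes.max()
            moved[i + 1] = sizes.max() >= area_thresh
    return MovementFlags(moved, fps=fps, timestamps=timestamps, areas=areas)


def flags_from_activity(
    activity: np.ndarray,
    fps: float,
    area_thresh: float,
    timestamps: np.ndarray | None = None,
) -> MovementFlags:
    """Build MovementFlags from precomputed per-frame activity (area) values."""
    activity = np.asarray(activity, dtype=float)
    return MovementFlags(activity >= area_thresh, fps=fps,
                         timestamps=timestamps, areas=activity)


def _runs(x: np.ndarray):
    """(start, stop, value) runs of a boolean vector; stop is exclusive."""
    if len(x) == 0:
        return []
    change = np.flatnonzero(np.diff(x.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(x)]])
    return [(int(a), int(b), bool(x[a])) for a, b in zip(starts, stops)]


def _run_duration(flags: MovementFlags, a: int, b: int) -> float:
    """Duration of frames [a, b) using timestamps (last frame spans 1/fps)."""
    t = flags.timestamps
    end = t[b] if b < len(t) else t[-1] + 1.0 / flags.fps
    return float(end - t[a])


def prune_movement(
    flags: MovementFlags, min_move_s: float = 1.0, min_still_s: float = 1.0
) -> MovementFlags:
    """Remove brief movement noise, then brief still gaps.

    Movement runs shorter than ``min_move_s`` become still; afterwards still
    runs shorter than ``min_still_s`` become moved.  Idempotent on its own
    output.
    """
    if min_move_s < 0 or min_still_s < 0:
        raise ValueError("durations must be non-negative")
    moved = flags.moved.copy()
    for a, b, val in _runs(moved):
        if val and _run_duration(flags, a, b) < min_move_s:
            moved[a:b] = False
    for a, b, val in _runs(moved):
        if not val and _run_duration(flags, a, b) < min_still_s:
            moved[a:b] = True
    return MovementFlags(moved, fps=flags.fps, timestamps=flags.timestamps,
                         areas=flags.areas)


def detect_sleep_bouts(
    flags: MovementFlags, min_sleep_min: float = MIN_SLEEP_MIN
) -> StateLabels:
    """Sleep/awake interval labels from pruned movement flags.

    Maximal still runs strictly longer than ``min_sleep_min`` minutes become
    sleep bouts (ties at exactly the threshold stay awake); everything else
    is awake.  Bout ids are assigned in time order.
    """
    t0 = float(flags.timestamps[0])
    t_end = float(flags.timestamps[-1] + 1.0 / flags.fps)
    rows = []
    bout_id = 0
    cursor = t0
    for a, b, val in _runs(flags.moved):
        if val:
            continue
        start = float(flags.timestamps[a])
        dur = _run_duration(flags, a, b)
        if dur > min_sleep_min * 60.0:
            if start > cursor:
                rows.append((cursor, start, "awake", -1))
            rows.append((start, start + dur, "sleep", bout_id))
            bout_id += 1
            cursor = start + dur
    if cursor < t_end:
        rows.append((cursor, t_end, "awake", -1))
    if not rows:
        rows.append((t0, t_end, "awake", -1))
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label", "bout_id"])
    return StateLabels(df, session_start_s=t0, session_end_s=t_end)


def label_epochs(bouts: StateLabels) -> StateLabels:
    """Expand sleep/awake labels into the full five-state + flanking scheme.

    Per bout: ``presleep`` = [-2, 0) min before bout start, ``earlysleep`` =
    first 2 min, ``latesleep`` = last 2 min, ``midsleep`` = the remainder;
    evaluation-only ``pre2`` = [-4, -2) and ``post2`` = the 2 min after
    waking.  When the awake gap between two bouts is too short for both
    bouts' flanking bins, bins are clipped at the gap midpoint with the
    sleep-side bins (presleep) taking priority over the awake-side ones
    (post2).
    """
    t0, t_end = bouts.session_start_s, bouts.session_end_s
    bt = bouts.bouts()
    stage = STAGE_MIN * 60.0
    rows = []
    for i, bout in bt.iterrows():
        s, e, bid = float(bout["start_s"]), float(bout["end_s"]), int(bout["bout_id"])
        prev_end = float(bt["end_s"].iloc[i - 1]) if i > 0 else t0
        next_start = float(bt["start_s"].iloc[i + 1]) if i + 1 < len(bt) else t_end
        # awake-side bins before the bout, clipped at the midpoint of the
        # preceding gap (sleep-side presleep wins over the previous post2)
        gap_lo = prev_end if i == 0 else max(prev_end, (prev_end + s) / 2.0)
        pre_lo = max(s - stage, gap_lo, t0)
        if pre_lo < s:
            rows.append((pre_lo, s, "presleep", bid))
        pre2_lo = max(s - 2 * stage, gap_lo, t0)
        if pre2_lo < pre_lo:
            rows.append((pre2_lo, pre_lo, "pre2", bid))
        # within-bout stages
        rows.append((s, s + stage, "earlysleep", bid))
        rows.append((max(s + stage, e - stage), e, "latesleep", bid))
        if s + stage < e - stage:
            rows.append((s + stage, e - stage, "midsleep", bid))
        # post-waking bin, clipped at the midpoint of the following gap
        gap_hi = next_start if i + 1 >= len(bt) else (e + next_start) / 2.0
        post_hi = min(e + stage, gap_hi, t_end)
        if post_hi > e:
            rows.append((e, post_hi, "post2", bid))
    labeled = pd.DataFrame(rows, columns=["start_s", "end_s", "label", "bout_id"])
    labeled = labeled.sort_values("start_s").reset_index(drop=True)
    # fill the remaining time with awake
    out_rows = []
    cursor = t0
    for _, r in labeled.iterrows():
        if r["start_s"] > cursor + 1e-9:
            out_rows.append((cursor, r["start_s"], "awake", -1))
        out_rows.append(tuple(r))
        cursor = max(cursor, r["end_s"])
    if cursor < t_end - 1e-9:
        out_rows.append((cursor, t_end, "awake", -1))
    df = pd.DataFrame(out_rows, columns=["start_s", "end_s", "label", "bout_id"])
    return StateLabels(df, session_start_s=t0, session_end_s=t_end)


def bout_summary(
    bouts: StateLabels,
    lights_on_h: float = 8.0,
    lights_off_h: float = 20.0,
    session_start_clock_h: float = 8.0,
) -> pd.DataFrame:
    """Day/night bout-duration medians, partitioned by bout onset clock time.

    Returns one row per period with ``n_bouts`` and ``median_min``; a period
    with no bouts is flagged with ``median_min = NaN``.
    """
    bt = bouts.bouts()
    onset_clock = (session_start_clock_h + bt["start_s"] / 3600.0) % 24.0
    is_day = (onset_clock >= lights_on_h) & (onset_clock < lights_off_h)
    dur_min = (bt["end_s"] - bt["start_s"]) / 60.0
    rows = []
    for period, mask in (("day", is_day), ("night", ~is_day)):
        sel = dur_min[mask]
        rows.append((period, int(mask.sum()),
                     float(sel.median()) if len(sel) else np.nan))
    return pd.DataFrame(rows, columns=["period", "n_bouts", "median_min"])


def movement_agreement(flags: MovementFlags, truth: MovementFlags) -> float:
    """Frame-level moved/still agreement between two flag series."""
    n = min(len(flags), len(truth))
    return float(np.mean(flags.moved[:n] == truth.moved[:n]))


def auto_pixel_threshold(frames: np.ndarray, percentile: float = 99.5) -> float:
    """Percentile-of-deltaframe heuristic for the per-fly binarization
    threshold (an artifact convention; the choice is always overridable)."""
    gray = _to_gray(np.asarray(frames))
    delta = np.abs(np.diff(gray, axis=0))
    return float(np.percentile(delta, percentile))
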