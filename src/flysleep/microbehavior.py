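"""Proboscis-extension detection, burst grouping and antennal periodicity.

Sleeping flies show stereotyped micro-behaviors: rhythmic proboscis
extensions (PEs) concentrated deep in sleep bouts, and slow antennal
oscillations.  Two complementary PE detectors are provided: a per-frame
SVM classifier over pose-derived features (the electrophysiology-rig route)
and a peak-picking detector on the proboscis-to-resting-position distance
with artifact exclusions (the behavior-rig route).  Detected events are
grouped into bursts when consecutive events fall within 10 s of each other,
and an event is *periodic* when its predecessor occurred less than 6 s
earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import PoseTrack, StateLabels, as_event_table, empty_events

PE_BURST_GAP_S = 10.0
PE_PERIODIC_MAX_GAP_S = 6.0

#: Parts whose filtered coordinates feed the per-frame PE classifier.
PE_FEATURE_PARTS = ("proboscis", "leg1_tip", "leg1_joint", "eye", "abdomen")


@dataclass
class PEFeatureTable:
    """Per-frame features for PE classification.

    ``frame`` holds, per body part, the raw and 0.1 Hz low-passed x/y, a
    centered 5-sample moving average of the filtered series, and
    ``dist_eyeprob``: the proboscis-eye Euclidean distance multiplied by the
    proboscis likelihood.
    """

    frame: pd.DataFrame
    fps: float

    @property
    def dist_eyeprob(self) -> np.ndarray:
        return self.frame["dist_eyeprob"].to_numpy()

    def matrix(self) -> np.ndarray:
        return self.frame.drop(columns=["nan_masked"]).to_numpy(dtype=float)


def compute_pe_features(
    pose: PoseTrack, parts=PE_FEATURE_PARTS, cutoff_hz: float = 0.1,
    ma_window: int = 5,
) -> PEFeatureTable:
    """Pose-derived per-frame feature table.

    NaN coordinates are interpolated, their likelihood forced to 0 and the
    frame flagged in ``nan_masked``.
    """
    missing = [p for p in parts if p not in pose.parts]
    if missing:
        raise ValueError(f"pose track lacks required parts: {missing}")
    fps = pose.fps
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fps, output="sos")
    cols: dict[str, np.ndarray] = {}
    nan_mask = np.zeros(pose.n_frames, dtype=bool)
    lk_by_part = {}
    for part in parts:
        xy = pose.xy(part)
        lk = pose.likelihood(part).copy()
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            nan_mask |= bad
            lk[bad] = 0.0
            for j in range(2):
                col = xy[:, j]
                good = np.isfinite(col)
                col[~good] = np.interp(
                    np.flatnonzero(~good), np.flatnonzero(good), col[good]
                )
        lk_by_part[part] = lk
        for j, coord in enumerate(("x", "y")):
            raw = xy[:, j]
            filt = signal.sosfiltfilt(sos, raw)
            ma = (
                pd.Series(filt).rolling(ma_window, center=True, min_periods=1)
                .mean().to_numpy()
            )
            cols[f"{part}_{coord}"] = raw
            cols[f"{part}_{coord}_filt"] = filt
            cols[f"{part}_{coord}_ma"] = ma
        cols[f"{part}_likelihood"] = lk
    d = np.linalg.norm(
        pose.xy("proboscis") - pose.xy("eye"), axis=1
    )
    d = np.nan_to_num(d, nan=0.0)
    cols["dist_eyeprob"] = d * lk_by_part["proboscis"]
    cols["nan_masked"] = nan_mask
    return PEFeatureTable(pd.DataFrame(cols), fps=fps)


@dataclass
class PEClassifier:
    scaler: StandardScaler
    model: SVC
    metrics: dict

    def predict(self, features: PEFeatureTable) -> np.ndarray:
        return self.model.predict(
            self.scaler.transform(features.matrix())
        ).astype(bool)


def train_pe_classifier(
    features: PEFeatureTable,
    ground_truth_frames,
    test_fraction: float = 0.30,
    seed: int = 0,
) -> PEClassifier:
    """RBF-kernel SVM classifying frames as PE vs not.

    Standardization is fit on the training frames only; accuracy, precision
    and recall are reported on the held-out fraction.
    """
    from sklearn.model_selection import train_test_split

    y = np.zeros(len(features.frame), dtype=bool)
    y[np.asarray(list(ground_truth_frames), dtype=int)] = True
    if y.all() or not y.any():
        raise ValueError("ground truth must contain both classes")
    X = features.matrix()
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    scaler = StandardScaler().fit(Xtr)
    model = SVC(kernel="rbf", random_state=seed)
    model.fit(scaler.transform(Xtr), ytr)
    pred = model.predict(scaler.transform(Xte))
    metrics = {
        "accuracy": float(accuracy_score(yte, pred)),
        "precision": float(precision_score(yte, pred, zero_division=0)),
        "recall": float(recall_score(yte, pred, zero_division=0)),
    }
    return PEClassifier(scaler=scaler, model=model, metrics=metrics)


def _segments_from_mask(mask: np.ndarray, fps: float, merge_gap_s: float):
    """Contiguous True segments, merging gaps shorter than ``merge_gap_s``."""
    idx = np.flatnonzero(mask)
    if not len(idx):
        return []
    gap = max(1, int(round(merge_gap_s * fps)))
    splits = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    stops = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def _split_subevents(dist: np.ndarray, a: int, b: int):
    """Split a candidate segment at internal minima below 50% of the
    neighboring peaks, yielding one sub-event window per extension."""
    seg = dist[a:b]
    if len(seg) < 3:
        return [(a, b)]
    peaks, _ = signal.find_peaks(seg)
    if len(peaks) < 2:
        return [(a, b)]
    windows = []
    start = 0
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        valley = p0 + int(np.argmin(seg[p0:p1 + 1]))
        if seg[valley] < 0.5 * min(seg[p0], seg[p1]):
            windows.append((a + start, a + valley + 1))
            start = valley + 1
    windows.append((a + start, b))
    return windows


def detect_pe_events(
    features: PEFeatureTable,
    positive_frames: np.ndarray | None = None,
    likelihood_thresh: float = 0.9,
    labels: StateLabels | None = None,
    merge_gap_s: float = 0.2,
) -> pd.DataFrame:
    """PE events from classifier output augmented by a likelihood threshold.

    Positive frames are merged into candidate segments; frames whose
    proboscis likelihood crosses ``likelihood_thresh`` are added; within
    each extension the peak frame is the maximum proboscis-eye displacement.
    """
    if positive_frames is None and likelihood_thresh is None:
        raise ValueError("need a classifier output or a likelihood threshold")
    n = len(features.frame)
    mask = np.zeros(n, dtype=bool)
    if positive_frames is not None:
        mask |= np.asarray(positive_frames, dtype=bool)
    if likelihood_thresh is not None:
        mask |= (
            features.frame["proboscis_likelihood"].to_numpy()
            >= likelihood_thresh
        )
    dist = features.dist_eyeprob
    rows = []
    for a, b in _segments_from_mask(mask, features.fps, merge_gap_s):
        for wa, wb in _split_subevents(dist, a, b):
            peak = wa + int(np.argmax(dist[wa:wb]))
            t = peak / features.fps
            rows.append({
                "peak_frame": peak,
                "peak_time_s": t,
                "state": labels.label_at(t) or "" if labels is not None else "",
                "provenance": "classifier",
            })
    if not rows:
        return empty_events()
    return as_event_table(pd.DataFrame(rows))


def review_export(events: pd.DataFrame, path=None) -> pd.DataFrame:
    """Frame-number spot-check table standing in for manual verification."""
    out = events[["peak_frame", "peak_time_s", "state", "provenance"]].copy()
    out["verified"] = ""
    if path is not None:
        out.to_csv(path, index=False)
    return out


def detect_pe_peaks(
    distance: np.ndarray,
    fps: float,
    height: float,
    max_dist_px: float,
    min_rise_s: float = 0.1,
    angle: np.ndarray | None = None,
) -> pd.DataFrame:
    """Peak-picking PE detector on distance-from-resting-position data.

    ``distance`` is measured from the per-recording median proboscis
    position (the assumed resting position).  Exclusions, in order:
    amplitude above ``max_dist_px`` (tracking artifact), single-frame peaks,
    and implausibly fast rises (baseline-to-peak in under ``min_rise_s``).
    """
    d = np.asarray(distance, dtype=float)
    peaks, props = signal.find_peaks(d, height=height)
    rows = []
    half_level = 0.5
    for p in peaks:
        amp = d[p]
        if amp > max_dist_px:
            continue
        lo = p
        while lo > 0 and d[lo - 1] > half_level * amp:
            lo -= 1
        hi = p
        while hi < len(d) - 1 and d[hi + 1] > half_level * amp:
            hi += 1
        if hi == lo:  # single-frame spike
            continue
        rise_s = (p - lo + 1) / fps
        if rise_s < min_rise_s:
            continue
        rows.append({
            "peak_frame": int(p),
            "peak_time_s": p / fps,
            "duration_s": (hi - lo + 1) / fps,
            "median_angle_deg": (
                float(np.median(angle[lo:hi + 1])) if angle is not None
                else np.nan
            ),
            "provenance": "peak-picker",
        })
    if not rows:
        ev = empty_events()
        ev["duration_s"] = pd.Series(dtype=float)
        ev["median_angle_deg"] = pd.Series(dtype=float)
        return ev
    return as_event_table(pd.DataFrame(rows))


def detect_pe_threshold(
    distance: np.ndarray,
    fps: float,
    thresh: float,
    angle: np.ndarray | None = None,
) -> pd.DataFrame:
    """Threshold-based PE detector (per-fly manual threshold route):
    contiguous supra-threshold runs become events with duration and median
    angle."""
    d = np.asarray(distance, dtype=float)
    rows = []
    for a, b in _segments_from_mask(d > thresh, fps, merge_gap_s=0.0):
        p = a + int(np.argmax(d[a:b]))
        rows.append({
            "peak_frame": int(p),
            "peak_time_s": p / fps,
            "duration_s": (b - a) / fps,
            "median_angle_deg": (
                float(np.median(angle[a:b])) if angle is not None else np.nan
            ),
            "provenance": "threshold",
        })
    if not rows:
        return empty_events()
    return as_event_table(pd.DataFrame(rows))


def group_bursts(events: pd.DataFrame, gap_s: float = PE_BURST_GAP_S) -> pd.DataFrame:
    """Single-linkage burst grouping.

    Consecutive events no more than ``gap_s`` apart share a burst; fills
    ``burst_id``, ``burst_length`` and the intra-burst interval to the
    previous event.  Idempotent; conserves events.
    """
    ev = as_event_table(events)
    if ev.empty:
        return ev
    t = ev["peak_time_s"].to_numpy()
    new_burst = np.concatenate([[True], np.diff(t) > gap_s])
    burst_id = np.cumsum(new_burst) - 1
    ev["burst_id"] = burst_id
    ev["burst_length"] = ev.groupby("burst_id")["peak_time_s"].transform("size")
    iei = ev.groupby("burst_id")["peak_time_s"].diff()
    ev["intra_burst_interval_s"] = iei
    return ev


def burst_composition(events: pd.DataFrame) -> dict:
    """Single vs multi burst fractions and the mean intra-burst interval."""
    if events.empty:
        return {"n_bursts": 0, "single_fraction": np.nan,
                "mean_intra_burst_interval_s": np.nan}
    per_burst = events.groupby("burst_id")["burst_length"].first()
    return {
        "n_bursts": int(len(per_burst)),
        "single_fraction": float((per_burst == 1).mean()),
        "mean_intra_burst_interval_s": float(
            events["intra_burst_interval_s"].mean()
        ),
    }


def antenna_angles(pose: PoseTrack) -> pd.DataFrame:
    """Head-axis-corrected antennal angles in degrees, unwrapped.

    The head axis is the anterior normal of the line joining the two
    antenna bases, so a rigid rotation of the whole head leaves the angles
    unchanged.  Positive values are anterior sweeps; a tip pointing straight
    ahead along the head axis reads 0.  Frames with coincident base/tip are
    masked (NaN).
    """
    need = ["antenna_L_base", "antenna_L_tip", "antenna_R_base", "antenna_R_tip"]
    missing = [p for p in need if p not in pose.parts]
    if missing:
        raise ValueError(f"pose track lacks antennal parts: {missing}")
    bl, br = pose.xy("antenna_L_base"), pose.xy("antenna_R_base")
    inter = br - bl
    head = np.arctan2(inter[:, 1], inter[:, 0]) - np.pi / 2.0  # anterior normal
    out = {}
    for side, sign in (("L", 1.0), ("R", -1.0)):
        base = pose.xy(f"antenna_{side}_base")
        tip = pose.xy(f"antenna_{side}_tip")
        v = tip - base
        degenerate = np.linalg.norm(v, axis=1) < 1e-9
        ang = np.arctan2(v[:, 1], v[:, 0]) - head
        ang = np.angle(np.exp(1j * ang))  # wrap to (-pi, pi]
        ang = np.unwrap(ang) * sign
        deg = np.rad2deg(ang)
        deg[degenerate] = np.nan
        out[f"antenna_{side}"] = deg
    return pd.DataFrame(out)


def antenna_periodicity(
    angle: np.ndarray,
    fps: float,
    window_s: float = 30.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (0.1, 5.0),
    peak_criterion: float = 6.0,
    organ: str = "antenna_L",
) -> pd.DataFrame:
    """Sliding-window FFT periodicity detection for antennal angle series.

    A window is periodic when its in-band spectral peak exceeds
    ``peak_criterion`` times the median spectral magnitude; the dominant
    in-band frequency is reported for periodic windows.
    """
    x = np.asarray(angle, dtype=float)
    n_win = int(round(window_s * fps))
    if n_win > len(x):
        raise ValueError("window longer than series")
    step = max(1, int(round(n_win * (1.0 - overlap))))
    freqs = np.fft.rfftfreq(n_win, 1.0 / fps)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    rows = []
    for a in range(0, len(x) - n_win + 1, step):
        seg = x[a:a + n_win]
        if np.isnan(seg).any():
            seg = np.nan_to_num(seg, nan=np.nanmean(seg))
        mag = np.abs(np.fft.rfft(seg - seg.mean()))
        med = np.median(mag[1:])
        peak_idx = np.argmax(np.where(in_band, mag, 0.0))
        periodic = bool(mag[peak_idx] > peak_criterion * max(med, 1e-12))
        rows.append({
            "start_s": a / fps,
            "end_s": (a + n_win) / fps,
            "organ": organ,
            "periodic": periodic,
            "dominant_freq_hz": float(freqs[peak_idx]) if periodic else np.nan,
        })
    return pd.DataFrame(rows)


def proboscis_periodicity(
    events: pd.DataFrame, max_gap_s: float = PE_PERIODIC_MAX_GAP_S
) -> pd.DataFrame:
    """Flag each PE event periodic iff its predecessor is < ``max_gap_s``
    earlier (proboscis activity is not sinusoidal, so no FFT is used)."""
    ev = as_event_table(events)
    t = ev["peak_time_s"].to_numpy()
    periodic = np.concatenate([[False], np.diff(t) < max_gap_s]) if len(t) else (
        np.zeros(0, dtype=bool)
    )
    ev = ev.copy()
    ev["periodic"] = periodic
    return ev


def periodic_fraction_by_state(
    events: pd.DataFrame, labels: StateLabels
) -> pd.DataFrame:
    """Fraction of sleep vs wake time whose PE events are periodic."""
    ev = proboscis_periodicity(events)
    sleep_states = {"earlysleep", "midsleep", "latesleep"}
    rows = []
    for name, pred in (("sleep", lambda s: s in sleep_states),
                       ("wake", lambda s: s not in sleep_states)):
        sub = ev[[pred(labels.label_at(t) or "awake")
                  for t in ev["peak_time_s"]]] if len(ev) else ev
        rows.append({
            "state": name,
            "n_events": int(len(sub)),
            "periodic_fraction": float(sub["periodic"].mean()) if len(sub)
            else np.nan,
        })
    return pd.DataFrame(rows)


def pe_depth_summary(events: pd.DataFrame, labels: StateLabels) -> dict:
    """Event counts by sleep depth and epoch-relative bin.

    Returns counts before/after the 5th minute of sleep bouts (and, as a
    control, of awake bouts), normalized event counts per relative-time bin,
    and the time-into-midsleep distribution with its 95th-percentile onset.
    """
    ev = as_event_table(events)
    bouts = labels.bouts()
    t = ev["peak_time_s"].to_numpy()
    before5 = after5 = 0
    into_mid = []
    for _, b in bouts.iterrows():
        rel = t[(t >= b["start_s"]) & (t < b["end_s"])] - b["start_s"]
        before5 += int((rel < 300.0).sum())
        after5 += int((rel >= 300.0).sum())
    mid = labels.of_labels(["midsleep"])
    for _, iv in mid.iterrows():
        sel = t[(t >= iv["start_s"]) & (t < iv["end_s"])]
        into_mid.extend((sel - iv["start_s"]).tolist())
    # awake-bout control: contiguous awake stretches between bouts
    aw_before5 = aw_after5 = 0
    for _, iv in labels.of_labels(["awake"]).iterrows():
        rel = t[(t >= iv["start_s"]) & (t < iv["end_s"])] - iv["start_s"]
        aw_before5 += int((rel < 300.0).sum())
        aw_after5 += int((rel >= 300.0).sum())
    # normalized counts per relative-time bin
    bins = {}
    for _, iv in labels.intervals.iterrows():
        sel = (t >= iv["start_s"]) & (t < iv["end_s"])
        n_ev = int(sel.sum())
        lab = iv["label"]
        if lab == "awake":
            continue
        if lab == "midsleep":
            keys = [("mid", iv["end_s"] - iv["start_s"], n_ev)]
        else:
            # split two-minute stages into their two one-minute bins
            mid_t = (iv["start_s"] + iv["end_s"]) / 2.0
            first = int(((t >= iv["start_s"]) & (t < mid_t)).sum())
            names = {
                "presleep": ("-2:-1", "-1:0"), "earlysleep": ("+0:+1", "+1:+2"),
                "latesleep": ("x:-2", "x:-1"), "pre2": ("-4:-3", "-3:-2"),
                "post2": ("x:+1", "x:+2"),
            }[lab]
            half = (iv["end_s"] - iv["start_s"]) / 2.0
            keys = [(names[0], half, first), (names[1], half, n_ev - first)]
        for name, dur, cnt in keys:
            total = bins.setdefault(name, [0.0, 0])
            total[0] += dur
            total[1] += cnt
    norm = {
        k: (v[1] / (v[0] / 60.0) if v[0] > 0 else np.nan)
        for k, v in bins.items()
    }
    into_mid = np.asarray(into_mid)
    return {
        "sleep_before_5min": before5,
        "sleep_after_5min": after5,
        "awake_before_5min": aw_before5,
        "awake_after_5min": aw_after5,
        "normalized_counts_per_min": norm,
        "time_into_midsleep_s": into_mid,
        "midsleep_onset_p95_s": (
            float(np.percentile(into_mid, 95)) if len(into_mid) else np.nan
        ),
    }


def match_events(
    detected: pd.DataFrame, truth: pd.DataFrame, tol_s: float = 0.25
) -> dict:
    """Event-level precision/recall by greedy nearest matching within
    ``tol_s`` (each truth event matches at most one detection)."""
    td = detected["peak_time_s"].to_numpy() if len(detected) else np.array([])
    tt = truth["peak_time_s"].to_numpy() if len(truth) else np.array([])
    used = np.zeros(len(td), dtype=bool)
    hits = 0
    for t in tt:
        if not len(td):
            break
        free = np.flatnonzero(~used)
        if not len(free):
            break
        j = free[np.argmin(np.abs(td[free] - t))]
        if abs(td[j] - t) <= tol_s:
            used[j] = True
            hits += 1
    precision = hits / len(td) if len(td) else np.nan
    recall = hits / len(tt) if len(tt) else np.nan
    return {"precision": float(precision), "recall": float(recall),
            "n_detected": int(len(td)), "n_truth": int(len(tt))}
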