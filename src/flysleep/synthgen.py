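"""Synthetic recording sessions with ground truth.

The generator emulates the statistical structure of long-term tethered-fly
recordings: 16-channel LFP with 1/f-shaped background noise plus a shared
broadband component whose channel weights flip sign at the polarity-reversal
electrode; state-dependent 5-40 Hz power (awake > early/late sleep >
midsleep); an extra 5-10 Hz component on central channels (1-3) during sleep
with a distinct amplitude per stage, making sleep stages separable; a
visual-stimulus calibration segment with evoked deflections; per-frame
movement activity that is high only outside sleep bouts; pose tables with
proboscis-extension pulses and sleep-gated antennal oscillation; and
ground-truth labels and events for every stream.

Every stream derives from a single seeded generator, so a config + seed pair
reproduces a session bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import behavior
from .core import PoseTrack, Recording, StateLabels, as_event_table

#: Amplitude scale of the central 5-10 Hz component per stage (midsleep = 1);
#: distinct values keep the five classes separable for the staging analyses.
THETA_STAGE_SCALE = {
    "presleep": 0.45, "earlysleep": 0.75, "midsleep": 1.0, "latesleep": 1.35,
}


@dataclass
class SimConfig:
    """Parameters of a synthetic recording session.

    Durations are minutes unless suffixed; amplitudes are microvolts (LFP)
    or pixels (pose).  Gains are multiplicative *power* factors relative to
    midsleep; the construction requires
    ``awake_power_gain > early_late_gain > 1`` so the stages are separable
    by broadband power alone.
    """

    n_flies: int = 16
    session_hours: float = 8.0
    fs_lfp: float = 250.0
    fs_lfp_raw: float | None = None  # emit raw at this rate to exercise resampling
    fps_video: float = 30.0
    n_channels: int = 16
    reversal_channel: int = 12
    session_start_clock_h: float = 8.0
    # sleep-bout process
    bout_mean_min: float = 12.0
    bout_sd_min: float = 4.0
    bout_min_min: float = 6.0
    interbout_mean_min: float = 14.0
    interbout_sd_min: float = 5.0
    interbout_min_min: float = 5.0
    night_bout_factor: float = 1.0
    sleep_probability: float = 1.0
    # spectral structure
    awake_power_gain: float = 2.0
    early_late_gain: float = 1.4
    central_theta_boost: float = 2.0  # 5-10 Hz power factor, channels 1-3, midsleep
    theta_band: tuple[float, float] = (5.0, 10.0)
    theta_channels: tuple[int, ...] = (1, 2, 3)
    noise_sd: float = 10.0
    shared_sd: float = 8.0
    sensor_sd: float = 0.5
    pink_exponent: float = 1.0
    hour_offset_sd: float = 15.0  # per-chunk DC offsets (exercises stitching)
    # calibration
    evoked_amp: float = 40.0
    calib_n_trains: int = 10
    # proboscis-extension process
    pe_rate_wake: float = 0.3       # events/min in awake time
    pe_rate_midsleep: float = 3.0   # events/min deep in midsleep
    pe_depth_onset_min: float = 2.5  # low-rate head of each midsleep interval
    pe_intra_burst_interval_s: float = 1.5
    pe_burst_gap_s: float = 12.0
    pe_single_fraction: float = 0.33
    pe_burst_len_mean: float = 4.0
    # pose kinematics
    pe_amplitude_px: float = 12.0
    pe_duration_s: float = 0.5
    pose_jitter_px: float = 0.4
    antenna_osc_freq_hz: float = 1.0
    antenna_osc_amp_deg: float = 8.0
    occlusion_rate_per_hour: float = 2.0
    occlusion_dur_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        positive = [
            "session_hours", "fs_lfp", "fps_video", "bout_mean_min",
            "bout_sd_min", "interbout_mean_min", "interbout_sd_min",
            "awake_power_gain", "early_late_gain", "central_theta_boost",
            "noise_sd", "pe_intra_burst_interval_s", "pe_burst_gap_s",
            "antenna_osc_freq_hz", "pe_amplitude_px", "pe_duration_s",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 1 <= self.reversal_channel <= self.n_channels:
            raise ValueError("reversal_channel outside channel range")
        if not self.awake_power_gain > self.early_late_gain > 1.0:
            raise ValueError(
                "need awake_power_gain > early_late_gain > 1 for stage separability"
            )
        if self.pe_burst_gap_s < 10.0:
            raise ValueError("pe_burst_gap_s must be >= 10 s to separate bursts")
        if not 0.0 <= self.sleep_probability <= 1.0:
            raise ValueError("sleep_probability must lie in [0, 1]")


@dataclass
class SimSession:
    """A complete synthetic session with ground truth."""

    recording: Recording
    calibration: Recording
    stimulus_onsets_s: np.ndarray
    movement_activity: np.ndarray  # per-frame contour-area-like values
    pose: PoseTrack
    truth_bouts: StateLabels   # sleep/awake only
    truth_labels: StateLabels  # full five-state + flanking scheme
    truth_events: pd.DataFrame
    config: SimConfig
    seed: int = field(init=False)

    def __post_init__(self):
        self.seed = self.config.seed


# ---------------------------------------------------------------------------
# signal primitives

def _shaped_noise(rng, n, fs, band, exponent=0.0, sd=1.0):
    """Gaussian noise band-limited to ``band`` with a 1/f**exponent spectrum."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(f)
    in_band = (f >= band[0]) & (f <= band[1])
    gain[in_band] = f[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_power_fraction(band, sub, exponent):
    """Fraction of a 1/f**a band-limited process's power inside ``sub``."""
    def integral(a, b):
        if exponent == 1.0:
            return np.log(b / a)
        p = 1.0 - exponent
        return (b ** p - a ** p) / p
    return integral(*sub) / integral(*band)


def reversal_weights(n_channels: int, reversal_channel: int) -> np.ndarray:
    """Signed channel weights of the shared component: a clipped linear ramp
    crossing zero at the reversal channel (peripheral positive, central
    negative), with full slope near the crossing so the sign change is sharp.
    """
    idx = np.arange(1, n_channels + 1, dtype=float)
    return np.clip((idx - reversal_channel) / 2.0, -1.0, 1.0)


# ---------------------------------------------------------------------------
# behavioral ground truth

def _draw_bouts(rng, cfg: SimConfig) -> StateLabels:
    total_s = cfg.session_hours * 3600.0
    if cfg.sleep_probability > 0 and total_s < (
        cfg.interbout_min_min + cfg.bout_min_min
    ) * 60.0:
        raise ValueError(
            f"session of {cfg.session_hours} h cannot contain a "
            f">= 5 min sleep bout after >= {cfg.interbout_min_min} min awake "
            f"(bout_mean_min={cfg.bout_mean_min}, "
            f"interbout_mean_min={cfg.interbout_mean_min})"
        )

    def trunc_normal(mean, sd, lo):
        for _ in range(100):
            x = rng.normal(mean, sd)
            if x >= lo:
                return x
        return lo

    rows, t, bout_id = [], 0.0, 0
    while t < total_s:
        awake_dur = trunc_normal(cfg.interbout_mean_min, cfg.interbout_sd_min,
                                 cfg.interbout_min_min) * 60.0
        sleep_roll = rng.random()
        bout_dur = trunc_normal(cfg.bout_mean_min, cfg.bout_sd_min,
                                cfg.bout_min_min) * 60.0
        awake_end = min(t + awake_dur, total_s)
        if sleep_roll >= cfg.sleep_probability or awake_end + bout_dur > total_s:
            rows.append((t, awake_end, "awake", -1))
            t = awake_end
            if sleep_roll >= cfg.sleep_probability:
                continue
            break
        clock = (cfg.session_start_clock_h + awake_end / 3600.0) % 24.0
        if not 8.0 <= clock < 20.0:
            bout_dur *= cfg.night_bout_factor
        bout_end = min(awake_end + bout_dur, total_s)
        rows.append((t, awake_end, "awake", -1))
        rows.append((awake_end, bout_end, "sleep", bout_id))
        bout_id += 1
        t = bout_end
    if t < total_s:
        rows.append((t, total_s, "awake", -1))
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label", "bout_id"])
    return StateLabels(df, session_start_s=0.0, session_end_s=total_s)


def _simulate_movement(rng, bouts: StateLabels, cfg: SimConfig) -> np.ndarray:
    """Per-frame activity values: bursty movement outside bouts, zero inside."""
    fps = cfg.fps_video
    n = int(round(bouts.session_end_s * fps))
    activity = np.zeros(n)
    for _, iv in bouts.intervals.iterrows():
        if iv["label"] != "awake":
            continue
        a = int(round(iv["start_s"] * fps))
        b = min(int(round(iv["end_s"] * fps)), n)
        t = a
        moving = True
        while t < b:
            dur = rng.exponential(8.0 if moving else 0.5)
            k = max(1, int(round(dur * fps)))
            if moving:
                activity[t:min(t + k, b)] = rng.lognormal(
                    np.log(300.0), 0.4, size=min(t + k, b) - t
                )
            t += k
            moving = not moving
        # anchor boundaries: movement right up to bout start / after bout end
        edge = int(2 * fps)
        activity[max(a, b - edge):b] = rng.lognormal(np.log(300.0), 0.4, size=min(edge, b - a))
        activity[a:min(a + edge, b)] = rng.lognormal(np.log(300.0), 0.4, size=min(edge, b - a))
    return activity


def _simulate_pe_truth(rng, labels: StateLabels, cfg: SimConfig) -> pd.DataFrame:
    """Burst-structured proboscis-extension ground truth events."""
    events = []
    burst_id = 0
    last_event_t = -np.inf
    mean_len = (
        cfg.pe_single_fraction * 1.0
        + (1 - cfg.pe_single_fraction) * cfg.pe_burst_len_mean
    )
    for _, iv in labels.intervals.iterrows():
        lab = iv["label"]
        if lab in ("awake", "presleep", "pre2", "post2"):
            rate_fn = lambda t: cfg.pe_rate_wake  # noqa: E731
        elif lab == "midsleep":
            onset = iv["start_s"] + cfg.pe_depth_onset_min * 60.0
            rate_fn = lambda t, onset=onset: (  # noqa: E731
                cfg.pe_rate_midsleep if t >= onset else 0.25 * cfg.pe_rate_midsleep
            )
        else:
            continue
        t = float(iv["start_s"])
        end = float(iv["end_s"])
        # inhomogeneous Poisson burst onsets by thinning at the peak rate
        rate_max = max(rate_fn(t), rate_fn(end)) / mean_len / 60.0
        while True:
            t += rng.exponential(1.0 / max(rate_max, 1e-9))
            t = max(t, last_event_t + cfg.pe_burst_gap_s + 1.0)
            if t >= end:
                break
            accept = rate_fn(t) / mean_len / 60.0 / rate_max
            if rng.random() >= accept:
                continue
            if rng.random() < cfg.pe_single_fraction:
                length = 1
            else:
                p = 1.0 / max(cfg.pe_burst_len_mean - 1.0, 1.0)
                length = 1 + int(rng.geometric(p))
            for k in range(length):
                et = t + k * cfg.pe_intra_burst_interval_s + (
                    rng.normal(0.0, 0.03) if k else 0.0
                )
                if et >= end - cfg.pe_duration_s:
                    break
                events.append({
                    "peak_time_s": et,
                    "peak_frame": int(round(et * cfg.fps_video)),
                    "state": lab,
                    "burst_id": burst_id,
                    "provenance": "truth",
                })
                last_event_t = et
            burst_id += 1
            t = last_event_t
    df = pd.DataFrame(events)
    if df.empty:
        return as_event_table(pd.DataFrame(columns=["peak_frame", "peak_time_s"]))
    sizes = df.groupby("burst_id")["peak_time_s"].transform("size")
    df["burst_length"] = sizes
    df["intra_burst_interval_s"] = df.groupby("burst_id")["peak_time_s"].diff()
    return as_event_table(df)


# ---------------------------------------------------------------------------
# public operations

def simulate_calibration(config: SimConfig, rng=None):
    """Visual-stimulus calibration segment with polarity-reversing evoked
    deflections (1 Hz square-wave trains of 3 s; one evoked deflection per
    leading edge).  Returns ``(Recording, stimulus_onsets_s)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    fs = config.fs_lfp
    train_period = 6.0
    onsets = np.concatenate([
        k * train_period + np.arange(3.0) for k in range(config.calib_n_trains)
    ]) + 1.0
    dur = config.calib_n_trains * train_period + 2.0
    n = int(round(dur * fs))
    w = reversal_weights(config.n_channels, config.reversal_channel)
    data = np.stack([
        _shaped_noise(rng, n, fs, (0.5, 45.0), config.pink_exponent,
                      config.noise_sd)
        for _ in range(config.n_channels)
    ])
    # evoked kernel: fast alpha-function bump, ~80 ms long
    tau = 0.02
    tk = np.arange(0.0, 0.12, 1.0 / fs)
    kernel = (tk / tau) * np.exp(1.0 - tk / tau)
    for t in onsets:
        i = int(round(t * fs))
        seg = min(len(kernel), n - i)
        if seg <= 0:
            continue
        data[:, i:i + seg] += config.evoked_amp * w[:, None] * kernel[None, :seg]
    rec = Recording(data, fs=fs, reference="raw")
    return rec, onsets


def _stage_envelopes(labels: StateLabels, n: int, fs: float, cfg: SimConfig):
    """Per-sample broadband sqrt-gain and central-theta amplitude scale."""
    gain = {
        "awake": cfg.awake_power_gain, "presleep": cfg.awake_power_gain,
        "pre2": cfg.awake_power_gain, "post2": cfg.awake_power_gain,
        "earlysleep": cfg.early_late_gain, "latesleep": cfg.early_late_gain,
        "midsleep": 1.0,
    }
    g = np.full(n, cfg.awake_power_gain)
    th = np.zeros(n)
    for _, iv in labels.intervals.iterrows():
        a = int(round(iv["start_s"] * fs))
        b = min(int(round(iv["end_s"] * fs)), n)
        g[a:b] = gain.get(iv["label"], cfg.awake_power_gain)
        th[a:b] = THETA_STAGE_SCALE.get(iv["label"], 0.0)
    # soften transitions over ~0.5 s to avoid spectral edge artifacts
    k = max(1, int(0.5 * fs))
    box = np.ones(k) / k
    g = np.convolve(g, box, mode="same")
    th = np.convolve(th, box, mode="same")
    return np.sqrt(g), th


def simulate_lfp(
    labels: StateLabels, config: SimConfig, rng
) -> Recording:
    """State-modulated multichannel LFP for a labeled session."""
    fs = config.fs_lfp_raw or config.fs_lfp
    n = int(round(labels.session_end_s * fs))
    w = reversal_weights(config.n_channels, config.reversal_channel)
    sqrt_g, theta_env = _stage_envelopes(labels, n, fs, config)
    shared = _shaped_noise(rng, n, fs, (5.0, 40.0), 0.0, config.shared_sd)
    # theta amplitude chosen so the midsleep 5-10 Hz power on the central
    # channels is central_theta_boost times its no-theta value
    frac_pink = _band_power_fraction((0.5, 45.0), config.theta_band,
                                     config.pink_exponent)
    frac_shared = _band_power_fraction((5.0, 40.0), config.theta_band, 0.0)
    n_hours = max(1, int(np.ceil(labels.session_end_s / 3600.0)))
    bounds = (np.arange(n_hours) * 3600.0 * fs).astype(int)
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        pink = _shaped_noise(rng, n, fs, (0.5, 45.0), config.pink_exponent,
                             config.noise_sd)
        x = sqrt_g * (pink + w[c] * shared)
        ch_id = c + 1
        if ch_id in config.theta_channels:
            base_p = (frac_pink * config.noise_sd ** 2
                      + frac_shared * (w[c] * config.shared_sd) ** 2)
            theta_sd = np.sqrt((config.central_theta_boost - 1.0) * base_p)
            theta = _shaped_noise(rng, n, fs, config.theta_band, 0.0, theta_sd)
            x = x + theta_env * theta
        x += rng.standard_normal(n) * config.sensor_sd
        # per-hour DC offsets emulate separate acquisition chunks
        offs = rng.normal(0.0, config.hour_offset_sd, size=n_hours)
        x += np.repeat(offs, np.diff(np.append(bounds, n)))
        data[c] = x
    return Recording(data, fs=fs, segment_bounds=bounds, reference="raw")


def simulate_pose(
    truth_events: pd.DataFrame,
    config: SimConfig,
    labels: StateLabels | None = None,
    duration_s: float | None = None,
    rng=None,
) -> PoseTrack:
    """Pose table with PE pulses, sleep-gated antennal oscillation and
    occlusion-driven likelihood dips."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    fps = config.fps_video
    if duration_s is None:
        duration_s = (
            labels.session_end_s if labels is not None
            else (float(truth_events["peak_time_s"].max()) + 10.0
                  if len(truth_events) else 60.0)
        )
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    if len(truth_events) and truth_events["peak_time_s"].max() > duration_s:
        raise ValueError("truth events extend past the session span")
    jit = config.pose_jitter_px

    def jitter(size=n):
        return rng.normal(0.0, jit, size=size)

    cols = {}
    base = {
        "eye": (100.0, 100.0), "abdomen": (60.0, 110.0),
        "leg1_tip": (95.0, 130.0), "leg1_joint": (90.0, 118.0),
        "leg3_tip": (70.0, 132.0), "leg3_joint": (72.0, 120.0),
    }
    for part, (x0, y0) in base.items():
        cols[(part, "x")] = x0 + jitter()
        cols[(part, "y")] = y0 + jitter()
        cols[(part, "likelihood")] = np.clip(
            rng.normal(0.97, 0.015, size=n), 0.0, 1.0
        )
    # proboscis: rest position plus raised-cosine excursions at truth events
    rest = np.array([112.0, 108.0])
    direction = np.array([0.8, 0.6])  # unit vector away from the eye
    disp = np.zeros(n)
    half = config.pe_duration_s / 2.0
    for et in np.atleast_1d(
        truth_events["peak_time_s"].to_numpy() if len(truth_events) else []
    ):
        lo = int(np.ceil((et - half) * fps))
        hi = int(np.floor((et + half) * fps))
        idx = np.arange(max(lo, 0), min(hi + 1, n))
        phase = (t[idx] - (et - half)) / config.pe_duration_s
        disp[idx] = np.maximum(
            disp[idx],
            config.pe_amplitude_px * 0.5 * (1 - np.cos(2 * np.pi * phase)),
        )
    cols[("proboscis", "x")] = rest[0] + direction[0] * disp + jitter()
    cols[("proboscis", "y")] = rest[1] + direction[1] * disp + jitter()
    lk = np.clip(rng.normal(0.75, 0.03, size=n), 0.0, 1.0)
    extended = disp > 0.15 * config.pe_amplitude_px
    lk[extended] = np.clip(rng.normal(0.98, 0.01, size=extended.sum()), 0.0, 1.0)
    # antennae: tips oscillate during sleep only
    sleep_mask = np.zeros(n, dtype=bool)
    if labels is not None:
        for _, iv in labels.of_labels(
            ("sleep", "earlysleep", "midsleep", "latesleep")
        ).iterrows():
            sleep_mask[int(iv["start_s"] * fps):int(iv["end_s"] * fps)] = True
    for side, (bx, by), sign in (("L", (90.0, 80.0), -1.0), ("R", (90.0, 120.0), 1.0)):
        rest_angle = np.deg2rad(30.0)
        osc = np.deg2rad(config.antenna_osc_amp_deg) * np.sin(
            2 * np.pi * config.antenna_osc_freq_hz * t
        )
        ang = rest_angle + np.where(sleep_mask, osc, 0.0) + np.deg2rad(
            rng.normal(0.0, 0.5, size=n)
        )
        length = 15.0
        # head axis points along +x (anterior); antennae sweep in +/- y
        cols[(f"antenna_{side}_base", "x")] = bx + jitter()
        cols[(f"antenna_{side}_base", "y")] = by + jitter()
        cols[(f"antenna_{side}_tip", "x")] = bx + length * np.cos(ang) + jitter()
        cols[(f"antenna_{side}_tip", "y")] = (
            by + sign * length * np.sin(ang) + jitter()
        )
        for stem in (f"antenna_{side}_base", f"antenna_{side}_tip"):
            cols[(stem, "likelihood")] = np.clip(
                rng.normal(0.97, 0.015, size=n), 0.0, 1.0
            )
    # occlusion windows: likelihood collapses on proboscis and eye
    n_occ = rng.poisson(config.occlusion_rate_per_hour * duration_s / 3600.0)
    occ_starts = rng.uniform(0.0, max(duration_s - config.occlusion_dur_s, 0.0),
                             size=n_occ)
    for os_ in occ_starts:
        a = int(os_ * fps)
        b = min(int((os_ + config.occlusion_dur_s) * fps), n)
        lk[a:b] = rng.uniform(0.05, 0.35, size=b - a)
        cols[("eye", "likelihood")][a:b] = rng.uniform(0.05, 0.35, size=b - a)
    cols[("proboscis", "likelihood")] = lk
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["bodyparts", "coords"])
    return PoseTrack(table, fps=fps)


def simulate_frames(
    movement_activity: np.ndarray,
    config: SimConfig,
    shape: tuple[int, int] = (48, 64),
    rng=None,
) -> np.ndarray:
    """Small grayscale frame stack: a textured blob that displaces between
    frames whenever the activity series is nonzero, static otherwise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    activity = np.asarray(movement_activity, dtype=float)
    n = len(activity)
    h, w = shape
    blob = rng.integers(80, 220, size=(12, 12))
    frames = np.empty((n, h, w), dtype=np.uint8)
    pos = np.array([h // 2, w // 2])
    phase = 0
    for i in range(n):
        frame = rng.normal(20.0, 2.0, size=(h, w))
        if activity[i] > 0:
            phase ^= 1
            offset = np.array([3, 2]) if phase else np.array([-3, -2])
        else:
            offset = np.zeros(2, dtype=int)
        r, c = np.clip(pos + offset, (0, 0), (h - 12, w - 12))
        frame[r:r + 12, c:c + 12] = blob
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return frames


def simulate_session(config: SimConfig, with_lfp: bool = True) -> SimSession:
    """Generate a complete session: LFP, calibration, movement, pose, truth.

    Each stream draws from its own child generator of the session seed, so
    the behavioral ground truth and pose are bit-identical whether or not
    the (far more expensive) LFP stream is generated (``with_lfp=False``
    replaces it with an empty recording for behavior-only analyses).
    """
    r_beh, r_lfp, r_cal, r_pose = (
        np.random.default_rng(c) for c in
        np.random.SeedSequence(config.seed).spawn(4)
    )
    bouts = _draw_bouts(r_beh, config)
    labels = behavior.label_epochs(bouts)
    movement = _simulate_movement(r_beh, bouts, config)
    events = _simulate_pe_truth(r_beh, labels, config)
    if with_lfp:
        recording = simulate_lfp(labels, config, r_lfp)
        calibration, onsets = simulate_calibration(config, r_cal)
    else:
        fs = config.fs_lfp
        recording = Recording(np.zeros((config.n_channels, 2)), fs=fs)
        calibration, onsets = recording, np.zeros(0)
    pose = simulate_pose(events, config, labels=labels,
                         duration_s=labels.session_end_s, rng=r_pose)
    return SimSession(
        recording=recording, calibration=calibration, stimulus_onsets_s=onsets,
        movement_activity=movement, pose=pose, truth_bouts=bouts,
        truth_labels=labels, truth_events=events, config=config,
    )


def fly_seeds(config: SimConfig) -> list[int]:
    """Deterministic per-fly seeds derived from the cohort seed (< 2**31)."""
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in
            ss.spawn(config.n_flies)]


def simulate_cohort(config: SimConfig) -> list[SimSession]:
    """One session per fly with independent, reproducible seeds."""
    return [
        simulate_session(replace(config, seed=s)) for s in fly_seeds(config)
    ]


def config_record(config: SimConfig) -> dict:
    """JSON-serializable provenance record of a configuration."""
    d = asdict(config)
    d["theta_band"] = list(d["theta_band"])
    d["theta_channels"] = list(d["theta_channels"])
    return d
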