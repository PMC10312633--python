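"""LFP preprocessing, polarity-reversal referencing and spectral features.

The 16-electrode linear probe enters through the eye, so channel 16 sits in
the periphery (eye/optic lobe) and channel 1 in the central brain.  Visual
square-wave stimulation evokes deflections that are positive on peripheral
electrodes and negative on central ones; the channel where the sign flips
(the polarity reversal, normally electrode 11-13) anchors the probe
spatially and serves as the re-referencing channel: subtracting every
channel from it cancels common-mode, non-brain physiological components and
leaves 15 channels.

Spectral features are Welch power spectral densities in decibels on a fixed
grid: at 250 samples/s with a 1024-point FFT, frequency bins 20-164
(4.88-40.04 Hz) give exactly 145 bins per channel, hence the 15 x 145
channel-by-frequency feature grid used by all downstream statistics and
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .core import Recording, SpectraTable, StateLabels, STATE_OF_LABEL

#: Channel groups by original electrode index (Fig-style regional pooling).
CHANNEL_GROUPS = {
    "central": tuple(range(1, 6)),
    "middle": tuple(range(6, 11)),
    "peripheral": tuple(range(12, 17)),
}

DEFAULT_FS = 250.0
DEFAULT_NFFT = 1024


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def _fir_bandpass(fs: float, band, transition_hz: float) -> np.ndarray:
    """Linear-phase Hamming windowed-sinc band-pass kernel."""
    numtaps = _odd(int(np.ceil(3.3 * fs / transition_hz)))
    return signal.firwin(numtaps, band, window="hamming", pass_zero=False, fs=fs)


def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an odd-length linear-phase FIR with zero net delay.

    Exploits linear phase: 'same'-mode convolution with a symmetric kernel is
    exactly zero-phase, so no forward-backward pass is needed.
    """
    pad = len(taps) // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.oaconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., pad:-pad]


def preprocess(
    raw: Recording,
    fs_out: float = DEFAULT_FS,
    band: tuple[float, float] = (0.5, 40.0),
    notch_hz: float | None = 50.0,
    transition_hz: float = 0.5,
) -> Recording:
    """Resample and zero-phase filter a raw recording.

    Anti-aliased polyphase resampling to ``fs_out``, Hamming windowed-sinc
    band-pass (zero phase by linear-phase symmetry) and a zero-phase notch
    for line noise.
    """
    if raw.fs < 2 * band[1]:
        raise ValueError(
            f"sampling rate {raw.fs} Hz below Nyquist need for {band[1]} Hz band"
        )
    data = raw.data
    bounds = raw.segment_bounds
    if raw.fs != fs_out:
        frac = Fraction(fs_out / raw.fs).limit_denominator(1000)
        data = signal.resample_poly(
            data, frac.numerator, frac.denominator,
            axis=-1, window=("kaiser", 5.0),
        )
        bounds = np.round(raw.segment_bounds * fs_out / raw.fs).astype(int)
    taps = _fir_bandpass(fs_out, band, transition_hz)
    data = _zero_phase_fir(data, taps)
    if notch_hz is not None and notch_hz < fs_out / 2:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs_out)
        data = signal.filtfilt(b, a, data, axis=-1)
    return replace(raw, data=data, fs=fs_out, segment_bounds=bounds)


def stitch_hours(segments: list[Recording], bridge_s: float = 0.2) -> Recording:
    """Concatenate hourly chunks, linearly interpolating across boundaries.

    Around each junction the last/first ``bridge_s/2`` seconds are replaced
    by a straight line between the flanking samples, removing step
    discontinuities between acquisition files.
    """
    if not segments:
        raise ValueError("no segments")
    if len(segments) == 1:
        return replace(segments[0], segment_bounds=np.array([0]))
    fs = segments[0].fs
    n_ch = segments[0].n_channels
    for seg in segments[1:]:
        if seg.n_channels != n_ch or seg.fs != fs:
            raise ValueError("segments disagree in channel count or rate")
    data = np.concatenate([s.data for s in segments], axis=1)
    bounds = np.cumsum([0] + [s.n_samples for s in segments[:-1]])
    half = max(1, int(round(bridge_s * fs / 2)))
    for b in bounds[1:]:
        lo, hi = max(0, b - half), min(data.shape[1] - 1, b + half)
        ramp = np.linspace(0.0, 1.0, hi - lo)
        data[:, lo:hi] = (
            data[:, lo, None] * (1 - ramp) + data[:, hi, None] * ramp
        )
    return replace(segments[0], data=data, segment_bounds=np.asarray(bounds))


@dataclass
class CalibrationResult:
    """Outcome of polarity-reversal detection on a calibration segment."""

    reversal_channel: int
    deflections: np.ndarray  # signed mean evoked amplitude per channel
    quality_ok: bool
    n_sign_changes: int
    snr: float


def detect_polarity_reversal(
    calibration: Recording,
    stimulus_onsets_s: np.ndarray,
    response_window_s: tuple[float, float] = (0.01, 0.10),
    baseline_window_s: tuple[float, float] = (-0.05, 0.0),
    min_repetitions: int = 5,
    snr_thresh: float = 2.0,
) -> CalibrationResult:
    """Find the channel where stimulus-evoked deflections flip sign.

    Per channel the stimulus-locked average (response window minus pre-onset
    baseline) gives a signed deflection amplitude; the reversal channel is
    the channel nearest the zero-crossing of that profile along the probe.
    Quality requires a single sign change and sufficient amplitude SNR.
    """
    onsets = np.asarray(stimulus_onsets_s, dtype=float)
    if len(onsets) < min_repetitions:
        raise ValueError(f"need >= {min_repetitions} stimulus repetitions")
    fs = calibration.fs
    trials = []
    for t in onsets:
        i = int(round(t * fs))
        lo = i + int(baseline_window_s[0] * fs)
        hi = i + int(response_window_s[1] * fs)
        if lo < 0 or hi > calibration.n_samples:
            continue
        seg = calibration.data[:, lo:hi]
        n_base = int((0 - baseline_window_s[0]) * fs)
        baseline = seg[:, :n_base].mean(axis=1)
        n_resp0 = n_base + int(response_window_s[0] * fs)
        response = seg[:, n_resp0:].mean(axis=1)
        trials.append(response - baseline)
    trials = np.asarray(trials)
    if len(trials) < min_repetitions:
        raise ValueError("too few usable stimulus repetitions inside the segment")
    d = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(len(trials))
    snr = float(np.max(np.abs(d)) / max(np.max(sem), 1e-12))
    signs = np.sign(d)
    flips = np.flatnonzero(np.diff(signs[signs != 0]) != 0)
    # map flip positions back to channel indices among nonzero-sign channels
    nz = np.flatnonzero(signs != 0)
    n_changes = len(flips)
    if n_changes == 0 or snr < snr_thresh:
        raise ValueError("no reversal found: evoked deflections do not change sign")
    k = nz[flips[0]]
    k2 = nz[flips[0] + 1]
    # linear zero-crossing between the two flanking channels
    x = k + d[k] / (d[k] - d[k2]) * (k2 - k)
    reversal = int(calibration.channel_ids[int(round(x))])
    return CalibrationResult(
        reversal_channel=reversal,
        deflections=d,
        quality_ok=(n_changes == 1 and snr >= snr_thresh),
        n_sign_changes=n_changes,
        snr=snr,
    )


def rereference_reversal(rec: Recording, reversal_channel: int) -> Recording:
    """Re-reference to the polarity-reversal channel.

    Output channel i = reference - channel_i (reference minus channel); the
    reversal channel itself is dropped, leaving 15 channels.  Any component
    identical on all input channels cancels exactly.
    """
    ids = list(rec.channel_ids)
    if reversal_channel not in ids:
        raise ValueError(f"reversal channel {reversal_channel} not in recording")
    r = ids.index(reversal_channel)
    keep = [i for i in range(rec.n_channels) if i != r]
    data = rec.data[r][np.newaxis, :] - rec.data[keep]
    return replace(
        rec, data=data, channel_ids=rec.channel_ids[keep], reference="reversal"
    )


def rereference_bipolar(rec: Recording) -> Recording:
    """Differential referencing: output i = channel_{i+1} - channel_i."""
    if rec.n_channels < 2:
        raise ValueError("bipolar referencing needs >= 2 channels")
    data = rec.data[1:] - rec.data[:-1]
    return replace(
        rec, data=data, channel_ids=rec.channel_ids[:-1], reference="bipolar"
    )


@dataclass
class EpochSet:
    """Fixed-length epochs cut from a labeled recording."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    channel_ids: np.ndarray
    meta: pd.DataFrame  # fly_id, state, time_bin, start_s, len_s, bout_id

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def _time_bin(label: str, offset_start_s: float, offset_end_s: float) -> str:
    """Relative-time bin of an epoch from its midpoint offsets (minutes)."""
    ms = offset_start_s / 60.0  # minutes after bout start
    me = offset_end_s / 60.0    # minutes before bout end (positive)
    if label == "midsleep":
        return "mid"
    if label in ("presleep", "pre2"):
        m = -ms  # minutes before bout start
        if m <= 1:
            return "-1:0"
        if m <= 2:
            return "-2:-1"
        if m <= 3:
            return "-3:-2"
        return "-4:-3"
    if label == "earlysleep":
        return "0:+1" if ms <= 1 else "+1:+2"
    if label == "latesleep":
        return "x-1:x" if me <= 1 else "x-2:x-1"
    if label == "post2":
        m = -me  # minutes after bout end
        return "x:x+1" if m <= 1 else "x+1:x+2"
    return "awake"


def epoch_by_labels(
    rec: Recording,
    labels: StateLabels,
    epoch_len_s: float = 60.0,
    fly_id: int = 0,
) -> EpochSet:
    """Cut non-overlapping fixed-length epochs, each inside one interval.

    Partial trailing windows are discarded.  Each epoch carries the interval
    label (mapped to its behavioral state), a relative-time tag (minute
    offset from bout start/end for bout-derived intervals) and the bout id.
    """
    n_len = int(round(epoch_len_s * rec.fs))
    if n_len < 2:
        raise ValueError("epoch length too short")
    bouts = labels.bouts().set_index("bout_id") if len(labels.bouts()) else None
    chunks, meta = [], []
    for _, iv in labels.intervals.iterrows():
        start, end, lab, bid = iv["start_s"], iv["end_s"], iv["label"], int(iv["bout_id"])
        n_fit = int(np.floor((end - start) / epoch_len_s))
        if n_fit == 0:
            warnings.warn(
                f"interval [{start:.1f}, {end:.1f}) {lab!r} shorter than one epoch",
                stacklevel=2,
            )
            continue
        for k in range(n_fit):
            t0 = start + k * epoch_len_s
            i0 = int(round(t0 * rec.fs))
            if i0 + n_len > rec.n_samples:
                break
            mid = t0 + epoch_len_s / 2.0
            if bid >= 0 and bouts is not None and bid in bouts.index:
                off_start = mid - float(bouts.loc[bid, "start_s"])
                off_end = float(bouts.loc[bid, "end_s"]) - mid
            else:
                off_start, off_end = np.nan, np.nan
            chunks.append(rec.data[:, i0:i0 + n_len])
            meta.append({
                "fly_id": fly_id,
                "label": lab,
                "state": STATE_OF_LABEL.get(lab, "awake"),
                "time_bin": _time_bin(lab, off_start, off_end),
                "start_s": t0,
                "len_s": epoch_len_s,
                "bout_id": bid,
            })
    data = (
        np.stack(chunks) if chunks
        else np.empty((0, rec.n_channels, n_len))
    )
    return EpochSet(data=data, fs=rec.fs, channel_ids=rec.channel_ids,
                    meta=pd.DataFrame(meta))


def _welch_density(data: np.ndarray, fs: float, nperseg: int, nfft: int):
    """Vectorized Welch PSD (Hamming, 50% overlap, constant detrend).

    Matches ``scipy.signal.welch`` to rounding; computed in float32 for
    speed since spectra are consumed on a decibel scale.
    """
    from numpy.lib.stride_tricks import sliding_window_view
    from scipy.fft import rfft

    win = signal.get_window("hamming", nperseg).astype(np.float32)
    step = max(1, nperseg // 2)
    x = np.ascontiguousarray(data, dtype=np.float32)
    frames = sliding_window_view(x, nperseg, axis=-1)[..., ::step, :]
    frames = frames - frames.mean(axis=-1, keepdims=True)
    spec = rfft(frames * win, n=nfft, axis=-1)
    psd = (spec.real ** 2 + spec.imag ** 2).mean(axis=-2)
    psd *= 1.0 / (fs * float((win ** 2).sum()))
    psd[..., 1:-1] *= 2.0  # one-sided density
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return freqs, psd.astype(np.float64)


def power_spectrum(
    epochs: EpochSet,
    band: tuple[float, float] = (5.0, 40.0),
    nfft: int = DEFAULT_NFFT,
    prefilter: bool = True,
) -> SpectraTable:
    """Welch power spectra in dB on the fixed channel x frequency grid.

    Each epoch is zero-phase band-pass filtered to ``band``, then Welch
    averaged (Hamming windows, 50% overlap, ``nfft``-point FFT; segments are
    ``min(n_samples, nfft)`` long and zero-padded so the frequency grid does
    not depend on epoch length).  Power is 10*log10(uV^2/Hz).  At the 250
    samples/s, 1024-point defaults the grid spans bins 20-164: 145 bins from
    4.88 to 40.04 Hz.
    """
    fs = epochs.fs
    n = epochs.data.shape[-1]
    if n < 64:
        raise ValueError("epoch shorter than the minimum analysis window")
    data = epochs.data
    if prefilter and epochs.n_epochs:
        taps = _fir_bandpass(fs, band, transition_hz=2.0)
        if len(taps) * 3 > n:  # short epochs: shrink kernel to 1/3 length
            taps = signal.firwin(_odd(max(5, n // 3)), band, window="hamming",
                                 pass_zero=False, fs=fs)
        flat = np.ascontiguousarray(data.reshape(-1, n), dtype=np.float32)
        flat = _zero_phase_fir(flat, taps.astype(np.float32))
        data = flat.reshape(data.shape)
    nperseg = min(n, nfft)
    freqs, psd = _welch_density(data, fs, nperseg, nfft)
    df = fs / nfft
    lo = int(round(band[0] / df))
    hi = int(round(band[1] / df))
    sel = slice(lo, hi + 1)
    power_db = 10.0 * np.log10(np.maximum(psd[..., sel], 1e-30))
    return SpectraTable(
        power=power_db, freqs_hz=freqs[sel],
        channel_ids=epochs.channel_ids, epochs=epochs.meta,
    )


def group_channels(spectra: SpectraTable,
                   groups: dict | None = None) -> pd.DataFrame:
    """Mean spectra per channel group per state per fly (long format).

    Groups follow original electrode indices, so the dropped reversal
    channel is simply absent from its group.
    """
    groups = groups or CHANNEL_GROUPS
    ids = spectra.channel_ids
    rows = []
    for gname, members in groups.items():
        idx = np.flatnonzero(np.isin(ids, members))
        if not len(idx):
            continue
        gp = spectra.power[:, idx, :].mean(axis=1)  # (epochs, freqs)
        meta = spectra.epochs
        for (fly, state), sub in meta.groupby(["fly_id", "state"]):
            mean_spec = gp[sub.index.to_numpy()].mean(axis=0)
            for f, p in zip(spectra.freqs_hz, mean_spec):
                rows.append((fly, state, gname, f, p))
    return pd.DataFrame(
        rows, columns=["fly_id", "state", "group", "freq_hz", "power_db"]
    )


@dataclass
class ElectrodeGeometry:
    """Electrode positions reconstructed from dye fragments along the probe."""

    axis: np.ndarray          # unit vector, pointing outward (to periphery)
    innermost: np.ndarray     # innermost electrode position (um)
    positions: np.ndarray     # (n, 3) electrode positions at fixed spacing
    residual_rms: float


def localize_electrodes(
    dye_points: np.ndarray,
    innermost_point: np.ndarray,
    spacing_um: float = 25.0,
    n_electrodes: int = 16,
) -> ElectrodeGeometry:
    """Reconstruct electrode positions from dye-track point fragments.

    The first principal axis of the centered point cloud is the probe track;
    the innermost electrode is the projection of the innermost dye point
    onto that axis and the remaining electrodes sit at ``spacing_um``
    intervals along the axis toward the periphery (away from the cloud's
    inner end).
    """
    pts = np.asarray(dye_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need >= 2 dye points")
    center = pts.mean(axis=0)
    centered = pts - center
    if np.allclose(centered, 0):
        raise ValueError("dye points are coincident")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    inner = np.asarray(innermost_point, dtype=float)
    # orient the axis from the innermost point toward the cloud (periphery)
    if np.dot(center - inner, axis) < 0:
        axis = -axis
    proj = center + np.dot(inner - center, axis) * axis
    offsets = np.arange(n_electrodes)[:, None] * spacing_um * axis[None, :]
    positions = proj[None, :] + offsets
    t = centered @ axis
    residual = centered - t[:, None] * axis[None, :]
    return ElectrodeGeometry(
        axis=axis, innermost=proj, positions=positions,
        residual_rms=float(np.sqrt((residual ** 2).sum(axis=1).mean())),
    )
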