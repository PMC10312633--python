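"""PE detection, burst grouping, antennal angles and periodicity."""

import numpy as np
import pandas as pd
import pytest

from flysleep import microbehavior as mb
from flysleep import synthgen
from flysleep.core import PoseTrack, StateLabels, as_event_table

from conftest import small_config

FPS = 30.0


def pose_from(columns, fps=FPS):
    df = pd.DataFrame(columns)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodyparts", "coords"])
    return PoseTrack(df, fps=fps)


def minimal_pose(n=600, prob_xy=None, prob_lk=None, eye=(0.0, 0.0)):
    cols = {}
    for part in mb.PE_FEATURE_PARTS:
        cols[(part, "x")] = np.full(n, 10.0)
        cols[(part, "y")] = np.full(n, 20.0)
        cols[(part, "likelihood")] = np.full(n, 0.95)
    cols[("eye", "x")] = np.full(n, eye[0])
    cols[("eye", "y")] = np.full(n, eye[1])
    if prob_xy is not None:
        cols[("proboscis", "x")] = prob_xy[0]
        cols[("proboscis", "y")] = prob_xy[1]
    if prob_lk is not None:
        cols[("proboscis", "likelihood")] = prob_lk
    return pose_from(cols)


# ---------------------------------------------------------------------------
# features

def test_dist_eyeprob_is_distance_times_likelihood():
    n = 600
    pose = minimal_pose(
        n, prob_xy=(np.full(n, 3.0), np.full(n, 4.0)),
        prob_lk=np.full(n, 0.5),
    )
    feats = mb.compute_pe_features(pose)
    assert np.allclose(feats.dist_eyeprob, 2.5)  # 5 px * 0.5


def test_coincident_proboscis_and_eye_gives_zero():
    n = 600
    pose = minimal_pose(n, prob_xy=(np.zeros(n), np.zeros(n)),
                        prob_lk=np.full(n, 0.9))
    feats = mb.compute_pe_features(pose)
    assert np.allclose(feats.dist_eyeprob, 0.0)


def test_constant_series_filter_identity():
    feats = mb.compute_pe_features(minimal_pose(600))
    col = feats.frame["proboscis_x_filt"].to_numpy()
    assert np.allclose(col, 10.0, atol=1e-6)
    assert np.allclose(feats.frame["proboscis_x_ma"], 10.0, atol=1e-6)


def test_nan_coordinates_masked_with_zero_likelihood():
    n = 600
    x = np.full(n, 3.0); x[100:105] = np.nan
    pose = minimal_pose(n, prob_xy=(x, np.full(n, 4.0)),
                        prob_lk=np.full(n, 0.8))
    feats = mb.compute_pe_features(pose)
    assert feats.frame["nan_masked"][100:105].all()
    assert np.allclose(feats.frame["proboscis_likelihood"][100:105], 0.0)
    assert np.isfinite(feats.matrix()).all()


def test_missing_part_rejected():
    cols = {("eye", c): np.zeros(60) for c in ("x", "y", "likelihood")}
    with pytest.raises(ValueError, match="lacks required parts"):
        mb.compute_pe_features(pose_from(cols))


# ---------------------------------------------------------------------------
# classifier

def separable_features(seed=0, n=900):
    rng = np.random.default_rng(seed)
    lk = np.clip(rng.normal(0.7, 0.02, n), 0, 1)
    x = np.full(n, 10.0) + rng.normal(0, 0.1, n)
    pe_frames = np.zeros(n, dtype=bool)
    for start in range(100, n - 20, 150):
        pe_frames[start:start + 10] = True
    x[pe_frames] += 12.0
    lk[pe_frames] = 0.98
    pose = minimal_pose(n, prob_xy=(x, np.full(n, 0.0)), prob_lk=lk)
    return mb.compute_pe_features(pose), np.flatnonzero(pe_frames)


def test_separable_frames_classified_perfectly():
    feats, truth = separable_features()
    clf = mb.train_pe_classifier(feats, truth, seed=0)
    assert clf.metrics["accuracy"] == 1.0


def test_shuffled_labels_score_at_class_prior():
    feats, truth = separable_features()
    n = len(feats.frame)
    prior = max(len(truth), n - len(truth)) / n
    rng = np.random.default_rng(1)
    accs = []
    for _ in range(10):
        fake = rng.choice(n, size=len(truth), replace=False)
        clf = mb.train_pe_classifier(feats, fake, seed=0)
        accs.append(clf.metrics["accuracy"])
    assert np.mean(accs) == pytest.approx(prior, abs=0.1)


def test_single_class_truth_rejected():
    feats, _ = separable_features()
    with pytest.raises(ValueError, match="both classes"):
        mb.train_pe_classifier(feats, [], seed=0)


def test_classifier_accuracy_on_generated_pose():
    """Frame-level SVM accuracy stays above the 0.8 working level on
    generator-default pose tracks."""
    s = synthgen.simulate_session(small_config(seed=2, session_hours=0.5),
                                  with_lfp=False)
    feats = mb.compute_pe_features(s.pose)
    truth = set()
    for t in s.truth_events["peak_time_s"]:
        c = int(round(t * FPS))
        truth.update(range(max(c - 7, 0), min(c + 8, s.pose.n_frames)))
    clf = mb.train_pe_classifier(feats, truth, seed=0)
    assert clf.metrics["accuracy"] >= 0.8


# ---------------------------------------------------------------------------
# event detection

def pulse_features(peaks, n=1800, amp=12.0, width=15):
    x = np.full(n, 10.0)
    lk = np.full(n, 0.7)
    for p in peaks:
        w = np.arange(max(0, p - width), min(n, p + width + 1))
        x[w] += amp * 0.5 * (1 - np.cos(2 * np.pi * (w - p + width) / (2 * width)))
        lk[w] = 0.97
    pose = minimal_pose(n, prob_xy=(x, np.zeros(n)), prob_lk=lk)
    return mb.compute_pe_features(pose)


def test_quiet_track_gives_empty_table():
    feats = mb.compute_pe_features(minimal_pose(600))
    events = mb.detect_pe_events(feats, likelihood_thresh=0.99)
    assert len(events) == 0


def test_single_pulse_gives_one_event_at_apex():
    feats = pulse_features([900])
    events = mb.detect_pe_events(feats, likelihood_thresh=0.9)
    assert len(events) == 1
    assert abs(int(events["peak_frame"].iloc[0]) - 900) <= 1


def test_time_reversed_track_gives_time_reversed_events():
    peaks = [300, 700, 1100]
    feats = pulse_features(peaks)
    fwd = mb.detect_pe_events(feats, likelihood_thresh=0.9)
    rev_frame = feats.frame.iloc[::-1].reset_index(drop=True)
    rev = mb.detect_pe_events(mb.PEFeatureTable(rev_frame, feats.fps),
                              likelihood_thresh=0.9)
    n = len(feats.frame)
    assert sorted(n - 1 - rev["peak_frame"]) == sorted(fwd["peak_frame"])


def test_detection_against_generator_truth():
    for seed in range(5):
        s = synthgen.simulate_session(small_config(seed=seed, session_hours=0.5),
                                      with_lfp=False)
        feats = mb.compute_pe_features(s.pose)
        events = mb.detect_pe_events(feats, likelihood_thresh=0.9,
                                     labels=s.truth_labels)
        m = mb.match_events(events, s.truth_events, tol_s=0.25)
        if m["n_truth"] == 0:
            continue
        assert m["precision"] >= 0.9
        assert m["recall"] >= 0.9


def test_events_carry_state_labels(session2h):
    feats = mb.compute_pe_features(session2h.pose)
    events = mb.detect_pe_events(feats, likelihood_thresh=0.9,
                                 labels=session2h.truth_labels)
    assert set(events["state"]) <= {"awake", "presleep", "pre2", "post2",
                                    "earlysleep", "midsleep", "latesleep"}


# ---------------------------------------------------------------------------
# peak-picking detector

def raised_cosine(n=600, peak=300, amp=8.0, width=15):
    d = np.zeros(n)
    w = np.arange(peak - width, peak + width + 1)
    d[w] = amp * 0.5 * (1 - np.cos(2 * np.pi * (w - peak + width) / (2 * width)))
    return d


def test_clean_pulse_detected():
    ev = mb.detect_pe_peaks(raised_cosine(), fps=FPS, height=2.0,
                            max_dist_px=50.0)
    assert len(ev) == 1 and int(ev["peak_frame"].iloc[0]) == 300


def test_single_frame_spike_excluded():
    d = np.zeros(600); d[300] = 8.0
    ev = mb.detect_pe_peaks(d, fps=FPS, height=2.0, max_dist_px=50.0)
    assert len(ev) == 0


def test_over_amplitude_peak_excluded():
    ev = mb.detect_pe_peaks(raised_cosine(amp=80.0), fps=FPS, height=2.0,
                            max_dist_px=50.0)
    assert len(ev) == 0


def test_implausible_rise_time_excluded():
    d = np.zeros(600)
    d[300] = 8.0; d[301] = 7.5  # two frames, instantaneous rise
    ev = mb.detect_pe_peaks(d, fps=FPS, height=2.0, max_dist_px=50.0,
                            min_rise_s=0.15)
    assert len(ev) == 0


def test_threshold_detector_durations():
    d = np.zeros(600); d[100:130] = 5.0; d[400:406] = 5.0
    ev = mb.detect_pe_threshold(d, fps=FPS, thresh=2.0)
    assert len(ev) == 2
    assert ev["duration_s"].iloc[0] == pytest.approx(1.0)
    assert ev["duration_s"].iloc[1] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# burst grouping

def events_at(times):
    return as_event_table(pd.DataFrame({
        "peak_time_s": times,
        "peak_frame": (np.asarray(times) * FPS).round().astype(int),
    }))


def test_burst_rule_arithmetic():
    ev = mb.group_bursts(events_at([0.0, 5.0, 30.0]), gap_s=10.0)
    assert list(ev["burst_id"]) == [0, 0, 1]
    assert list(ev["burst_length"]) == [2, 2, 1]
    assert ev["intra_burst_interval_s"].iloc[1] == pytest.approx(5.0)


def test_all_gaps_large_every_event_single():
    ev = mb.group_bursts(events_at([0.0, 20.0, 45.0, 80.0]), gap_s=10.0)
    assert (ev["burst_length"] == 1).all()


def test_group_bursts_idempotent_order_independent_and_conserving():
    times = [0.0, 1.5, 3.0, 40.0, 41.4, 90.0]
    base = mb.group_bursts(events_at(times))
    again = mb.group_bursts(base)
    pd.testing.assert_frame_equal(base, again)
    shuffled = events_at(list(np.random.default_rng(0).permutation(times)))
    pd.testing.assert_frame_equal(mb.group_bursts(shuffled), base)
    assert len(base) == len(times)


def test_intra_burst_interval_recovered_from_generator():
    ieis = []
    for seed in range(8):
        s = synthgen.simulate_session(small_config(seed=seed, session_hours=1.0),
                                      with_lfp=False)
        ev = mb.group_bursts(s.truth_events)
        ieis.extend(ev["intra_burst_interval_s"].dropna().tolist())
    assert np.mean(ieis) == pytest.approx(1.5, abs=0.1)


# ---------------------------------------------------------------------------
# antennal angles & periodicity

def antenna_pose(angles_deg, rotation_deg=0.0, fps=FPS):
    """Pose with both antennae at the given anterior-sweep angle series.

    Bases at (0, -10) and (0, 10), head axis +x; the L tip sweeps toward +y
    for positive angles and the R tip toward -y (mirror symmetry).
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = len(ang)
    rot = np.deg2rad(rotation_deg)
    c, s = np.cos(rot), np.sin(rot)

    def rotate(x, y):
        return c * x - s * y, s * x + c * y

    cols = {}
    for side, by, sweep in (("L", -10.0, 1.0), ("R", 10.0, -1.0)):
        tipx = 15.0 * np.cos(ang)
        tipy = by + sweep * 15.0 * np.sin(ang)
        bx_r, by_r = rotate(np.zeros(n), np.full(n, by))
        tx_r, ty_r = rotate(tipx, tipy)
        cols[(f"antenna_{side}_base", "x")] = bx_r
        cols[(f"antenna_{side}_base", "y")] = by_r
        cols[(f"antenna_{side}_tip", "x")] = tx_r
        cols[(f"antenna_{side}_tip", "y")] = ty_r
        for stem in ("base", "tip"):
            cols[(f"antenna_{side}_{stem}", "likelihood")] = np.full(n, 0.95)
    return pose_from(cols)


def test_tip_along_head_axis_reads_zero():
    pose = antenna_pose(np.zeros(60))
    ang = mb.antenna_angles(pose)
    assert np.allclose(ang["antenna_L"], 0.0, atol=1e-9)
    assert np.allclose(ang["antenna_R"], 0.0, atol=1e-9)


def test_rigid_head_rotation_leaves_angles_unchanged():
    base = mb.antenna_angles(antenna_pose(np.full(60, 20.0)))
    rotated = mb.antenna_angles(antenna_pose(np.full(60, 20.0),
                                             rotation_deg=30.0))
    assert np.allclose(base.to_numpy(), rotated.to_numpy(), atol=1e-6)


def test_oscillation_amplitude_recovered_within_one_degree():
    t = np.arange(1800) / FPS
    pose = antenna_pose(10.0 * np.sin(2 * np.pi * 0.5 * t))
    ang = mb.antenna_angles(pose)["antenna_L"].to_numpy()
    amp = (ang.max() - ang.min()) / 2.0
    assert amp == pytest.approx(10.0, abs=1.0)


def test_pure_sine_flagged_periodic_at_its_frequency():
    t = np.arange(3600) / FPS
    x = 5.0 * np.sin(2 * np.pi * 1.0 * t)
    seg = mb.antenna_periodicity(x, fps=FPS)
    assert seg["periodic"].all()
    assert np.allclose(seg["dominant_freq_hz"], 1.0, atol=0.05)


def test_white_noise_rarely_flagged():
    rng = np.random.default_rng(0)
    flagged = total = 0
    for _ in range(10):
        x = rng.normal(size=3600)
        seg = mb.antenna_periodicity(x, fps=FPS)
        flagged += int(seg["periodic"].sum())
        total += len(seg)
    assert flagged / total <= 0.1


def test_window_longer_than_series_rejected():
    with pytest.raises(ValueError, match="window longer"):
        mb.antenna_periodicity(np.zeros(100), fps=FPS, window_s=30.0)


def test_proboscis_periodicity_rule():
    ev = mb.proboscis_periodicity(events_at([0.0, 3.0, 20.0]))
    assert list(ev["periodic"]) == [False, True, False]
    assert int(ev["periodic"].sum()) == 1


def test_antennal_oscillation_periodic_during_sleep_only(session2h):
    s = session2h
    ang = mb.antenna_angles(s.pose)["antenna_L"].to_numpy()
    seg = mb.antenna_periodicity(ang, fps=s.pose.fps)
    bouts = s.truth_bouts.bouts()

    def inside_sleep(row):
        return any((row["start_s"] >= b["start_s"] - 1)
                   and (row["end_s"] <= b["end_s"] + 1)
                   for _, b in bouts.iterrows())

    sleep_mask = seg.apply(inside_sleep, axis=1)
    awake_mask = ~seg.apply(
        lambda r: any((r["end_s"] > b["start_s"]) and (r["start_s"] < b["end_s"])
                      for _, b in bouts.iterrows()), axis=1)
    assert seg[sleep_mask]["periodic"].mean() > 0.9
    assert seg[awake_mask]["periodic"].mean() < 0.1


# ---------------------------------------------------------------------------
# depth summary

def depth_labels():
    rows = [
        (0, 600, "awake", -1), (600, 720, "presleep", 0),
        (720, 840, "earlysleep", 0), (840, 1440, "midsleep", 0),
        (1440, 1560, "latesleep", 0), (1560, 2400, "awake", -1),
    ]
    return StateLabels(pd.DataFrame(rows, columns=["start_s", "end_s", "label",
                                                   "bout_id"]))


def test_events_in_first_minute_have_no_after5_count():
    out = mb.pe_depth_summary(events_at([730.0, 740.0]), depth_labels())
    assert out["sleep_before_5min"] == 2
    assert out["sleep_after_5min"] == 0


def test_uniform_events_split_evenly_at_the_5th_minute():
    # bout spans 720-1560 (14 min); uniform events every 30 s
    times = np.arange(725.0, 1555.0, 30.0)
    out = mb.pe_depth_summary(events_at(times), depth_labels())
    assert abs(out["sleep_before_5min"] - 10) <= 1
    assert out["sleep_before_5min"] + out["sleep_after_5min"] == len(times)


def test_midsleep_bin_maximal_for_generator_sessions(session2h):
    out = mb.pe_depth_summary(session2h.truth_events, session2h.truth_labels)
    norm = out["normalized_counts_per_min"]
    assert norm["mid"] == max(norm.values())
    assert out["sleep_after_5min"] > out["sleep_before_5min"]
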