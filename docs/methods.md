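# Methods

This note documents the models and procedures implemented in `flysleep`,
the assumptions they make, the tunable parameters that matter, and the
numerical choices behind them.

## Overview

`flysleep` re-implements, as a tested pipeline, an analysis of long-term
multichannel local field potential (LFP) recordings from the brain of
tethered, behaving *Drosophila*, aimed at resolving distinct sleep stages.
The stages of the pipeline are:

1. **Behavior** — quantify movement from video (or precomputed activity
   values), detect sleep bouts by the 5-minute immobility criterion, and
   partition each bout into temporal stages.
2. **LFP** — resample/filter the raw voltage traces, find the
   polarity-reversal electrode from a visual-stimulation calibration
   segment, re-reference to it, epoch by behavioral label, and compute
   channel × frequency power spectra.
3. **Cluster statistics** — group-level inference on per-fly spectral
   difference maps with a one-sample cluster-based permutation test.
4. **Staging** — a linear-SVM "probability probe" (awake vs midsleep) read
   out on epochs it never saw, and a multiclass random forest with
   permutation feature importance.
5. **Micro-behavior** — proboscis-extension (PE) event detection from pose
   tables, burst grouping, antennal angle periodicity, and sleep-depth
   summaries.
6. **Synthetic data** — a generator that emulates all four input streams
   with known ground truth, so that every stage is testable end to end.

## Behavioral labeling

A frame is *moved* when the absolute difference to the previous frame,
binarized at a per-fly pixel threshold, dilated (3×3, two iterations) and
grouped into connected components, contains a component of at least
`area_thresh` pixels. Movement runs shorter than `min_move_s` (default 1 s)
are treated as noise and removed; still runs shorter than `min_still_s`
(default 1 s) are then filled. A maximal still run **strictly longer than
5 minutes** is a sleep bout (a run of exactly 300.0 s stays awake — the
criterion is read literally as "more than 5 min"). Durations are computed
from frame timestamps, not frame counts, so dropped frames do not bias bout
lengths.

Each bout is partitioned, in minutes relative to bout start (0) and end
(x): `presleep` = [−2, 0), `earlysleep` = [0, +2), `latesleep` = the last
2 min, `midsleep` = the remainder. Two evaluation-only flanking bins,
`pre2` = [−4, −2) and `post2` = [x, x+2), are tagged but **never used for
classifier training**. When two bouts are closer than 8 min, flanking bins
are clipped at the midpoint of the gap; within each half the bin nearest
the bout wins (presleep before pre2). This keeps all bins disjoint.

The per-fly binarization threshold is not derivable from first principles;
`behavior.auto_pixel_threshold` offers a percentile-of-deltaframe heuristic
as a starting point, and the threshold is always an explicit argument.

## LFP processing

Raw data are resampled to 250 samples/s (polyphase, Kaiser anti-aliasing)
and band-passed 0.5–40 Hz with a Hamming windowed-sinc FIR filter. Because
the kernel is symmetric (linear phase), applying it by 'same'-mode
convolution is exactly zero-phase; no forward–backward pass is needed. Line
noise is removed with a zero-phase IIR notch at 50 Hz. Hourly acquisition
chunks are concatenated with a short linear interpolation bridge (default
0.2 s) across each file boundary so no step discontinuities remain.

**Polarity reversal.** The probe enters through the eye, so evoked
responses to a 1-Hz square-wave visual stimulus are positive-going on
peripheral electrodes and negative-going centrally. Per channel we average
the stimulus-locked response (10–100 ms post-onset minus a 50 ms pre-onset
baseline) over ≥5 repetitions; the reversal channel is the channel nearest
the zero-crossing of the signed profile. Quality requires exactly one sign
change and an amplitude SNR above threshold; a profile with no sign change
raises "no reversal found". Re-referencing subtracts every channel **from**
the reversal channel (output = reference − channel, the stated convention;
the opposite convention flips all difference maps) and drops it, leaving 15
channels. A bipolar variant (neighbor differences) is provided for the
full-brain probe recordings.

**Spectra.** Epochs (60 s for sleep analyses, 1 s for PE analyses) are cut
strictly inside single labeled intervals; partial windows are discarded.
Each epoch is band-passed 5–40 Hz and Welch-averaged: Hamming windows, 50%
overlap, 1024-point FFT at 250 samples/s. Segments are `min(n, 1024)`
samples, zero-padded to the 1024-point grid, so 1-s epochs produce the same
frequency grid as 60-s epochs. The grid is restricted to bins 20–164
(4.88–40.04 Hz, 0.2441 Hz spacing): exactly **145 bins × 15 channels =
2175 features**. Power is reported as 10·log10(µV²/Hz). These estimator
parameters were chosen because they are the grid that yields the printed
145-bin feature dimension. Spectra are computed in float32 (the dB scale
consumes them; agreement with the float64 reference implementation is at
the 1e-6 relative level).

Channel groups for regional summaries follow original electrode indices:
central 1–5, middle 6–10, peripheral 12–16 (the dropped reversal channel is
simply absent from its group).

**Electrode geometry.** Dye fragments along the probe track are reduced by
PCA; the first principal axis is the probe path, the innermost electrode is
the projection of the innermost dye point, and the remaining 15 electrodes
sit at exact 25 µm intervals along the axis toward the periphery.

## Cluster-based permutation test

For a condition contrast, each fly contributes one mean-spectrum difference
map (condition A − condition B, dB); flies with fewer than `min_trials`
epochs in either condition are excluded (10 for sleep/wake, 50 for the
1-s PE contrasts). Cell-wise one-sample t statistics across flies are
thresholded at the two-tailed t quantile (cluster-forming α = 0.05,
df = n−1); supra-threshold cells form 4-connected clusters on the
(channel, frequency) grid, positive and negative clusters separately.
Channel adjacency follows original electrode indices, so the dropped
reversal channel does **not** bridge its neighbors (channels 10 and 12 are
not adjacent) — a conservative choice that affects cluster shapes and is
therefore stated prominently. Cluster mass is the sum of t within the
cluster; the null distribution of the maximum |mass| is built from **all
2ⁿ sign-flip permutations** for n ≤ 20 flies (seed-independent by
construction) or a seeded random subset of 2¹⁶ beyond that. Cluster p =
proportion of permutations whose max |mass| reaches the observed |mass|.

The permutation engine is vectorized: sign flips leave per-cell sums of
squares invariant, so a whole batch of permutation t-maps is one matrix
product; the batch is thresholded and labeled in a single
connected-component pass with no linkage across the permutation axis.
Null t-maps are computed in float32 (p-value counting uses a relative
slack of 1e−6). The test agrees with MNE's
`permutation_cluster_1samp_test` — identical clusters, p within one
permutation unit — on random small instances; MNE's exhaustive test
enumerates the 2^(n−1) sign-symmetric orbit with a slightly different
denominator convention, which is within that unit.

Effect sizes are one-sample Cohen's d per cell (mean of per-fly differences
over their SD); zero-SD cells with nonzero mean are capped and flagged.
Within-cluster post-hocs average the in-cluster difference per fly and
report the direction with a one-sample t summary.

## Classifier staging

Features are the flattened channel-major (channel, frequency) power grid,
one row per 60-s epoch. Rows from the `pre2`/`post2` bins are retained but
flagged never-train; every training split is audited against their row ids.

**Probability probe.** Awake and midsleep rows are balanced by random
undersampling (the multiclass analysis reserves SMOTE), split 80/20
stratified, standardized (scaler fit on training rows only), and fit with a
linear-kernel SVM with sigmoid-calibrated class probabilities. The
calibrated awake-probability is then read out on *all* epochs — including
presleep, early/late sleep and the flanking bins the model never saw — and
averaged per relative-time bin, over 5 independent splits. The pipeline's
core qualitative readout is the ordering: midsleep lowest, early/late sleep
intermediate, awake and post-waking bins high.

**Multiclass stager.** All five classes are SMOTE-balanced to the majority
count (synthetic points uniform on segments between a minority point and
one of its 5 nearest same-class neighbors), then split 80/20, standardized
and fit with a random forest. SMOTE is applied before the split — the
literal published order — which leaks interpolated copies of training
points into the test partition; held-out metrics are therefore optimistic
and are treated as internal diagnostics, not generalization estimates. A
fly-grouped split is the obvious remedy on real data and epoch-level
splitting is kept here to match the published procedure. Hyperparameters
come from a seeded two-stage search (randomized screen, then one-step local
grid) within a fit budget over trees {200–800}, depth {None, 10–40},
min-leaf {1–4}.

**Permutation importance.** Per split, each held-out feature column is
shuffled 5 times and the mean model-score drop recorded; maps are averaged
over the 5 splits and reshaped to channels × frequencies. The default score
is the **mean predicted probability of the true class** rather than
accuracy: at the held-out sizes used in this package's tests (~100–400
rows), accuracy is quantized at 1/n_rows and cannot resolve the small
per-cell drops that redundant, correlated spectral features produce, even
when the forest's impurity importances localize perfectly. The smooth score
resolves them; accuracy scoring remains available
(`scoring="accuracy"`) and matches `sklearn.inspection.permutation_importance`.
Importance is computed batched over (feature, repeat) copies of the
held-out rows, which is an order of magnitude faster than column-at-a-time
scoring and identical in semantics.

## Micro-behavior

Pose tables carry (x, y, likelihood) per body part per frame. PE features
are the raw and 0.1-Hz Butterworth low-passed coordinates (zero-phase), a
centered 5-sample moving average of the filtered series, and
`dist_eyeprob` — the proboscis–eye Euclidean distance multiplied by the
proboscis likelihood. NaN coordinates are interpolated, their likelihood
forced to 0, and the frames flagged.

Two detectors:

* **Classifier route** (electrophysiology rig): an RBF-kernel SVM labels
  frames as PE/not-PE (70/30 split, scaler on training rows); positive
  frames merge into candidate segments (gaps ≤ 0.2 s), segments are
  augmented by proboscis-likelihood threshold crossings (default 0.9 — the
  generator emulates the fact that a retracted proboscis tracks with lower
  confidence than an extended one), multi-extension segments are split at
  internal minima below 50% of the neighboring peaks, and the event peak is
  the maximum displacement frame. A review-export CSV with frame numbers
  replaces the manual verification step of the original workflow.
* **Peak-picking route** (behavior rig): local maxima of the distance to
  the per-recording median (resting) position, with three exclusions in
  order — amplitude above a plausibility cap, single-frame peaks, and
  implausibly fast baseline-to-peak rises.

Events within 10 s of each other share a burst (single-linkage); burst
length and intra-burst intervals are attached. An event is *periodic* iff
its predecessor occurred < 6 s earlier (PE dynamics are not sinusoidal, so
no FFT is used for the proboscis). Antennal angles are head-axis-corrected:
the head axis is the anterior normal of the line joining the antenna bases,
so rigid head rotations cancel exactly; angles are reported in degrees,
positive = anterior sweep. Antennal periodicity uses sliding 30-s windows
(50% overlap): a window is periodic when its 0.1–5 Hz spectral peak exceeds
6× the median spectral magnitude (all overridable; these windows/criteria
are package conventions, not published values).

Sleep-depth summaries count PE events before/after the 5th minute of each
sleep bout (with awake bouts as control), normalize event counts per
relative-time bin by time spent in the bin, and report the time-into-
midsleep distribution with its 95th percentile.

## Synthetic data generator

The generator is the test substrate, not a model of fly biology. Per
session it draws an alternating awake/sleep-bout sequence (truncated
normals; defaults: bouts 12 ± 4 min, ≥ 6; inter-bout 14 ± 5 min, ≥ 5;
8-h sessions), derives the full stage labels with the same labeling code
used for real data, and synthesizes:

* **LFP**: per-channel 1/f (exponent 1) background noise band-limited
  0.5–45 Hz (`noise_sd` 10 µV) plus a shared 5–40 Hz component (8 µV)
  whose channel weights follow a clipped linear ramp crossing zero at the
  reversal channel — the simplest geometry reproducing the
  positive/peripheral, negative/central deflection pattern, with full slope
  at the crossing so detection is sharp. The whole brain signal is scaled
  by a per-sample stage envelope: awake/presleep power ×2.0, early/late
  sleep ×1.4, midsleep ×1.0 (transitions smoothed over 0.5 s). Channels
  1–3 additionally carry a 5–10 Hz component during sleep whose power
  doubles the midsleep 5–10 Hz level (`central_theta_boost` = 2) with a
  distinct amplitude per stage (presleep 0.45, early 0.75, mid 1.0, late
  1.35) — this is the known "discriminative box" that the importance
  analyses must find. Per-hour DC offsets emulate separate acquisition
  files. Band-power ratios estimated back from generated data recover the
  configured gains within 10%.
* **Calibration**: 1-Hz square-wave trains (3 s each); each leading edge
  evokes an alpha-function deflection with the same signed ramp weights.
* **Movement**: bursty lognormal activity values outside bouts (brief
  sub-second still gaps exercise pruning; the 2 s flanking each bout edge
  are forced active so boundary recovery is well-defined), exactly zero
  inside bouts.
* **PE events**: burst onsets follow an inhomogeneous Poisson process
  (thinning) — 0.3 events/min during wake, 3/min in midsleep but reduced
  to 25% during the first 2.5 min of each midsleep interval, so events
  concentrate deep in sleep. A burst is single with probability 0.33, else
  geometric with mean 4 events at 1.5 ± 0.03 s spacing; bursts are ≥ 11 s
  apart.
* **Pose**: raised-cosine proboscis excursions (0.5 s, 12 px) at event
  times; proboscis likelihood ~0.75 at rest, ~0.98 while extended, < 0.4
  in occlusion windows; antennal tips oscillate (default 1 Hz, ±8°) during
  sleep only; other parts are quasi-static with 0.4 px jitter.
* **Frames**: 48×64 grayscale with a textured blob that displaces whenever
  the activity series is nonzero.

Every stream draws from its own child generator of the session seed:
identical config + seed reproduces a session bit-for-bit, and behavioral
streams are unchanged when LFP synthesis is skipped.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, fly-to-fly spectral variability, movement artifacts in
the LFP, grooming/leg kinematics, heartbeat (the reference scheme removes
common-mode components regardless of their origin), and pose-estimation
identity swaps. Passing tests therefore demonstrate that the pipeline's
operations are correct and its statistics calibrated on data with the
assumed structure — not that the biological conclusions transfer to any
particular real recording.

## Problem sizes used in tests and the acceptance script

The published analyses used 8-h recordings from 16 flies and the full
15 × 145 grid. The automated checks run the same code at reduced sizes
chosen for a single CPU: 2-h sessions with inter-bout mean 10 min (so a
session still contains ~5 bouts), the 256-point (37-bin) grid for the
probe ordering runs, the 128-point (18-bin) grid for the importance and
effect-recovery runs, 12×16 to 15×20 cells for permutation-test
calibration (200 null simulations, 16 flies, exhaustive 2¹⁶ sign flips),
and a reduced forest search space (100–300 trees). Structural constants
(15 channels after re-referencing; 145 frequency bins) are always checked
at the full default settings. `scripts/acceptance.py` recomputes all
headline quantities from scratch at these sizes from a single `--seed`.

## Numerical conventions and degenerate inputs

* All interval times are half-open `[start, end)` seconds; channel indices
  are 1-based (1 = most central).
* Zero-variance cells in the cluster test get t = 0 with a warning; empty
  candidate segments yield empty (not missing) event tables; intervals
  shorter than one epoch yield zero epochs with a warning.
* `prune_movement` is idempotent; `group_bursts` is idempotent,
  order-independent and event-conserving; exhaustive permutation p-values
  are in (0, 1] (the identity permutation is always counted).
* Ties in peak picking resolve to the first maximal frame (numpy argmax).
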