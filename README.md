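# flysleep

Sleep staging and micro-behavior analysis for long-term multichannel
local field potential (LFP) recordings from the *Drosophila* brain.

Flies sleep, and their sleep is not monolithic: spectral activity recorded
across the brain changes as a sleep bout deepens, proboscis extensions
occur in rhythmic bursts concentrated deep in sleep, and the antennae
oscillate slowly while the fly is immobile. `flysleep` implements the full
analysis chain needed to quantify these phenomena from a 16-electrode
linear probe plus behavioral video and pose tracking:

* **behavior** — frame-differencing movement quantification, the 5-minute
  immobility sleep criterion, and the temporal partition of each bout into
  `presleep / earlysleep / midsleep / latesleep` (plus evaluation-only
  flanking bins).
* **lfp** — zero-phase resampling/filtering, detection of the
  polarity-reversal electrode from visual-evoked calibration data,
  re-referencing to it (16 → 15 channels), epoching by behavioral label,
  and Welch power spectra on the fixed 15 × 145 channel × frequency grid
  (4.88–40.04 Hz); plus PCA-based electrode localization from dye tracks.
* **clusterstats** — one-sample cluster-based permutation tests over
  per-fly spectral difference maps (exhaustive sign flips for n ≤ 20
  flies), Cohen's d maps, and within-cluster post-hocs.
* **staging** — the classifier analyses: a linear-SVM *probability probe*
  trained only on awake vs midsleep whose calibrated awake-probability is
  read out on epochs it never saw, and a SMOTE-balanced multiclass random
  forest with permutation feature importance over the channel × frequency
  grid.
* **microbehavior** — proboscis-extension detection (SVM-over-pose and
  peak-picking routes), 10-s burst grouping, the <6-s periodicity rule,
  head-axis-corrected antennal angles with FFT periodicity, and sleep-depth
  summaries.
* **synthgen** — a seeded generator producing complete synthetic sessions
  (LFP + calibration + movement + pose + ground truth) with configurable
  effect sizes, so the entire pipeline is testable without any recording.

The probability probe is the package's core statistical idea: train a
binary classifier on the two unambiguous ends of the behavioral spectrum
(awake, midsleep), calibrate its class probabilities, and read the awake
probability P(awake | spectrum) on epochs from intermediate time bins.
Bins the model never saw order themselves — presleep reads as awake,
early and late sleep read as intermediate, midsleep as deep — which is
evidence for distinct stages rather than a binary sleep switch.

## Worked example

```python
from flysleep import behavior, lfp, staging, synthgen

cfg = synthgen.SimConfig(session_hours=2.0, interbout_mean_min=10.0,
                         bout_mean_min=14.0, seed=5)
session = synthgen.simulate_session(cfg)

# behavior: movement -> sleep bouts -> stage labels
flags = behavior.prune_movement(behavior.flags_from_activity(
    session.movement_activity, fps=30.0, area_thresh=50.0))
labels = behavior.label_epochs(behavior.detect_sleep_bouts(flags))

# LFP: find the polarity reversal, re-reference, epoch, spectra
cal = lfp.detect_polarity_reversal(session.calibration,
                                   session.stimulus_onsets_s)
rec = lfp.rereference_reversal(session.recording, cal.reversal_channel)
epochs = lfp.epoch_by_labels(rec, labels, epoch_len_s=60.0)
spectra = lfp.power_spectrum(epochs)
print(cal.reversal_channel, rec.n_channels, spectra.power.shape)

# staging: the awake-probability probe
table = staging.build_feature_table(spectra)
probe = staging.train_probe_svm(table, seed=0)
profile = staging.probability_profile(probe, table)
print(profile.pooled.set_index("time_bin")["mean"].round(3))
```

Output (seed 5):

```
12 15 (116, 15, 145)
time_bin
+1:+2      0.474
-1:0       0.968
-2:-1      0.966
-3:-2      0.971
-4:-3      0.971
0:+1       0.435
awake      0.968
mid        0.030
x+1:x+2    0.972
x-1:x      0.536
x-2:x-1    0.500
x:x+1      0.971
```

The detector recovered the configured reversal electrode (12), the
re-referenced recording has 15 channels, and each 60-s epoch contributes a
15 × 145 spectrum. The probe — trained only on `awake` and `mid` epochs —
assigns awake-probability ≈ 0.97 to awake and presleep bins, ≈ 0.03 to
midsleep, and intermediate values (≈ 0.43–0.54) to the early- and
late-sleep bins it never saw, with the post-waking bins (`x:x+1`,
`x+1:x+2`) indistinguishable from awake: the ordering that indicates
distinct sleep stages.

A thin CLI wraps the same functions:

```
flysleep simulate --out session/ --seed 0
flysleep behavior --in session/ --out labels.csv
flysleep spectra --in session/ --labels labels.csv --out spectra.h5
flysleep cluster --spectra cohort.h5 --cond-a awake --cond-b midsleep --out clusters.json
# (cohort.h5: a spectra table pooling several flies; the group test needs >= 2)
flysleep stage --spectra spectra.h5 --mode probe --out probe.json
flysleep detect --pose session/pose.csv --out pe/
```

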