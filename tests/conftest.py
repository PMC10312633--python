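"""Shared fixtures: scaled-down synthetic sessions and derived tables.

Sessions here are 2 h with slightly denser sleep bouts than the 8-h
defaults, so each carries several bouts and enough epochs per stage while
keeping the suite fast; the spectral grid for classifier fixtures is the
reduced 128-point-FFT grid (18 bins, 5.9-39.1 Hz).
"""

import warnings

import numpy as np
import pytest

from flysleep import behavior, lfp, staging, synthgen

SMALL_SESSION = dict(session_hours=2.0, interbout_mean_min=10.0,
                     bout_mean_min=14.0)


def small_config(seed, **overrides):
    kw = {**SMALL_SESSION, **overrides}
    return synthgen.SimConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def session2h():
    return synthgen.simulate_session(small_config(seed=5))


@pytest.fixture(scope="session")
def spectra2h(session2h):
    """Reversal-referenced 60-s epoch spectra on the reduced grid."""
    s = session2h
    rec = lfp.rereference_reversal(s.recording, s.config.reversal_channel)
    epochs = lfp.epoch_by_labels(rec, s.truth_labels, epoch_len_s=60.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lfp.power_spectrum(epochs, nfft=128)


@pytest.fixture(scope="session")
def feature_table(spectra2h):
    return staging.build_feature_table(spectra2h)


@pytest.fixture(scope="session")
def detected_labels(session2h):
    flags = behavior.flags_from_activity(
        session2h.movement_activity, fps=session2h.config.fps_video,
        area_thresh=50.0,
    )
    flags = behavior.prune_movement(flags)
    return behavior.label_epochs(behavior.detect_sleep_bouts(flags))


def rng(seed=0):
    return np.random.default_rng(seed)
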