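"""Feature tables, balancing, the probability probe and the multiclass stager."""

import numpy as np
import pandas as pd
import pytest

from flysleep import staging
from flysleep.staging import (
    FeatureMatrix, balance_undersample, build_feature_table,
    classifier_metrics, permutation_feature_importance, probability_profile,
    smote_oversample, train_multiclass_rf, train_probe_svm,
)

LIGHT_SPACE = {"n_estimators": [100, 200], "max_depth": [None, 10],
               "min_samples_leaf": [1, 2]}


def toy_table(n_per_class=40, n_channels=3, n_freqs=4, classes=("awake", "midsleep"),
              sep=4.0, seed=0, time_bins=None):
    """Gaussian-blob features, one blob per class, channel-major layout."""
    rng = np.random.default_rng(seed)
    nf = n_channels * n_freqs
    X, rows = [], []
    for k, c in enumerate(classes):
        mu = np.zeros(nf)
        mu[k % nf] = sep * (k + 1)
        X.append(rng.normal(mu, 1.0, size=(n_per_class, nf)))
        for i in range(n_per_class):
            rows.append({
                "fly_id": 0, "label": c, "class_label": c,
                "time_bin": time_bins[k] if time_bins else
                ("mid" if c == "midsleep" else "awake"),
                "bout_id": -1, "never_train": False,
            })
    return FeatureMatrix(np.concatenate(X), pd.DataFrame(rows),
                         np.arange(1, n_channels + 1), np.arange(n_freqs))


# ---------------------------------------------------------------------------
# feature table

def test_feature_count_is_channels_times_frequencies(feature_table, spectra2h):
    nc, nf = spectra2h.power.shape[1:]
    assert feature_table.n_features == nc * nf
    assert feature_table.grid_shape() == (nc, nf)


def test_full_grid_yields_2175_features():
    """15 channels x 145 bins under default spectral settings."""
    from flysleep.core import SpectraTable
    power = np.zeros((3, 15, 145))
    sp = SpectraTable(power, np.linspace(4.88, 40.04, 145), np.arange(1, 16),
                      pd.DataFrame({"fly_id": 0, "state": "awake",
                                    "label": "awake", "time_bin": "awake",
                                    "bout_id": -1, "start_s": 0.0,
                                    "len_s": 60.0}, index=range(3)))
    assert build_feature_table(sp).n_features == 2175


def test_channel_major_flattening(feature_table, spectra2h):
    e, c, f = 0, 3, 5
    nf = len(spectra2h.freqs_hz)
    assert feature_table.X[e, c * nf + f] == spectra2h.power[e, c, f]


def test_flanking_bins_flagged_never_train(feature_table):
    meta = feature_table.meta
    assert (meta.loc[meta["label"].isin(["pre2", "post2"]), "never_train"]).all()
    assert not meta.loc[meta["label"] == "midsleep", "never_train"].any()


def test_feature_table_csv_round_trip(tmp_path, feature_table):
    sub = feature_table.subset(np.arange(10))
    path = tmp_path / "features.csv"
    sub.to_csv(path)
    back = FeatureMatrix.from_csv(path, sub.channel_ids, sub.freqs_hz)
    assert np.array_equal(back.X, sub.X)
    assert list(back.meta["label"]) == list(sub.meta["label"])


# ---------------------------------------------------------------------------
# balancing

def test_undersample_to_minority_count():
    t = toy_table(n_per_class=40, seed=1)
    t2 = t.subset(np.arange(len(t.meta) - 15))  # 40 awake / 25 midsleep
    bal = balance_undersample(t2, seed=0)
    counts = bal.meta["class_label"].value_counts()
    assert counts.to_dict() == {"awake": 25, "midsleep": 25}


def test_undersample_balanced_input_identity_up_to_order():
    t = toy_table(n_per_class=30)
    bal = balance_undersample(t, seed=0)
    assert sorted(bal.meta["row_id"]) == sorted(t.meta["row_id"])


def test_undersample_seed_contract():
    t = toy_table(n_per_class=40, seed=1)
    t2 = t.subset(np.arange(len(t.meta) - 15))
    a = balance_undersample(t2, seed=0).meta["row_id"]
    b = balance_undersample(t2, seed=1).meta["row_id"]
    assert len(a) == len(b)
    assert set(a) != set(b)


def test_smote_counts_equalized_and_convex():
    t = toy_table(n_per_class=40, seed=2)
    keep = np.concatenate([np.arange(40), np.arange(40, 50)])  # 40 vs 10
    t2 = t.subset(keep)
    out = smote_oversample(t2, k_neighbors=5, seed=0)
    counts = out.meta["class_label"].value_counts()
    assert counts.to_dict() == {"awake": 40, "midsleep": 40}
    synth = out.meta["label"] == "synthetic"
    Xs = out.X[synth.to_numpy()]
    parents = t2.X[(t2.meta["class_label"] == "midsleep").to_numpy()]
    lo, hi = parents.min(axis=0), parents.max(axis=0)
    assert (Xs >= lo - 1e-9).all() and (Xs <= hi + 1e-9).all()


def test_smote_one_dimensional_brute_force():
    """Minority {0, 1} with k=1: the only neighbor pair is (0, 1), so every
    synthetic value must lie inside [0, 1]."""
    X = np.array([[0.0], [1.0]] + [[10.0]] * 8)
    meta = pd.DataFrame({
        "fly_id": 0, "label": ["m", "m"] + ["M"] * 8,
        "class_label": ["m", "m"] + ["M"] * 8,
        "time_bin": "mid", "bout_id": -1, "never_train": False,
    })
    t = FeatureMatrix(X, meta, np.array([1]), np.array([0.0]))
    out = smote_oversample(t, k_neighbors=1, seed=0)
    synth = out.X[(out.meta["label"] == "synthetic").to_numpy()]
    assert len(synth) == 6
    assert ((synth >= 0.0) & (synth <= 1.0)).all()


def test_smote_rejects_tiny_class():
    t = toy_table(n_per_class=40, seed=3)
    t2 = t.subset(np.arange(44))  # 4 midsleep members
    with pytest.raises(ValueError, match="k_neighbors"):
        smote_oversample(t2, k_neighbors=5, seed=0)


# ---------------------------------------------------------------------------
# metrics

def test_perfect_predictions():
    out = classifier_metrics(["a", "b", "a"], ["a", "b", "a"])
    assert out["accuracy"] == out["precision"] == out["recall"] == out["f1"] == 1.0
    assert np.allclose(out["confusion_matrix"], np.eye(2))


def test_enumerated_binary_case():
    """truth {+,+,-,-}, predicted {+,-,+,-}: TP=1 FP=1 FN=1 TN=1."""
    out = classifier_metrics(["+", "+", "-", "-"], ["+", "-", "+", "-"],
                             classes=["-", "+"])
    assert out["precision"] == 0.5
    assert out["recall"] == 0.5
    assert out["f1"] == 0.5
    assert out["accuracy"] == 0.5


def test_all_one_class_predictions():
    out = classifier_metrics(["a", "a", "b", "b", "b"], ["b"] * 5,
                             classes=["a", "b"])
    assert out["per_class"]["b"]["recall"] == 1.0
    assert out["per_class"]["b"]["precision"] == pytest.approx(3 / 5)


def test_confusion_rows_sum_to_one():
    rng = np.random.default_rng(0)
    y = rng.choice(list("abc"), 60)
    p = rng.choice(list("abc"), 60)
    cm = classifier_metrics(y, p)["confusion_matrix"]
    assert np.allclose(cm.sum(axis=1), 1.0)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        classifier_metrics([1, 2], [1])


# ---------------------------------------------------------------------------
# probability probe

def test_separable_classes_score_perfectly():
    t = toy_table(n_per_class=50, sep=6.0)
    probe = train_probe_svm(t, seed=0, n_iterations=2)
    for it in probe.iterations:
        assert it.report["accuracy"] == 1.0
        assert it.report["roc_auc"] == 1.0


def test_shuffled_labels_give_chance_auc():
    rng = np.random.default_rng(3)
    aucs = []
    for k in range(20):
        t = toy_table(n_per_class=50, sep=6.0, seed=k)
        shuffled = t.meta.copy()
        shuffled["class_label"] = rng.permutation(shuffled["class_label"].to_numpy())
        t2 = FeatureMatrix(t.X, shuffled, t.channel_ids, t.freqs_hz)
        probe = train_probe_svm(t2, seed=k, n_iterations=1)
        aucs.append(probe.iterations[0].report["roc_auc"])
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)


def test_never_train_rows_audited_out(feature_table):
    probe = train_probe_svm(feature_table, seed=0, n_iterations=2)
    forbidden = set(
        feature_table.meta.loc[feature_table.meta["never_train"], "row_id"]
    )
    for it in probe.iterations:
        assert not (set(it.train_row_ids) & forbidden)


def test_scaler_fit_on_training_rows_only(feature_table):
    probe = train_probe_svm(feature_table, seed=0, n_iterations=1)
    it = probe.iterations[0]
    train_mask = feature_table.meta["row_id"].isin(it.train_row_ids).to_numpy()
    expected = feature_table.X[train_mask].mean(axis=0)
    assert np.allclose(it.scaler.mean_, expected)


def test_probe_missing_class_rejected():
    t = toy_table(classes=("awake",))
    with pytest.raises(ValueError, match="midsleep"):
        train_probe_svm(t, seed=0)


def test_probe_deterministic_given_seed(feature_table):
    a = train_probe_svm(feature_table, seed=3, n_iterations=2)
    b = train_probe_svm(feature_table, seed=3, n_iterations=2)
    pa = probability_profile(a, feature_table).pooled
    pb = probability_profile(b, feature_table).pooled
    pd.testing.assert_frame_equal(pa, pb)


def test_probe_orders_sleep_depth_on_generated_session(feature_table):
    """The core staging readout: midsleep lowest awake-probability, early
    and late sleep intermediate, awake and post-waking bins high."""
    probe = train_probe_svm(feature_table, seed=0)
    pooled = probability_profile(probe, feature_table).pooled
    p = pooled.set_index("time_bin")["mean"]
    early = (p["0:+1"] + p["+1:+2"]) / 2
    late = (p["x-2:x-1"] + p["x-1:x"]) / 2
    assert p["mid"] < early < p["awake"]
    assert p["mid"] < late < p["awake"]
    assert p["x:x+1"] > 0.5 and p["x+1:x+2"] > 0.5
    assert p["mid"] < 0.5 < p["awake"]


def test_profile_flat_on_all_awake_input():
    t = toy_table(n_per_class=50, sep=6.0)
    probe = train_probe_svm(t, seed=0, n_iterations=1)
    awake_only = t.subset((t.meta["class_label"] == "awake").to_numpy())
    prof = probability_profile(probe, awake_only)
    assert (prof.pooled["mean"] > 0.8).all()


# ---------------------------------------------------------------------------
# multiclass stager

def five_class_table(sep=5.0, seed=0, n=40):
    classes = ("awake", "presleep", "earlysleep", "midsleep", "latesleep")
    return toy_table(n_per_class=n, n_channels=3, n_freqs=4, classes=classes,
                     sep=sep, seed=seed)


def test_well_separated_classes_near_perfect_confusion_diagonal():
    t = five_class_table()
    res = train_multiclass_rf(t, seed=0, tuning_budget=2,
                              search_space=LIGHT_SPACE)
    assert np.diag(res.mean_confusion()).min() >= 0.95


def test_aliased_classes_confused():
    """Two classes drawn from the same distribution must show mutual
    confusion."""
    rng = np.random.default_rng(5)
    t = five_class_table(seed=5)
    classes = ("awake", "presleep", "earlysleep", "midsleep", "latesleep")
    y = t.meta["class_label"].to_numpy()
    # make earlysleep identical in distribution to latesleep
    src = t.X[y == "latesleep"]
    t.X[y == "earlysleep"] = src + rng.normal(0, 1e-6, size=src.shape)
    res = train_multiclass_rf(t, seed=0, tuning_budget=2,
                              search_space=LIGHT_SPACE)
    cm = res.mean_confusion()
    i, j = classes.index("earlysleep"), classes.index("latesleep")
    assert cm[i, j] + cm[j, i] >= 0.3


def test_permuted_labels_give_chance_macro_f1():
    rng = np.random.default_rng(6)
    f1s = []
    for k in range(5):
        t = five_class_table(seed=k)
        t.meta["class_label"] = rng.permutation(t.meta["class_label"].to_numpy())
        res = train_multiclass_rf(t, seed=k, tuning_budget=1,
                                  search_space={"n_estimators": [100],
                                                "max_depth": [None],
                                                "min_samples_leaf": [1]})
        f1s.append(np.mean([it.report["f1"] for it in res.iterations]))
    assert np.mean(f1s) == pytest.approx(0.2, abs=0.1)


def test_missing_class_rejected():
    t = toy_table(classes=("awake", "midsleep"))
    with pytest.raises(ValueError, match="missing"):
        train_multiclass_rf(t, seed=0)


# ---------------------------------------------------------------------------
# permutation importance

def test_noise_feature_importance_near_zero():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(300, 6))
    y = (X[:, 2] > 0).astype(int)
    from sklearn.ensemble import RandomForestClassifier
    m = RandomForestClassifier(n_estimators=100, random_state=0).fit(X[:200], y[:200])
    imp = permutation_feature_importance(m, X[200:], y[200:], repeats=10, seed=0)
    assert imp[2] > 0.2
    noise = np.delete(imp, 2)
    assert np.abs(noise).max() < 0.05


def test_accuracy_scoring_matches_sklearn_reference():
    """Oracle equivalence: under accuracy scoring the batched implementation
    agrees with sklearn's permutation_importance up to shuffle noise."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance as skpi
    rng = np.random.default_rng(8)
    X = rng.normal(size=(240, 8))
    y = ((X[:, 1] + 0.5 * X[:, 5]) > 0).astype(int)
    m = RandomForestClassifier(n_estimators=100, random_state=0).fit(X[:160], y[:160])
    ours = permutation_feature_importance(m, X[160:], y[160:], repeats=30,
                                          seed=0, scoring="accuracy")
    ref = skpi(m, X[160:], y[160:], n_repeats=30, random_state=0,
               n_jobs=1).importances_mean
    assert np.argmax(ours) == np.argmax(ref)
    assert np.abs(ours - ref).max() < 0.06


def test_importance_map_localizes_discriminative_feature():
    t = five_class_table(sep=5.0, seed=9)
    res = train_multiclass_rf(t, seed=0, tuning_budget=1,
                              search_space={"n_estimators": [100],
                                            "max_depth": [None],
                                            "min_samples_leaf": [1]})
    imp = staging.permutation_importance_map(res, t)
    assert imp.shape == t.grid_shape()
    # classes live on features 0..4 of the 12-cell grid (channel-major)
    informative = {(k // 4, k % 4) for k in range(5)}
    top = np.unravel_index(np.argsort(imp.ravel())[::-1][:5], imp.shape)
    top_cells = set(zip(*[ax.tolist() for ax in top]))
    assert len(top_cells & informative) >= 4
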