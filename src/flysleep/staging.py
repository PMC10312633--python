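"""Classifier-based sleep staging on channel x frequency spectral features.

Two analyses share the flattened (channel-major) 15 x 145 = 2175-feature
grid of per-epoch power spectra:

* the *probability probe*: a linear-kernel SVM trained only on awake vs
  midsleep epochs, whose calibrated awake-class probability is then read
  out on epochs from every relative-time bin — including bins the model
  never saw — revealing intermediate brain states around sleep onset;
* the *multiclass stager*: a random forest over all five classes (after
  SMOTE balancing), whose permutation feature importance localizes the
  discriminative (channel, frequency) cells.

Evaluation-only flanking bins (pre2/post2) are retained in the feature
table but flagged never-train, and a row-id audit proves they are absent
from every training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import NEVER_TRAIN_LABELS, SpectraTable, STATES

N_ITERATIONS = 5  # independent train/test splits per analysis


@dataclass
class FeatureMatrix:
    """Epochs x features table with per-epoch metadata.

    ``X`` flattens each epoch's (channel, frequency) power grid
    channel-major: feature ``k`` is channel ``k // n_freqs`` (in
    ``channel_ids`` order), frequency bin ``k % n_freqs``.
    """

    X: np.ndarray
    meta: pd.DataFrame  # fly_id, label (class), time_bin, never_train, row_id
    channel_ids: np.ndarray
    freqs_hz: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        nc, nf = len(self.channel_ids), len(self.freqs_hz)
        if self.X.shape[1] != nc * nf:
            raise ValueError("feature count does not match the channel/freq grid")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing values")
        self.meta = self.meta.reset_index(drop=True)
        if "row_id" not in self.meta.columns:
            self.meta["row_id"] = np.arange(len(self.meta))

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def grid_shape(self):
        return len(self.channel_ids), len(self.freqs_hz)

    def subset(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(self.X[mask], self.meta.iloc[mask],
                             self.channel_ids, self.freqs_hz)

    def to_csv(self, path) -> None:
        nf = len(self.freqs_hz)
        names = [
            f"ch{self.channel_ids[k // nf]}_f{self.freqs_hz[k % nf]:.4f}"
            for k in range(self.n_features)
        ]
        df = pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.X, columns=names)], axis=1,
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, channel_ids, freqs_hz) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        feat_cols = [c for c in df.columns if c.startswith("ch")]
        meta = df.drop(columns=feat_cols)
        return cls(df[feat_cols].to_numpy(), meta,
                   np.asarray(channel_ids), np.asarray(freqs_hz))


def build_feature_table(spectra: SpectraTable) -> FeatureMatrix:
    """Flatten per-epoch spectra into the classifier feature table.

    One row per epoch; evaluation-only flanking bins are kept but flagged
    ``never_train``.
    """
    ne, nc, nf = spectra.power.shape
    X = spectra.power.reshape(ne, nc * nf)
    meta = spectra.epochs[["fly_id", "label", "state", "time_bin",
                           "bout_id"]].copy()
    meta = meta.rename(columns={"state": "class_label"})
    meta["never_train"] = meta["label"].isin(NEVER_TRAIN_LABELS)
    meta["row_id"] = np.arange(ne)
    return FeatureMatrix(X, meta, spectra.channel_ids, spectra.freqs_hz)


def balance_undersample(
    table: FeatureMatrix, classes=None, seed: int = 0,
    class_column: str = "class_label",
) -> FeatureMatrix:
    """Randomly subsample majority classes to the minority count."""
    y = table.meta[class_column]
    classes = list(classes) if classes is not None else sorted(y.unique())
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) == 0:
        raise ValueError(f"empty class among {classes}")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero((y == c).to_numpy())
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return table.subset(keep)


def smote_oversample(
    table: FeatureMatrix, k_neighbors: int = 5, seed: int = 0,
    class_column: str = "class_label",
) -> FeatureMatrix:
    """Synthetic minority over-sampling.

    Minority classes are augmented to the majority count with synthetic
    points placed uniformly at random on the segment between a minority
    point and one of its ``k_neighbors`` nearest same-class neighbors.
    """
    y = table.meta[class_column]
    counts = y.value_counts()
    n_max = int(counts.max())
    rng = np.random.default_rng(seed)
    Xs, metas = [table.X], [table.meta]
    next_row = int(table.meta["row_id"].max()) + 1 if len(table.meta) else 0
    for c, n_c in counts.items():
        need = n_max - int(n_c)
        if need == 0:
            continue
        if n_c <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {n_c} members; needs > k_neighbors="
                f"{k_neighbors} for SMOTE"
            )
        idx = np.flatnonzero((y == c).to_numpy())
        Xc = table.X[idx]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        _, nbrs = nn.kneighbors(Xc)
        pick = rng.integers(0, len(Xc), size=need)
        which = rng.integers(1, k_neighbors + 1, size=need)  # skip self
        lam = rng.random(size=need)[:, None]
        parents_a = Xc[pick]
        parents_b = Xc[nbrs[pick, which]]
        Xs.append(parents_a + lam * (parents_b - parents_a))
        m = pd.DataFrame({
            "fly_id": -1, "label": "synthetic", "class_label": c,
            "time_bin": "synthetic", "bout_id": -1, "never_train": False,
            "row_id": np.arange(next_row, next_row + need),
        })
        m[class_column] = c
        for col in table.meta.columns:
            if col not in m.columns:
                m[col] = pd.NA
        next_row += need
        metas.append(m[table.meta.columns])
    return FeatureMatrix(
        np.concatenate(Xs), pd.concat(metas, ignore_index=True),
        table.channel_ids, table.freqs_hz,
    )


def classifier_metrics(y_true, y_pred, probabilities=None, classes=None) -> dict:
    """Standard classification metrics.

    Recall TP/(TP+FN), precision TP/(TP+FP), f1 their harmonic mean,
    accuracy correct/total; roc_auc from probability rankings in the binary
    case; row-normalized confusion matrix (rows = actual class).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction/truth length mismatch")
    classes = list(classes) if classes is not None else sorted(
        np.unique(np.concatenate([y_true, y_pred]))
    )
    binary = len(classes) == 2
    avg = "binary" if binary else "macro"
    pos = classes[-1] if binary else 1
    out = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "precision": float(skm.precision_score(
            y_true, y_pred, average=avg, pos_label=pos, zero_division=0)),
        "recall": float(skm.recall_score(
            y_true, y_pred, average=avg, pos_label=pos, zero_division=0)),
        "f1": float(skm.f1_score(
            y_true, y_pred, average=avg, pos_label=pos, zero_division=0)),
        "per_class": {
            c: {
                "precision": float(skm.precision_score(
                    y_true, y_pred, labels=[c], average="macro",
                    zero_division=0)),
                "recall": float(skm.recall_score(
                    y_true, y_pred, labels=[c], average="macro",
                    zero_division=0)),
                "f1": float(skm.f1_score(
                    y_true, y_pred, labels=[c], average="macro",
                    zero_division=0)),
            } for c in classes
        },
    }
    cm = skm.confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    rowsum = cm.sum(axis=1, keepdims=True)
    out["confusion_matrix"] = np.divide(
        cm, rowsum, out=np.zeros_like(cm), where=rowsum > 0
    )
    out["classes"] = classes
    if binary and probabilities is not None:
        out["roc_auc"] = float(skm.roc_auc_score(
            (y_true == pos).astype(int), np.asarray(probabilities)
        ))
    return out


@dataclass
class ProbeIteration:
    scaler: StandardScaler
    model: SVC
    report: dict
    train_row_ids: np.ndarray
    test_row_ids: np.ndarray


@dataclass
class ProbeResult:
    """Awake-vs-midsleep probability probe over several splits."""

    iterations: list[ProbeIteration]
    classes: list[str]

    def awake_probability(self, table: FeatureMatrix) -> np.ndarray:
        """(n_iterations, n_epochs) awake-class probability."""
        out = []
        awake_col = self.classes.index("awake")
        for it in self.iterations:
            p = it.model.predict_proba(it.scaler.transform(table.X))
            out.append(p[:, awake_col])
        return np.asarray(out)


def train_probe_svm(
    table: FeatureMatrix,
    seed: int = 0,
    n_iterations: int = N_ITERATIONS,
    test_fraction: float = 0.20,
) -> ProbeResult:
    """Linear-kernel SVM probe with calibrated class probabilities.

    Per iteration: undersample-balance the awake/midsleep rows, stratified
    80/20 split, z-score standardization fit on the training rows only,
    linear SVM with sigmoid-calibrated probabilities, held-out metrics.
    Never-train rows are excluded before balancing and audited afterwards.
    """
    eligible = table.subset(
        (~table.meta["never_train"]).to_numpy()
        & table.meta["class_label"].isin(["awake", "midsleep"]).to_numpy()
    )
    for cls in ("awake", "midsleep"):
        if not (eligible.meta["class_label"] == cls).any():
            raise ValueError(f"no {cls!r} epochs available for the probe")
    forbidden = set(table.meta.loc[table.meta["never_train"], "row_id"])
    iterations = []
    classes = ["awake", "midsleep"]
    for i in range(n_iterations):
        bal = balance_undersample(eligible, classes=classes, seed=seed + 1000 * i)
        y = bal.meta["class_label"].to_numpy()
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=test_fraction, random_state=seed + i, stratify=y
        )
        train_ids = bal.meta["row_id"].to_numpy()[tr]
        assert not (set(train_ids) & forbidden), \
            "never-train rows leaked into a training split"
        scaler = StandardScaler().fit(bal.X[tr])
        model = SVC(kernel="linear", probability=True, random_state=seed + i)
        model.fit(scaler.transform(bal.X[tr]), y[tr])
        proba = model.predict_proba(scaler.transform(bal.X[te]))
        pred = model.classes_[np.argmax(proba, axis=1)]
        awake_col = list(model.classes_).index("awake")
        report = classifier_metrics(
            y[te], pred, probabilities=proba[:, awake_col],
            classes=["midsleep", "awake"],
        )
        report["iteration"] = i
        iterations.append(ProbeIteration(
            scaler=scaler, model=model, report=report,
            train_row_ids=train_ids,
            test_row_ids=bal.meta["row_id"].to_numpy()[te],
        ))
    # align class order for probability readout
    cls_order = list(iterations[0].model.classes_)
    return ProbeResult(iterations=iterations, classes=cls_order)


@dataclass
class StagingProfile:
    """Mean awake-probability per relative-time bin, per iteration and pooled."""

    per_bin: pd.DataFrame       # time_bin, iteration, mean, sd, n
    pooled: pd.DataFrame        # time_bin, mean, sd, n
    epoch_probability: np.ndarray  # (n_iterations, n_epochs)


def probability_profile(probe: ProbeResult, table: FeatureMatrix) -> StagingProfile:
    """Awake-class probability across relative-time bins.

    Every epoch is scored — including never-train bins, which the probe has
    provably not seen — and averaged per bin per iteration, then pooled.
    """
    probs = probe.awake_probability(table)
    bins = table.meta["time_bin"].to_numpy()
    rows = []
    for i, p in enumerate(probs):
        for b in pd.unique(bins):
            sel = p[bins == b]
            rows.append({"time_bin": b, "iteration": i,
                         "mean": float(sel.mean()), "sd": float(sel.std()),
                         "n": int(len(sel))})
    per_bin = pd.DataFrame(rows)
    pooled = (
        per_bin.groupby("time_bin")
        .apply(lambda g: pd.Series({
            "mean": float(np.average(g["mean"], weights=g["n"])),
            "sd": float(g["sd"].mean()),
            "n": int(g["n"].sum()),
        }), include_groups=False)
        .reset_index()
    )
    return StagingProfile(per_bin=per_bin, pooled=pooled,
                          epoch_probability=probs)


DEFAULT_SEARCH_SPACE = {
    "n_estimators": [200, 400, 600, 800],
    "max_depth": [None, 10, 20, 30, 40],
    "min_samples_leaf": [1, 2, 3, 4],
}


def _two_stage_search(Xtr, ytr, Xval, yval, seed, budget, space):
    """Seeded randomized screen followed by a local grid around the best."""
    rng = np.random.default_rng(seed)
    keys = list(space)

    def fit_score(params):
        m = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        m.fit(Xtr, ytr)
        return m, m.score(Xval, yval)

    best, best_score, tried = None, -np.inf, set()
    n_random = max(1, budget // 2)
    for _ in range(n_random):
        params = {k: space[k][rng.integers(len(space[k]))] for k in keys}
        key = tuple(params.values())
        if key in tried:
            continue
        tried.add(key)
        m, s = fit_score(params)
        if s > best_score:
            best, best_score = params, s
    # local grid: one-step neighbors of the best along each axis
    budget_left = budget - len(tried)
    for k in keys:
        options = space[k]
        j = options.index(best[k])
        for jj in (j - 1, j + 1):
            if budget_left <= 0 or not 0 <= jj < len(options):
                continue
            params = dict(best, **{k: options[jj]})
            key = tuple(params.values())
            if key in tried:
                continue
            tried.add(key)
            budget_left -= 1
            m, s = fit_score(params)
            if s > best_score:
                best, best_score = params, s
    return best


@dataclass
class StagingIteration:
    scaler: StandardScaler
    model: RandomForestClassifier
    report: dict
    params: dict
    Xte_scaled: np.ndarray = field(repr=False)
    yte: np.ndarray = field(repr=False)
    train_row_ids: np.ndarray = field(repr=False)


@dataclass
class StagingResult:
    iterations: list[StagingIteration]
    classes: list[str]

    def mean_confusion(self) -> np.ndarray:
        return np.mean([it.report["confusion_matrix"]
                        for it in self.iterations], axis=0)


def train_multiclass_rf(
    table: FeatureMatrix,
    seed: int = 0,
    tuning_budget: int = 10,
    n_iterations: int = N_ITERATIONS,
    test_fraction: float = 0.20,
    classes=STATES,
    class_column: str = "class_label",
    k_neighbors: int = 5,
    search_space: dict | None = None,
) -> StagingResult:
    """Multiclass random-forest stager with SMOTE balancing.

    SMOTE balance -> stratified 80/20 split -> scaling -> seeded two-stage
    hyperparameter search within ``tuning_budget`` model fits -> held-out
    per-class metrics and row-normalized confusion matrix, over
    ``n_iterations`` independent splits.
    """
    present = set(table.meta[class_column][~table.meta["never_train"]])
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes missing from the table: {missing}")
    eligible = table.subset((~table.meta["never_train"]).to_numpy()
                            & table.meta[class_column].isin(classes).to_numpy())
    forbidden = set(table.meta.loc[table.meta["never_train"], "row_id"])
    balanced = smote_oversample(eligible, k_neighbors=k_neighbors, seed=seed,
                                class_column=class_column)
    y = balanced.meta[class_column].to_numpy()
    iterations = []
    for i in range(n_iterations):
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=test_fraction, random_state=seed + i, stratify=y
        )
        train_ids = balanced.meta["row_id"].to_numpy()[tr]
        real = balanced.meta["label"].to_numpy()[tr] != "synthetic"
        assert not (set(train_ids[real]) & forbidden), \
            "never-train rows leaked into a training split"
        scaler = StandardScaler().fit(balanced.X[tr])
        Xtr = scaler.transform(balanced.X[tr])
        Xte = scaler.transform(balanced.X[te])
        tr2, val = train_test_split(
            np.arange(len(tr)), test_size=0.25, random_state=seed + i,
            stratify=y[tr],
        )
        params = _two_stage_search(
            Xtr[tr2], y[tr][tr2], Xtr[val], y[tr][val],
            seed=seed + i, budget=tuning_budget,
            space=search_space or DEFAULT_SEARCH_SPACE,
        )
        model = RandomForestClassifier(random_state=seed + i, n_jobs=1, **params)
        model.fit(Xtr, y[tr])
        pred = model.predict(Xte)
        report = classifier_metrics(y[te], pred, classes=list(classes))
        report["iteration"] = i
        iterations.append(StagingIteration(
            scaler=scaler, model=model, report=report, params=params,
            Xte_scaled=Xte, yte=y[te], train_row_ids=train_ids,
        ))
    return StagingResult(iterations=iterations, classes=list(classes))


def permutation_feature_importance(
    model, X: np.ndarray, y: np.ndarray, repeats: int = 5, seed: int = 0,
    scoring: str = "true_class_probability", feature_chunk: int = 64,
) -> np.ndarray:
    """Mean model-score drop per feature over independent column shuffles.

    Shuffling a column breaks its relationship with the target; important
    features show a large score drop.  ``scoring`` is either ``accuracy``
    (the held-out accuracy) or ``true_class_probability`` (the mean
    predicted probability of the true class) — the latter resolves small
    importances that accuracy, quantized at 1/n_rows, cannot.  Equivalent
    to scoring each shuffle separately, but predictions are batched over
    (feature, repeat) copies of the held-out rows, which is an order of
    magnitude faster for forests.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_feat = X.shape

    if scoring == "accuracy":
        def score_block(block, tiled_y):
            pred = model.predict(block)
            return (pred.reshape(-1, n_rows) == y[None, :]).mean(axis=1)
        base = float(np.mean(model.predict(X) == y))
    elif scoring == "true_class_probability":
        classes = list(model.classes_)
        yi = np.array([classes.index(c) for c in y])

        def score_block(block, tiled_y):
            p = model.predict_proba(block)
            ptrue = p[np.arange(p.shape[0]), tiled_y]
            return ptrue.reshape(-1, n_rows).mean(axis=1)
        base = float(
            model.predict_proba(X)[np.arange(n_rows), yi].mean()
        )
    else:
        raise ValueError(f"unknown scoring {scoring!r}")

    drops = np.empty(n_feat)
    for f0 in range(0, n_feat, feature_chunk):
        feats = range(f0, min(f0 + feature_chunk, n_feat))
        stack = np.repeat(X[None, :, :], len(feats) * repeats, axis=0)
        for k, f in enumerate(feats):
            for r in range(repeats):
                stack[k * repeats + r, :, f] = rng.permutation(X[:, f])
        tiled = (np.tile(yi, len(feats) * repeats)
                 if scoring == "true_class_probability" else None)
        scores = score_block(stack.reshape(-1, n_feat), tiled)
        drops[f0:f0 + len(feats)] = base - scores.reshape(
            len(feats), repeats).mean(axis=1)
    return drops


def permutation_importance_map(
    result: StagingResult,
    table: FeatureMatrix,
    repeats: int = 5,
    seed: int = 0,
    scoring: str = "true_class_probability",
) -> np.ndarray:
    """Mean permutation-importance per feature, as a channels x freqs map.

    Per iteration, each held-out feature column is shuffled ``repeats``
    times and the mean model-score drop recorded; scores are averaged
    across the split iterations and reshaped to the feature grid.
    """
    maps = []
    for i, it in enumerate(result.iterations):
        if len(it.yte) < 2:
            raise ValueError("held-out set too small for importance")
        maps.append(permutation_feature_importance(
            it.model, it.Xte_scaled, it.yte, repeats=repeats, seed=seed + i,
            scoring=scoring,
        ))
    mean_imp = np.mean(maps, axis=0)
    return mean_imp.reshape(table.grid_shape())


def top_fraction_mask(importance: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the top ``fraction`` of cells by importance."""
    k = max(1, int(round(fraction * importance.size)))
    thresh = np.sort(importance.ravel())[-k]
    return importance >= thresh
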