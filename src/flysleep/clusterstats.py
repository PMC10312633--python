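"""Group-level inference on channel x frequency difference maps.

The group statistic is a one-sample cluster-based permutation test over
per-fly mean spectral differences (condition A minus condition B, dB):
cell-wise t statistics across flies are thresholded at the two-tailed t
quantile, supra-threshold cells are grouped into 4-connected clusters on
the (channel, frequency) grid, and each cluster's mass (sum of t) is
calibrated against the distribution of the maximum absolute cluster mass
under sign-flip permutations — exhaustive (all 2^n flips) for n <= 20
flies, a seeded random subset otherwise.

Channel adjacency follows original electrode indices: channels are adjacent
iff their indices are consecutive, so the dropped reversal channel does not
bridge its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import SpectraTable

EXHAUSTIVE_LIMIT = 20          # n flies up to which all 2^n flips are used
RANDOM_PERMUTATIONS = 2 ** 16  # seeded subset beyond that
EFFECT_SIZE_CAP = 1e6


@dataclass
class DifferenceMap:
    """Per-fly mean spectral differences, flies x channels x frequencies."""

    values: np.ndarray
    channel_ids: np.ndarray
    freqs_hz: np.ndarray
    fly_ids: np.ndarray
    cond_a: str = "A"
    cond_b: str = "B"
    trial_counts: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (flies, channels, freqs)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference map has missing cells")
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.fly_ids = np.asarray(self.fly_ids)

    @property
    def n_flies(self) -> int:
        return self.values.shape[0]


def build_difference_map(
    spectra: SpectraTable,
    cond_a: str,
    cond_b: str,
    min_trials: int = 10,
    condition_column: str = "state",
) -> DifferenceMap:
    """Per-fly mean spectrum per condition, A minus B, gated on trial count.

    Flies with fewer than ``min_trials`` epochs in either condition are
    excluded (and reported via a warning), mirroring the trial gates used
    for the sleep/wake (10) and proboscis (50) contrasts.
    """
    meta = spectra.epochs
    for cond in (cond_a, cond_b):
        if not (meta[condition_column] == cond).any():
            raise ValueError(f"condition {cond!r} absent from spectra")
    diffs, flies, counts = [], [], []
    for fly, sub in meta.groupby("fly_id"):
        na = int((sub[condition_column] == cond_a).sum())
        nb = int((sub[condition_column] == cond_b).sum())
        counts.append({"fly_id": fly, cond_a: na, cond_b: nb,
                       "included": na >= min_trials and nb >= min_trials})
        if na < min_trials or nb < min_trials:
            warnings.warn(
                f"fly {fly} excluded: {na} {cond_a!r} / {nb} {cond_b!r} trials "
                f"< gate {min_trials}", stacklevel=2,
            )
            continue
        ia = sub.index[sub[condition_column] == cond_a].to_numpy()
        ib = sub.index[sub[condition_column] == cond_b].to_numpy()
        diffs.append(spectra.power[ia].mean(axis=0)
                     - spectra.power[ib].mean(axis=0))
        flies.append(fly)
    if len(diffs) < 2:
        raise ValueError("fewer than 2 flies survive the trial-count gate")
    return DifferenceMap(
        values=np.stack(diffs), channel_ids=spectra.channel_ids,
        freqs_hz=spectra.freqs_hz, fly_ids=np.asarray(flies),
        cond_a=cond_a, cond_b=cond_b, trial_counts=pd.DataFrame(counts),
    )


@dataclass
class ClusterResult:
    """Clusters of coherent spectral difference with permutation p-values."""

    masks: list[np.ndarray]       # boolean (channels, freqs) per cluster
    masses: np.ndarray            # sum of t within each cluster (signed)
    p_values: np.ndarray
    t_map: np.ndarray
    t_threshold: float
    n_permutations: int
    alpha: float

    def significant(self) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p <= self.alpha]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(len(self.masses)),
            "mass": self.masses,
            "sign": np.sign(self.masses).astype(int),
            "n_cells": [int(m.sum()) for m in self.masks],
            "p_value": self.p_values,
        })


def _channel_rows(channel_ids: np.ndarray) -> np.ndarray:
    """Row index per channel on a grid where only consecutive original
    indices touch; a dropped channel leaves an unbridged gap row."""
    ids = np.asarray(channel_ids)
    return ids - ids.min()


def _grid_shape(channel_ids: np.ndarray, n_freqs: int):
    rows = _channel_rows(channel_ids)
    return rows, (int(rows.max()) + 1, n_freqs)


_STRUCT2 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_STRUCT3 = np.zeros((3, 3, 3), dtype=bool)
_STRUCT3[1] = _STRUCT2  # no connections across the permutation axis


def _cluster_masses(t_grid: np.ndarray, thresh: float):
    """Clusters and signed masses of a single (rows, freqs) t map."""
    masks, masses = [], []
    for sign in (1.0, -1.0):
        lab, n_lab = ndimage.label(sign * t_grid > thresh, structure=_STRUCT2)
        for k in range(1, n_lab + 1):
            m = lab == k
            masks.append(m)
            masses.append(float(t_grid[m].sum()))
    return masks, np.asarray(masses)


def _sign_matrix(n: int, n_permutations, rng) -> np.ndarray:
    if n_permutations == "all":
        codes = np.arange(2 ** n, dtype=np.uint32)
        bits = (codes[:, None] >> np.arange(n)[None, :]) & 1
        return (1.0 - 2.0 * bits).astype(np.float32)
    S = rng.integers(0, 2, size=(int(n_permutations), n)).astype(np.float32)
    S = 1.0 - 2.0 * S
    S[0] = 1.0  # keep the identity among the permutations
    return S


def _null_max_masses(
    X: np.ndarray, rows: np.ndarray, shape, thresh: float,
    S: np.ndarray, batch_cells: int = 20_000_000,
) -> np.ndarray:
    """Max |cluster mass| per sign-flip permutation, batched and vectorized.

    For a one-sample t, sign flips leave the per-cell sum of squares
    unchanged, so only the flipped means vary: t maps for a whole batch of
    permutations reduce to one matrix product plus one connected-component
    labeling of the stacked thresholded maps (no linkage across the
    permutation axis).
    """
    n, n_cells = X.shape
    ssq = (X ** 2).sum(axis=0)
    P = len(S)
    null_max = np.zeros(P)
    slice_cells = shape[0] * shape[1]
    batch = max(1, batch_cells // max(n_cells, 1))
    inv = 1.0 / (n * (n - 1))
    ssq32 = ssq.astype(np.float32)
    for b0 in range(0, P, batch):
        Sb = S[b0:b0 + batch].astype(np.float64)
        means = ((Sb @ X) / n).astype(np.float32)
        var_n = (ssq32[None, :] - n * means * means) * np.float32(inv)
        se = np.sqrt(np.maximum(var_n, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, means / se, np.float32(0.0))
        grid = np.zeros((len(Sb),) + shape, dtype=np.float32)
        grid[:, rows, :] = t.reshape(len(Sb), -1, shape[1])
        flat_t = grid.ravel()
        bmax = np.zeros(len(Sb))
        for sign in (1.0, -1.0):
            lab, n_lab = ndimage.label(sign * grid > thresh, structure=_STRUCT3)
            if n_lab == 0:
                continue
            flat = lab.ravel()
            nz = np.flatnonzero(flat)
            ids = flat[nz]
            # each cluster lives in exactly one permutation slice
            perm_of = np.zeros(n_lab + 1, dtype=np.int64)
            perm_of[ids] = nz // slice_cells
            masses = np.abs(np.bincount(ids, weights=flat_t[nz],
                                        minlength=n_lab + 1))
            np.maximum.at(bmax, perm_of[1:], masses[1:])
        null_max[b0:b0 + len(Sb)] = bmax
    return null_max


def cluster_permutation_test(
    diff: DifferenceMap,
    alpha: float = 0.05,
    cluster_forming_alpha: float = 0.05,
    n_permutations: int | str = "auto",
    seed: int | None = 0,
) -> ClusterResult:
    """One-sample spatio-spectral cluster permutation test.

    Two-sided throughout: positive and negative clusters are formed
    separately and calibrated against the common max-|mass| null.  With
    ``n_permutations='auto'`` the test is exhaustive (all 2^n sign flips,
    hence seed-independent) for n <= 20 flies and uses a seeded random
    subset of 2^16 flips beyond that.
    """
    X3 = diff.values
    n = X3.shape[0]
    if n < 2:
        raise ValueError("need at least 2 flies")
    n_cells = X3.shape[1] * X3.shape[2]
    X = X3.reshape(n, n_cells)
    thresh = float(stats.t.ppf(1.0 - cluster_forming_alpha / 2.0, df=n - 1))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("zero-variance cells: their t set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(~degenerate, mean / (sd / np.sqrt(n)), 0.0)
    rows, shape = _grid_shape(diff.channel_ids, X3.shape[2])
    t_grid = np.zeros(shape)
    t_grid[rows, :] = t_obs.reshape(X3.shape[1], X3.shape[2])
    grid_masks, masses = _cluster_masses(t_grid, thresh)
    # map masks back from the gap-expanded grid to (channels, freqs)
    masks = [m[rows, :] for m in grid_masks]

    if n_permutations == "auto":
        n_permutations = "all" if n <= EXHAUSTIVE_LIMIT else RANDOM_PERMUTATIONS
    rng = np.random.default_rng(seed)
    S = _sign_matrix(n, n_permutations, rng)
    null_max = _null_max_masses(X, rows, shape, thresh, S)
    P = len(S)
    # relative slack: the null t maps are computed in float32
    p_values = np.array([
        float((null_max >= abs(m) * (1 - 1e-6) - 1e-9).sum()) / P
        for m in masses
    ])
    order = np.argsort(p_values, kind="stable")
    return ClusterResult(
        masks=[masks[i] for i in order],
        masses=masses[order],
        p_values=p_values[order],
        t_map=t_grid[rows, :],
        t_threshold=thresh,
        n_permutations=P,
        alpha=alpha,
    )


def effect_size_map(diff: DifferenceMap) -> np.ndarray:
    """Cell-wise one-sample Cohen's d: mean of per-fly differences divided
    by their standard deviation.  Zero-SD cells with nonzero mean are capped
    (with a warning); identically zero cells give d = 0."""
    mean = diff.values.mean(axis=0)
    sd = diff.values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = mean / sd
    zero_sd = sd == 0
    d[zero_sd & (mean == 0)] = 0.0
    bad = zero_sd & (mean != 0)
    if bad.any():
        warnings.warn("zero-SD cells with nonzero mean: d capped", stacklevel=2)
        d[bad] = np.sign(mean[bad]) * EFFECT_SIZE_CAP
    return d


def within_cluster_posthoc(diff: DifferenceMap, mask: np.ndarray) -> dict:
    """Direction of the effect within a cluster.

    Averages the in-cluster difference per fly and reports the sign with a
    one-sample t summary ('A > B', 'A < B' or 'indeterminate').
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cluster mask")
    per_fly = diff.values[:, mask].mean(axis=1)
    t, p = stats.ttest_1samp(per_fly, 0.0)
    m = per_fly.mean()
    consistent_pos = bool((per_fly > 0).all())
    consistent_neg = bool((per_fly < 0).all())
    if m > 0 and (p < 0.05 or consistent_pos):
        direction = f"{diff.cond_a} > {diff.cond_b}"
    elif m < 0 and (p < 0.05 or consistent_neg):
        direction = f"{diff.cond_a} < {diff.cond_b}"
    else:
        direction = "indeterminate"
    return {
        "per_fly_mean": per_fly,
        "mean": float(m),
        "t": float(t),
        "p": float(p),
        "direction": direction,
    }


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap of two cell masks: |intersection| / |union|."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 0.0
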