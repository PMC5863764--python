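"""Sliding-window spatiotemporal representational similarity analysis.

At each center time (every 10 ms from -0.2 to 2.5 s around cue onset) a
trial is summarized by the concatenated 8-channel x 41-sample raw EEG
window (200 ms at 200 Hz, both ends included). Spearman correlations
between trial feature vectors quantify pairwise similarity; only the
upper triangle is kept, same-adjective pairs across cueing rounds are
excluded, and within-category (object-object and scene-scene) versus
between-category (object-scene) cell means are compared after randomly
sub-sampling the majority class so both means use the same number of
cells. Mean similarities are Fisher z-transformed.

Category distinctiveness is 1 minus the mean raw between-category
similarity over a stated window (default 1.76-2.06 s, the behavioral
correlation window; 1.5-2.5 s is the spindle-correlation window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .filters import lowpass
from .io_core import EpochSet

RSA_TMIN, RSA_TMAX = -0.2, 2.5
WINDOW_MS, STEP_MS = 200, 10
BEHAVIOR_WINDOW = (1.76, 2.06)
SPINDLE_WINDOW = (1.5, 2.5)
_Z_CLIP = 1.0 - 1e-6


@dataclass
class FeatureSet:
    """Per-trial, per-time feature vectors: (trials, times, features)."""

    features: np.ndarray
    times: np.ndarray
    metadata: pd.DataFrame = field(repr=False)


@dataclass
class SimilaritySeries:
    """Within/between-category similarity over time for one subject.

    ``within_r``/``between_r`` are mean Spearman correlations;
    ``within_z``/``between_z`` their Fisher transforms.
    """

    times: np.ndarray
    within_r: np.ndarray
    between_r: np.ndarray
    within_z: np.ndarray
    between_z: np.ndarray
    n_cells: int

    def to_frame(self, subject=None) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times,
                           "within_z": self.within_z,
                           "between_z": self.between_z,
                           "within_r": self.within_r,
                           "between_r": self.between_r})
        if subject is not None:
            df.insert(0, "subject", subject)
        return df


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with correlations clipped away from +/-1 to keep z finite."""
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def build_feature_vectors(epochs: EpochSet, window_ms: int = WINDOW_MS,
                          step_ms: int = STEP_MS, tmin: float = RSA_TMIN,
                          tmax: float = RSA_TMAX,
                          lowpass_hz: float | None = None) -> FeatureSet:
    """Concatenated channel x sample windows at each sliding center time.

    ``epochs`` should already be high-pass filtered at 0.5 Hz. With
    ``lowpass_hz`` set (e.g. 4 Hz) an additional zero-phase low-pass is
    applied first, to test whether the diagnostic information is carried
    by low-frequency topographies.
    """
    fs = epochs.sampling_rate
    data = epochs.select().data
    meta = epochs.metadata.loc[epochs.retained].reset_index(drop=True)
    if lowpass_hz is not None:
        data = lowpass(data, fs, lowpass_hz, axis=2)
    half = int(round(window_ms / 2000.0 * fs))        # 20 samples for 200 ms
    step = int(round(step_ms / 1000.0 * fs))
    if step < 1 or abs(step - step_ms / 1000.0 * fs) > 1e-9:
        raise ValueError("step must be a whole number of samples")
    centers_t = np.round(np.arange(tmin, tmax + 1e-9, step_ms / 1000.0), 6)
    centers = np.searchsorted(np.round(epochs.times, 6), centers_t)
    if (centers - half < 0).any() or (centers + half >= data.shape[2]).any():
        raise ValueError("sliding window exceeds the epoch bounds")
    n_trials, n_ch, _ = data.shape
    wlen = 2 * half + 1
    feats = np.empty((n_trials, centers.size, n_ch * wlen))
    for k, c in enumerate(centers):
        feats[:, k, :] = data[:, :, c - half:c + half + 1].reshape(n_trials, -1)
    return FeatureSet(features=feats, times=centers_t, metadata=meta)


def similarity_matrix(features_t: np.ndarray) -> np.ndarray:
    """Trials x trials Spearman correlation matrix at one time point.

    Average ranks resolve ties. Zero-variance vectors produce NaN rows and
    columns with a warning.
    """
    x = np.asarray(features_t, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (trials, features) array with >= 2 trials")
    var = x.var(axis=1)
    ranks = stats.rankdata(x, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.corrcoef(ranks)
    if (var == 0).any():
        warnings.warn("zero-variance feature vector; its cells set to missing")
        bad = var == 0
        mat[bad, :] = np.nan
        mat[:, bad] = np.nan
    np.fill_diagonal(mat, 1.0)
    return mat


def pair_cells(metadata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index pairs of within- and between-category cells.

    Only object/scene (old-cue) trials enter; pairs sharing an adjective
    id (the same cue replayed in different rounds) are excluded.
    """
    cats = metadata["category"].to_numpy()
    adj = metadata["adjective_id"].to_numpy()
    old = np.isin(cats, ["object", "scene"])
    idx = np.flatnonzero(old)
    within, between = [], []
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            i, j = idx[a], idx[b]
            if adj[i] == adj[j]:
                continue
            if cats[i] == cats[j]:
                within.append((i, j))
            else:
                between.append((i, j))
    return np.array(within, int).reshape(-1, 2), np.array(between, int).reshape(-1, 2)


def within_between_series(feature_set: FeatureSet,
                          rng: np.random.Generator | int | None = 0
                          ) -> SimilaritySeries:
    """Within- and between-category similarity time courses for one subject.

    The majority cell class is sub-sampled once (same cells at every time
    point) to equate the number of within and between cells.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    meta = feature_set.metadata
    for cat in ("object", "scene"):
        if (meta["category"] == cat).sum() < 2:
            raise ValueError(f"need at least 2 trials of category {cat!r}")
    within, between = pair_cells(meta)
    n = min(len(within), len(between))
    if n == 0:
        raise ValueError("no usable similarity cells")
    if len(within) > n:
        within = within[rng.choice(len(within), n, replace=False)]
    if len(between) > n:
        between = between[rng.choice(len(between), n, replace=False)]

    n_times = feature_set.times.size
    w_r = np.empty(n_times)
    b_r = np.empty(n_times)
    for k in range(n_times):
        mat = similarity_matrix(feature_set.features[:, k, :])
        w_r[k] = np.nanmean(mat[within[:, 0], within[:, 1]])
        b_r[k] = np.nanmean(mat[between[:, 0], between[:, 1]])
    return SimilaritySeries(times=feature_set.times.copy(), within_r=w_r,
                            between_r=b_r, within_z=fisher_z(w_r),
                            between_z=fisher_z(b_r), n_cells=n)


@dataclass
class Distinctiveness:
    value: float
    window: tuple[float, float]


def distinctiveness(series: SimilaritySeries,
                    window: tuple[float, float] = BEHAVIOR_WINDOW
                    ) -> Distinctiveness:
    """1 minus mean raw between-category similarity over ``window``."""
    sel = (series.times >= window[0]) & (series.times <= window[1])
    if not sel.any():
        raise ValueError("empty distinctiveness window")
    return Distinctiveness(value=float(1.0 - np.nanmean(series.between_r[sel])),
                           window=window)


def brain_behavior_correlation(distinct: np.ndarray, benefit: np.ndarray
                               ) -> tuple[float, float]:
    """Spearman rank correlation between distinctiveness and cueing benefit."""
    distinct = np.asarray(distinct, float)
    benefit = np.asarray(benefit, float)
    if distinct.size != benefit.size or distinct.size < 5:
        raise ValueError("need matched samples from at least 5 subjects")
    rho, p = stats.spearmanr(distinct, benefit)
    if np.isnan(rho):
        raise ValueError("correlation undefined (constant input)")
    return float(rho), float(p)
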