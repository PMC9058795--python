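"""Song-trait derivation from syllable tables.

Three traits are analyzed per song: song length (SL, seconds), maximum
frequency (MF, the largest per-syllable mean frequency in the song, Hz) and
short-term complexity (distinct syllable types divided by the number of
syllables, in (0, 1]). Syllable types are k-means clusters over the five
spectro-acoustic features measured per syllable (duration, minimum and
maximum frequency, bandwidth, mean frequency); the field-standard
repertoire partition uses K=200 types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

FEATURE_COLUMNS = ("duration", "min_freq", "max_freq", "bandwidth", "mean_freq")
DEFAULT_K = 200


@dataclass
class SyllableTypeModel:
    """A fitted syllable-type partition (k-means over 5 features)."""

    K: int
    centroids: np.ndarray          # (K, 5)
    assignment: np.ndarray         # (N,) labels in [0, K)
    inertia: float
    standardized: bool = False
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.standardized:
            x = (x - self.feature_mean) / self.feature_scale
        d = ((x[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def fit_syllable_types(
    features: np.ndarray,
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = False,
) -> SyllableTypeModel:
    """Partition syllables into ``K`` types by k-means.

    Lloyd's algorithm with k-means++ initialization, best of ``n_restarts``
    by within-cluster sum of squares; deterministic for a given ``seed``.
    Features are used unscaled by default; set ``standardize=True`` to
    z-score each feature first.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D (N, 5) array")
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    n = x.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} syllables, got {n}")
    mean = scale = None
    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        x = (x - mean) / scale
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_restarts,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(x)
    return SyllableTypeModel(
        K=K,
        centroids=km.cluster_centers_,
        assignment=labels,
        inertia=float(km.inertia_),
        standardized=standardize,
        feature_mean=mean,
        feature_scale=scale,
    )


def complexity(type_labels) -> float:
    """Distinct syllable types divided by total syllables in one song."""
    labels = np.asarray(type_labels)
    if labels.size == 0:
        raise ValueError("complexity undefined for an empty song")
    return float(len(np.unique(labels)) / labels.size)


def max_frequency(mean_freqs) -> float:
    """Maximum of the per-syllable mean frequencies within one song (Hz)."""
    f = np.asarray(mean_freqs, dtype=float)
    if f.size == 0:
        raise ValueError("max_frequency undefined for an empty song")
    return float(f.max())


def song_length(onsets, durations) -> float:
    """Span from the first syllable onset to the last syllable offset (s)."""
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size == 0:
        raise ValueError("song_length undefined for an empty song")
    if not (np.isfinite(onsets).all() and np.isfinite(durations).all()):
        raise ValueError("onsets and durations must be finite")
    span = float((onsets + durations).max() - onsets.min())
    if span < 0:
        raise ValueError("negative song span")
    return span


def z_transform(x, allow_missing: bool = True) -> np.ndarray:
    """Center and scale to mean 0, SD 1 (n-1 denominator), preserving sign.

    Missing values (NaN) are preserved in place; the moments are computed
    over non-missing entries only.
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if not allow_missing and not finite.all():
        raise ValueError("missing values not allowed")
    vals = x[finite]
    if vals.size < 2:
        raise ValueError("need at least 2 non-missing values to z-transform")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot z-transform a constant vector")
    out = np.full_like(x, np.nan, dtype=float)
    out[finite] = (vals - vals.mean()) / sd
    return out


def derive_song_traits(
    syllables: pd.DataFrame,
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = False,
) -> pd.DataFrame:
    """Compute SL, MF and complexity per song from a syllable table.

    ``syllables`` needs columns ``song_id``, ``onset``, ``duration`` and the
    five features of :data:`FEATURE_COLUMNS`. ``K`` is capped at the number
    of syllables available. Returns one row per song_id.
    """
    required = {"song_id", "onset", "duration", *FEATURE_COLUMNS}
    missing = required - set(syllables.columns)
    if missing:
        raise ValueError(f"syllable table missing columns: {sorted(missing)}")
    feats = syllables[list(FEATURE_COLUMNS)].to_numpy(float)
    k_eff = min(K, len(syllables))
    model = fit_syllable_types(feats, K=k_eff, seed=seed, n_restarts=n_restarts,
                               standardize=standardize)
    tbl = syllables[["song_id", "onset", "duration", "mean_freq"]].copy()
    tbl["type"] = model.assignment
    rows = []
    for song_id, grp in tbl.groupby("song_id", sort=False):
        rows.append({
            "song_id": song_id,
            "SL": song_length(grp["onset"], grp["duration"]),
            "MF": max_frequency(grp["mean_freq"]),
            "complexity": complexity(grp["type"]),
        })
    return pd.DataFrame(rows)
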