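"""Offline gesture recognition from time-domain features and LDA.

The classical myocontrol pipeline: the 10 band-pass-filtered steady-state
segments of every gesture are concatenated (about 10 s per gesture), cut into
200 ms windows with 100 ms overlap, and each window is described per channel
by the four Hudgins time-domain features — mean absolute value (MAV), zero
crossings (ZC), slope-sign changes (SSC) and waveform length (WL).  A linear
discriminant classifier with Ledoit-Wolf shrinkage of the pooled covariance
(the feature dimension, 4 x 64 = 256, exceeds what a few hundred windows can
estimate without regularization) is evaluated with three-split Monte Carlo
cross-validation using stratified 70/30 train/test partitions.

By default feature windows never span the splice between two concatenated
1-s segments (9 windows per segment, 90 per gesture); a straddle mode slides
across the full concatenation (99 windows) for compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError

FEATURE_NAMES = ("MAV", "ZC", "SSC", "WL")


def concatenate_steady_segments(segments: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-repetition steady-state signal segments along time.

    Input segments are channels x samples slices of the band-pass-filtered
    raw signal, in repetition order.
    """
    if not segments:
        raise ParameterError("no steady-state segments to concatenate")
    n_ch = segments[0].shape[0]
    for i, seg in enumerate(segments):
        if seg.ndim != 2 or seg.shape[0] != n_ch:
            raise ParameterError(f"segment {i} has inconsistent channel count")
    return np.concatenate(segments, axis=-1)


def sliding_windows(
    x: np.ndarray, fs: float, window_s: float = 0.2, step_s: float = 0.1
) -> list[np.ndarray]:
    """Overlapping windows along the last axis (floor-based sample counts)."""
    w = int(window_s * fs)
    step = int(step_s * fs)
    if w < 2 or step < 1:
        raise ParameterError("window too short for the sampling rate")
    n = x.shape[-1]
    if n < w:
        return []
    starts = range(0, n - w + 1, step)
    return [x[..., s : s + w] for s in starts]


def extract_features(window: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Hudgins time-domain features of one channels x samples window.

    Returns a channel-major vector (MAV, ZC, SSC, WL per channel).  ``eps``
    is the dead-band: sign changes (ZC) and slope-sign changes (SSC) are only
    counted when the relevant excursion is at least ``eps``.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    d = np.diff(x, axis=-1)
    mav = np.abs(x).mean(axis=-1)
    wl = np.abs(d).sum(axis=-1)
    zc = ((x[:, :-1] * x[:, 1:] < 0) & (np.abs(d) >= eps)).sum(axis=-1)
    d1 = x[:, 1:-1] - x[:, :-2]
    d2 = x[:, 1:-1] - x[:, 2:]
    ssc = (
        (d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps)
    ).sum(axis=-1)
    return np.stack([mav, zc, ssc, wl], axis=1).reshape(-1)


def features_from_segments(
    segments: list[np.ndarray],
    fs: float,
    window_s: float = 0.2,
    step_s: float = 0.1,
    eps: float = 0.0,
    straddle: bool = False,
) -> np.ndarray:
    """Feature matrix (windows x 4*n_channels) for one gesture's segments."""
    if straddle:
        sources = [concatenate_steady_segments(segments)]
    else:
        sources = segments
    rows = []
    for src in sources:
        for win in sliding_windows(src, fs, window_s, step_s):
            rows.append(extract_features(win, eps))
    if not rows:
        raise ParameterError("segments too short to produce any feature window")
    return np.stack(rows)


def train_lda(features: np.ndarray, labels: np.ndarray) -> Pipeline:
    """Fit the shrinkage-LDA classifier (features z-scored on the training set).

    Requires at least two classes with at least two samples each; the
    Ledoit-Wolf shrinkage keeps training well-posed even for singular pooled
    covariances (e.g. duplicated feature columns).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ParameterError("training requires at least two classes")
    thin = classes[counts < 2]
    if thin.size:
        raise ParameterError(f"classes with fewer than two samples: {thin.tolist()}")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("lda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
        ]
    )
    model.fit(np.asarray(features, dtype=np.float64), labels)
    return model


@dataclass
class CVResult:
    """Monte Carlo cross-validation outcome."""

    split_accuracies: list[float]
    mean_accuracy: float
    confusions: list[np.ndarray]
    class_labels: list
    train_fraction: float = 0.7
    seed: int = 0

    def accuracy_from_confusion(self) -> float:
        """Mean accuracy recomputed from the stored confusion matrices."""
        accs = [np.trace(c) / c.sum() for c in self.confusions]
        return float(np.mean(accs))


def monte_carlo_cv(
    features: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 3,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified random 70/30 partitions; accuracy averaged over splits."""
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed
    )
    accs, confusions = [], []
    for train_idx, test_idx in splitter.split(features, labels):
        model = train_lda(features[train_idx], labels[train_idx])
        pred = model.predict(features[test_idx])
        conf = confusion_matrix(labels[test_idx], pred, labels=classes)
        confusions.append(conf)
        accs.append(float(np.trace(conf) / conf.sum()))
    return CVResult(
        split_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusions=confusions,
        class_labels=classes.tolist(),
        train_fraction=train_fraction,
        seed=seed,
    )


def accuracy_vs_gesture_count(
    features_by_gesture: dict[str, np.ndarray],
    gesture_order: list[str] | None = None,
    seed: int = 0,
    n_splits: int = 3,
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """Mean CV accuracy as the first k gestures are included, k = 2..n.

    Returns a long table (k, split, accuracy, mean_accuracy).  Single-class
    problems (k = 1) are degenerate and excluded.
    """
    order = list(gesture_order) if gesture_order is not None else list(features_by_gesture)
    if len(order) < 2:
        raise ParameterError("need at least two gestures")
    rows = []
    for k in range(2, len(order) + 1):
        x = np.concatenate([features_by_gesture[g] for g in order[:k]])
        y = np.concatenate(
            [np.full(len(features_by_gesture[g]), g) for g in order[:k]]
        )
        res = monte_carlo_cv(x, y, n_splits=n_splits, train_fraction=train_fraction, seed=seed)
        for split, acc in enumerate(res.split_accuracies):
            rows.append(
                {"k": k, "split": split, "accuracy": acc, "mean_accuracy": res.mean_accuracy}
            )
    return pd.DataFrame(rows)
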