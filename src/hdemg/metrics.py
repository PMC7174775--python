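"""Repeatability, gesture similarity, dimensionality and activation summaries.

Repeatability and inter-gesture similarity are squared Pearson correlations
between heatmaps reshaped to 1 x 64 vectors (45 unique pairs among 10
repetitions; 21 among 7 gestures).  Dimensionality is the number of principal
components whose cumulative variance explained exceeds 90%, computed on the
64 x 70 concatenation of all repetition heatmaps: the 70 gesture-repetition
vectors are the variables (columns, mean-centred) and the 64 electrodes the
observations — the orientation under which the centred matrix has at most 63
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .errors import ParameterError, ZeroVarianceError
from .heatmap import Heatmap


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of squared Pearson coefficients with unit diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParameterError("similarity matrix shape must match labels")

    @property
    def n_unique_pairs(self) -> int:
        return comb(len(self.labels), 2)

    def pair_values(self) -> np.ndarray:
        """The upper-triangle coefficients (one per unordered pair)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _r_squared_matrix(vectors: np.ndarray, labels: list, what: str) -> SimilarityMatrix:
    sds = vectors.std(axis=1)
    means = vectors.mean(axis=1)
    for i, (sd, mu) in enumerate(zip(sds, means)):
        if sd <= 1e-12 * max(1.0, abs(mu)):
            raise ZeroVarianceError(
                f"{what} {labels[i]!r} has zero variance across its cells; "
                "Pearson correlation is undefined"
            )
    r = np.corrcoef(vectors)
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    r2 = (r2 + r2.T) / 2
    return SimilarityMatrix(labels=list(labels), values=r2)


def repeatability(maps: list[Heatmap]) -> SimilarityMatrix:
    """R^2 between every unordered pair of repetition heatmaps of one gesture."""
    if len(maps) < 2:
        raise ParameterError("repeatability requires at least two heatmaps")
    vectors = np.stack([m.vector() for m in maps])
    labels = [m.repetition_index for m in maps]
    return _r_squared_matrix(vectors, labels, "repetition")


def gesture_similarity(avg_maps: list[Heatmap]) -> SimilarityMatrix:
    """R^2 between the gesture-average heatmaps of one participant."""
    if len(avg_maps) < 2:
        raise ParameterError("gesture_similarity requires at least two gestures")
    vectors = np.stack([m.vector() for m in avg_maps])
    labels = [m.gesture_label for m in avg_maps]
    return _r_squared_matrix(vectors, labels, "gesture")


def average_similarity(matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of similarity matrices (group-level matrix)."""
    if not matrices:
        raise ParameterError("average_similarity requires at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ParameterError("similarity matrices have mismatched labels")
    return SimilarityMatrix(labels, np.mean([m.values for m in matrices], axis=0))


@dataclass
class DimensionalityResult:
    """Variance-explained spectrum and the >90% component count."""

    ve: np.ndarray
    cumulative_ve: np.ndarray
    n_pcs_90: int
    ve_threshold: float = 0.9


def pca_dimensionality(
    maps: list[Heatmap],
    ve_threshold: float = 0.9,
    electrodes_as_observations: bool = True,
) -> DimensionalityResult:
    """PCA of the electrode x gesture-repetition heatmap concatenation.

    With the default orientation the heatmap vectors are the variables
    (columns, mean-centred over the 64 electrode observations).  The flag
    transposes the matrix so electrodes become the variables.
    """
    if len(maps) < 2:
        raise ParameterError("pca_dimensionality requires at least two heatmaps")
    if not 0 < ve_threshold < 1:
        raise ParameterError("ve_threshold must be in (0, 1)")
    x = np.stack([m.vector() for m in maps], axis=1)  # 64 x n_maps
    if not electrodes_as_observations:
        x = x.T
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    power = s * s
    total = power.sum()
    if total <= 0:
        raise ZeroVarianceError("all heatmaps identical after centering; PCA undefined")
    ve = power / total
    cum = np.cumsum(ve)
    cum[-1] = 1.0  # guard against float drift in the invariant cum[-1] == 1
    n90 = int(np.argmax(cum > ve_threshold)) + 1
    return DimensionalityResult(ve=ve, cumulative_ve=cum, n_pcs_90=n90, ve_threshold=ve_threshold)


def activation_summary(activations: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of per-repetition maximal activations.

    ``activations`` must hold one row per (participant, gesture, repetition)
    with columns ``group``, ``max_normalized`` and ``max_absolute``.
    """
    required = {"group", "max_normalized", "max_absolute"}
    missing = required - set(activations.columns)
    if missing:
        raise ParameterError(f"activation table missing columns: {sorted(missing)}")
    out = activations.groupby("group").agg(
        n=("max_normalized", "size"),
        mean_max_normalized=("max_normalized", "mean"),
        sd_max_normalized=("max_normalized", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_max_absolute=("max_absolute", "mean"),
        sd_max_absolute=("max_absolute", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
    )
    return out.reset_index()
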