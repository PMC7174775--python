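"""Activation heatmaps and center-of-gravity spatial statistics.

A repetition heatmap holds, for each electrode, the mean envelope over the
middle-second steady-state window of one contraction, arranged on the 8x8
grid; the per-gesture map is the cell-wise mean of the 10 repetition maps.
The center of gravity (COG) is the amplitude-weighted centroid of the cells
at or above 80% of the map maximum.  Because the rows encircle the forearm,
the row coordinate is a circular (angular) mean by default; a planar fallback
is provided for compatibility with grid-on-a-plane conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedCOGError
from .grid import Anthropometrics, ElectrodeGrid
from .preprocess import EnvelopeSet, NormalizationFactors


@dataclass
class Heatmap:
    """8x8 non-negative amplitude map for one repetition or a gesture average."""

    values: np.ndarray
    kind: str  # "normalized" | "absolute"
    gesture_label: str = ""
    repetition_index: int | str = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("heatmap values must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ParameterError("heatmap values must be non-negative")
        if self.kind not in ("normalized", "absolute"):
            raise ParameterError(f"kind must be 'normalized' or 'absolute', got {self.kind!r}")

    def vector(self) -> np.ndarray:
        """The map reshaped to a 1 x 64 vector (row-major)."""
        return self.values.reshape(-1)


@dataclass
class CenterOfGravity:
    """Thresholded amplitude-weighted centroid, in grid and physical coordinates.

    ``COGx`` is the circumferential position as % of forearm circumference,
    ``COGy`` the longitudinal position as % of forearm length from the elbow.
    """

    grid_coords: tuple[float, float]
    cog_x_pct: float
    cog_y_pct: float | None
    threshold_used: float
    n_cells_included: int


def build_repetition_heatmap(
    env: EnvelopeSet,
    steady_window: tuple[int, int],
    factors: NormalizationFactors,
    grid: ElectrodeGrid,
    gesture_label: str = "",
    repetition_index: int = 0,
) -> tuple[Heatmap, Heatmap]:
    """Normalized and absolute heatmaps for one steady-state window.

    Each cell is the mean over the window of the (normalized | absolute)
    envelope of the channel mapped to that cell.
    """
    i0, i1 = steady_window
    if not 0 <= i0 < i1 <= env.n_samples:
        raise ParameterError(f"steady window {steady_window} outside recording")
    mean_abs = env.envelopes[:, i0:i1].mean(axis=-1)
    mean_norm = mean_abs / factors.factors
    abs_map = Heatmap(grid.map_channels(mean_abs), "absolute", gesture_label, repetition_index)
    norm_map = Heatmap(grid.map_channels(mean_norm), "normalized", gesture_label, repetition_index)
    return norm_map, abs_map


def average_heatmap(maps: list[Heatmap]) -> Heatmap:
    """Cell-wise arithmetic mean of repetition heatmaps; kind is preserved."""
    if not maps:
        raise ParameterError("average_heatmap requires at least one map")
    kinds = {m.kind for m in maps}
    if len(kinds) != 1:
        raise ParameterError(f"cannot average maps of mixed kinds {kinds}")
    values = np.mean([m.values for m in maps], axis=0)
    return Heatmap(values, maps[0].kind, maps[0].gesture_label, "average")


def _circular_row_centroid(rows: np.ndarray, weights: np.ndarray, n_rows: int) -> float:
    ang = 2 * np.pi * rows / n_rows
    x = float((weights * np.cos(ang)).sum())
    y = float((weights * np.sin(ang)).sum())
    if math.hypot(x, y) < 1e-12 * weights.sum():
        # symmetric around the cylinder: fall back to the planar mean
        return float((weights * rows).sum() / weights.sum())
    rc = (math.atan2(y, x) * n_rows / (2 * np.pi)) % n_rows
    return ((rc + 0.5) % n_rows) - 0.5


def compute_cog(
    heatmap: Heatmap,
    grid: ElectrodeGrid,
    anthropometrics: Anthropometrics | None = None,
    threshold: float = 0.8,
    circular_rows: bool = True,
) -> CenterOfGravity:
    """COG over cells with value >= threshold x map maximum (ties included).

    The row (circumferential) centroid is a weighted circular mean by
    default; ``circular_rows=False`` selects the planar convention.  Physical
    coordinates: a cell centre in row i sits at (i + 0.5) * CID along the
    circumference; in column j at ``start_offset_fraction`` of the forearm
    length plus (j + 0.5) * LID from the elbow.
    """
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    values = heatmap.values
    vmax = values.max()
    if vmax <= 0:
        raise UndefinedCOGError("COG undefined for an all-zero heatmap")
    mask = values >= threshold * vmax
    rows, cols = np.nonzero(mask)
    w = values[rows, cols].astype(np.float64)
    total = w.sum()
    col_c = float((w * cols).sum() / total)
    if circular_rows:
        row_c = _circular_row_centroid(rows.astype(np.float64), w, grid.n_rows)
    else:
        row_c = float((w * rows).sum() / total)
    cog_x = (row_c + 0.5) / grid.n_rows * 100.0
    cog_y = None
    if anthropometrics is not None:
        length = anthropometrics.forearm_length_cm
        y_cm = (
            anthropometrics.start_offset_fraction * length
            + col_c * grid.lid_cm
            + grid.lid_cm / 2
        )
        cog_y = y_cm / length * 100.0
    return CenterOfGravity(
        grid_coords=(row_c, col_c),
        cog_x_pct=cog_x,
        cog_y_pct=cog_y,
        threshold_used=threshold,
        n_cells_included=int(mask.sum()),
    )


def max_activation(map_norm: Heatmap, map_abs: Heatmap) -> tuple[float, float]:
    """Cell-wise maxima of the normalized and absolute heatmaps."""
    return float(map_norm.values.max()), float(map_abs.values.max())
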