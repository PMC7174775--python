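"""Electrode grid geometry for the cylindrical 8x8 forearm array.

The 64 monopolar electrodes are arranged in 8 circumferential rows of 8
electrodes each.  Channels 1-8 fill the first row from proximal to distal,
starting just dorsal of the line connecting the lateral epicondyle and the
styloid process of the ulna; successive rows proceed counterclockwise as seen
looking at a right arm, so channels 1-32 cover the dorsal and 33-64 the
ventral side.  The longitudinal inter-electrode distance (LID) is fixed at
2 cm; the circumferential distance (CID) is the forearm circumference divided
by the 8 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Fixed longitudinal inter-electrode distance in cm.
LID_CM = 2.0


@dataclass(frozen=True)
class Anthropometrics:
    """Forearm measurements that anchor the grid to physical coordinates.

    ``start_offset_fraction`` is the fraction of forearm length (from the
    elbow) at which the first, most proximal electrode column sits.
    """

    forearm_length_cm: float
    circumference_cm: float
    start_offset_fraction: float = 0.20
    handedness: str = "right"

    def __post_init__(self):
        if self.forearm_length_cm <= 0 or self.circumference_cm <= 0:
            raise ParameterError("forearm length and circumference must be positive")
        if self.handedness not in ("right", "left"):
            raise ParameterError(f"handedness must be 'right' or 'left', got {self.handedness!r}")


@dataclass(frozen=True)
class ElectrodeGrid:
    """Bijection between channel indices 1..64 and (row, column) grid cells.

    Rows index the circumferential direction (wrapping around the forearm),
    columns the longitudinal (proximal -> distal) direction.  For left arms
    the circumferential direction is mirrored so that the counterclockwise
    convention defined for a right arm is preserved in the mirrored frame.
    """

    n_rows: int = 8
    n_cols: int = 8
    lid_cm: float = LID_CM
    cid_cm: float = 3.0
    handedness: str = "right"
    start_offset_fraction: float = field(default=0.20)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def _physical_row(self, row: int) -> int:
        # Mirror the circumferential direction for left arms; row 0 stays put.
        if self.handedness == "left":
            return (-row) % self.n_rows
        return row

    def channel_of(self, row: int, col: int) -> int:
        """1-based channel number of grid cell (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ParameterError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return self._physical_row(row) * self.n_cols + col + 1

    def position_of(self, channel: int) -> tuple[int, int]:
        """(row, col) of a 1-based channel number."""
        if not (1 <= channel <= self.n_channels):
            raise ParameterError(f"channel {channel} outside 1..{self.n_channels}")
        row, col = divmod(channel - 1, self.n_cols)
        if self.handedness == "left":
            row = (-row) % self.n_rows
        return row, col

    def map_channels(self, per_channel: np.ndarray) -> np.ndarray:
        """Arrange a length-64 per-channel vector as an (n_rows, n_cols) matrix."""
        per_channel = np.asarray(per_channel)
        if per_channel.shape[0] != self.n_channels:
            raise ParameterError(
                f"expected {self.n_channels} channel values, got {per_channel.shape[0]}"
            )
        out = np.empty((self.n_rows, self.n_cols), dtype=per_channel.dtype)
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                out[r, c] = per_channel[self.channel_of(r, c) - 1]
        return out

    def channel_values(self, grid_matrix: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`map_channels`: flatten a grid matrix to channel order."""
        grid_matrix = np.asarray(grid_matrix)
        if grid_matrix.shape != (self.n_rows, self.n_cols):
            raise ParameterError(f"expected {(self.n_rows, self.n_cols)} matrix")
        out = np.empty(self.n_channels, dtype=grid_matrix.dtype)
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                out[self.channel_of(r, c) - 1] = grid_matrix[r, c]
        return out

    def neighbors(self, row: int, col: int) -> list[tuple[int, int]]:
        """8-neighborhood of a cell: rows wrap circumferentially, columns clip.

        Cells at the longitudinal extremes (first/last column) therefore have
        5 neighbors instead of 8.
        """
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r = (row + dr) % self.n_rows
                c = col + dc
                if 0 <= c < self.n_cols:
                    out.append((r, c))
        return out


def grid_from_anthropometrics(
    forearm_length_cm: float,
    circumference_cm: float,
    handedness: str = "right",
    start_offset_fraction: float = 0.20,
) -> ElectrodeGrid:
    """Build the 8x8 grid for a participant.

    LID is fixed at 2 cm; CID is the circumference divided by the 8
    circumferential rows (e.g. a 27 cm forearm gives CID 3.375 cm).
    """
    anth = Anthropometrics(
        forearm_length_cm, circumference_cm, start_offset_fraction, handedness
    )
    return ElectrodeGrid(
        cid_cm=anth.circumference_cm / 8,
        handedness=anth.handedness,
        start_offset_fraction=start_offset_fraction,
    )
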