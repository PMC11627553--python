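"""Electrode-grid geometry and montage mappings.

High-density surface-EMG grids are rectangular arrays of electrodes
(typically 13 rows x 5 columns with one corner electrode absent) recorded
in a monopolar montage. Columns run along the muscle-fibre direction, so
single-differential (SD) derivations are computed between adjacent rows
within each column. Multiple grids are laid side by side over the muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: grid-local (row, col) of the absent corner electrode, when present
ABSENT_CORNER = (0, 0)


@dataclass(frozen=True)
class GridGeometry:
    """Layout of one or more HD-EMG electrode grids.

    Parameters
    ----------
    n_rows, n_cols
        Electrode rows and columns per grid; rows run along the fibre
        (column) direction.
    ied_mm
        Inter-electrode distance in millimetres (4 mm or 8 mm grids are
        the common commercial variants).
    absent_corner
        Whether each grid is missing its corner electrode (row 0, col 0).
    n_grids
        Number of identical grids placed side by side.
    grid_gap_mm
        Extra spacing between the last column of one grid and the first
        column of the next.
    """

    n_rows: int = 13
    n_cols: int = 5
    ied_mm: float = 4.0
    absent_corner: bool = True
    n_grids: int = 1
    grid_gap_mm: float = field(default=8.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_grids < 1:
            raise ValueError("grid dimensions must be positive")
        if self.ied_mm <= 0:
            raise ValueError("inter-electrode distance must be positive")

    @property
    def electrodes_per_grid(self) -> int:
        return self.n_rows * self.n_cols - (1 if self.absent_corner else 0)

    @property
    def n_channels(self) -> int:
        """Total monopolar channels across all grids."""
        return self.electrodes_per_grid * self.n_grids

    def is_present(self, row: int, col: int) -> bool:
        return not (self.absent_corner and (row, col) == ABSENT_CORNER)

    def channel_index(self, grid: int, row: int, col: int) -> int | None:
        """Monopolar channel index of an electrode, or None if absent.

        Channels are enumerated grid by grid, column-major within a grid
        (column 0 rows 0..n_rows-1, then column 1, ...), skipping the
        absent corner.
        """
        if not (0 <= grid < self.n_grids and 0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError("electrode coordinates out of range")
        if not self.is_present(row, col):
            return None
        idx = grid * self.electrodes_per_grid
        for c in range(col):
            idx += self.n_rows - (1 if (self.absent_corner and c == ABSENT_CORNER[1]) else 0)
        rows_before = row
        if self.absent_corner and col == ABSENT_CORNER[1] and row > ABSENT_CORNER[0]:
            rows_before -= 1
        return idx + rows_before

    def electrode_positions(self) -> np.ndarray:
        """(n_channels, 2) electrode positions in mm: x across columns/grids, y along rows."""
        pos = np.empty((self.n_channels, 2))
        for g in range(self.n_grids):
            x0 = g * ((self.n_cols - 1) * self.ied_mm + self.grid_gap_mm + self.ied_mm)
            for c in range(self.n_cols):
                for r in range(self.n_rows):
                    ch = self.channel_index(g, r, c)
                    if ch is not None:
                        pos[ch] = (x0 + c * self.ied_mm, r * self.ied_mm)
        return pos

    def sd_pairs(self) -> list[tuple[int, int]]:
        """Single-differential derivations along the column direction.

        Each pair (a, b) yields SD channel ``signal[a] - signal[b]`` for
        adjacent rows within a column; pairs touching the absent corner
        electrode are dropped. Four 13x5-minus-corner grids give 236 SD
        channels.
        """
        pairs: list[tuple[int, int]] = []
        for g in range(self.n_grids):
            for c in range(self.n_cols):
                for r in range(self.n_rows - 1):
                    a = self.channel_index(g, r + 1, c)
                    b = self.channel_index(g, r, c)
                    if a is not None and b is not None:
                        pairs.append((a, b))
        return pairs

    @property
    def n_sd_channels(self) -> int:
        return len(self.sd_pairs())
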