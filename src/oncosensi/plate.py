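"""Geometry of the 384-pillar plate.

The screening plate is a 16 x 24 grid of pillars; each pillar carries one
organoid dome and maps onto a rectangular tile of the scanned image.
Viability is read out either per pillar or aggregated over consecutive
"strips" of pillars within a row (8 pillars per strip by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_ROWS = 16
N_COLS = 24
N_PILLARS = N_ROWS * N_COLS


@dataclass(frozen=True)
class PlateLayout:
    """Maps pillar grid coordinates onto pixel regions of a plate scan.

    The image is divided into ``n_rows x n_cols`` equal rectangular tiles;
    pillar (r, c) owns tile (r, c).  ``strip_size`` pillars along a row form
    one quantification strip, enumerated row-major.
    """

    n_rows: int = N_ROWS
    n_cols: int = N_COLS
    image_shape: tuple[int, int] = (640, 960)
    strip_size: int = 8

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols != N_PILLARS:
            raise ValueError(
                f"plate must have {N_PILLARS} pillars, got {self.n_rows}x{self.n_cols}"
            )
        if self.n_cols % self.strip_size != 0:
            raise ValueError("strip_size must divide the number of columns")
        h, w = self.image_shape
        if h < self.n_rows or w < self.n_cols:
            raise ValueError("image too small to hold the pillar grid")

    @property
    def tile_shape(self) -> tuple[float, float]:
        return (self.image_shape[0] / self.n_rows, self.image_shape[1] / self.n_cols)

    @property
    def strips_per_row(self) -> int:
        return self.n_cols // self.strip_size

    @property
    def n_strips(self) -> int:
        return self.n_rows * self.strips_per_row

    def pillar_slice(self, row: int, col: int) -> tuple[slice, slice]:
        """Pixel-index slices of the tile owned by pillar (row, col)."""
        th, tw = self.tile_shape
        r0, r1 = int(round(row * th)), int(round((row + 1) * th))
        c0, c1 = int(round(col * tw)), int(round((col + 1) * tw))
        return slice(r0, r1), slice(c0, c1)

    def pillar_center(self, row: int, col: int) -> tuple[float, float]:
        th, tw = self.tile_shape
        return ((row + 0.5) * th, (col + 0.5) * tw)

    def strip_index(self, row: int, col: int) -> int:
        """Row-major strip id of pillar (row, col)."""
        return row * self.strips_per_row + col // self.strip_size

    def strip_pillars(self, strip: int) -> list[tuple[int, int]]:
        row, block = divmod(strip, self.strips_per_row)
        c0 = block * self.strip_size
        return [(row, c0 + k) for k in range(self.strip_size)]

    def pillar_map(self) -> np.ndarray:
        """Integer image labelling every pixel with its pillar id (row*n_cols+col)."""
        h, w = self.image_shape
        rows = np.minimum((np.arange(h) * self.n_rows) // h, self.n_rows - 1)
        cols = np.minimum((np.arange(w) * self.n_cols) // w, self.n_cols - 1)
        return rows[:, None] * self.n_cols + cols[None, :]
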