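"""Hexagonal cell lattice: side indexing, cell-cell apposition, side adjacency.

Each cell is a hexagon with sides numbered 1..6 clockwise starting from the
anterior-facing diagonal: 1 = up-left, 2 = left, 3 = down-left, 4 = down-right,
5 = right, 6 = up-right.  Side j of a cell is apposed to side ((j+2) mod 6)+1
of the neighbouring cell (1<->4, 2<->5, 3<->6), so a protein pool sitting on
side 5 of one cell faces the pool on side 2 of the cell to its right.

The lattice is periodic (toroidal) in both directions.  For a single-row grid
the four diagonal neighbours wrap back into the row: sides 1-3 all face the
left column neighbour and sides 4-6 the right one, which preserves both the
apposition involution and the one-dimensional periodic stripe geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridTopology", "make_grid", "adjacent_sides", "apposed_side"]

#: axial-coordinate (row, col) offsets per 1-based side, used for n_rows > 1
_AXIAL_OFFSETS = {
    1: (-1, 0),   # up-left
    2: (0, -1),   # left
    3: (1, -1),   # down-left
    4: (1, 0),    # down-right
    5: (0, 1),    # right
    6: (-1, 1),   # up-right
}


def apposed_side(side: int) -> int:
    """The side index facing ``side`` on the apposed neighbour (1<->4, 2<->5, 3<->6)."""
    _check_side(side)
    return ((side + 2) % 6) + 1


def adjacent_sides(side: int) -> tuple[int, int]:
    """The two sides cyclically adjacent to ``side`` within the same membrane.

    A membrane pool exchanges material only with the pools on these two sides
    (e.g. the pool on side 5 with those on sides 4 and 6).
    """
    _check_side(side)
    return ((side % 6) + 1, ((side + 4) % 6) + 1)


def _check_side(side: int) -> None:
    if not isinstance(side, (int, np.integer)) or not 1 <= side <= 6:
        raise ValueError(f"side must be an integer in 1..6, got {side!r}")


@dataclass(frozen=True)
class GridTopology:
    """Periodic hexagonal lattice of ``n_rows`` x ``n_cols`` six-sided cells."""

    n_rows: int
    n_cols: int
    boundary: str = "periodic"
    #: neighbour cell index for (cell, side): shape (n_cells, 6), 0-based sides
    neighbor_cell: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def cell_id(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_cols)

    def apposed(self, cell: tuple[int, int], side: int) -> tuple[tuple[int, int], int]:
        """Return ((row, col), side) of the membrane patch facing ``(cell, side)``."""
        _check_side(side)
        idx = self.cell_index(*cell)
        nb = int(self.neighbor_cell[idx, side - 1])
        return self.cell_id(nb), apposed_side(side)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "boundary": self.boundary,
                "neighbor_cell": self.neighbor_cell.tolist(),
            }
        )


def make_grid(n_rows: int, n_cols: int) -> GridTopology:
    """Build a periodic hexagonal grid topology.

    A 1 x 4 row is the canonical configuration for the four-cell parasegment
    repeat; larger grids are supported generically.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {n_rows}x{n_cols}")
    n_cells = n_rows * n_cols
    neighbor = np.empty((n_cells, 6), dtype=np.int64)
    for r in range(n_rows):
        for c in range(n_cols):
            idx = r * n_cols + c
            for side in range(1, 7):
                if n_rows == 1:
                    dc = -1 if side in (1, 2, 3) else 1
                    nr, nc = 0, (c + dc) % n_cols
                else:
                    dr, dc = _AXIAL_OFFSETS[side]
                    nr, nc = (r + dr) % n_rows, (c + dc) % n_cols
                neighbor[idx, side - 1] = nr * n_cols + nc
    topo = GridTopology(n_rows=n_rows, n_cols=n_cols, neighbor_cell=neighbor)
    _check_involution(topo)
    return topo


def _check_involution(topo: GridTopology) -> None:
    for idx in range(topo.n_cells):
        cell = topo.cell_id(idx)
        for side in range(1, 7):
            nb, ns = topo.apposed(cell, side)
            back, bs = topo.apposed(nb, ns)
            if back != cell or bs != side:
                raise AssertionError(
                    f"apposition is not an involution at cell {cell} side {side}"
                )
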