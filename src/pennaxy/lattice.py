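"""Torus square lattice with distance-limited neighborhood queries.

The habitat is a ``side x side`` grid with opposite edges identified; each
cell holds at most one individual.  Distance is toroidal Chebyshev (a square
neighborhood of half-width D), matching the square partner-search and
child-placement ranges of the model.  Offsets are deduplicated under
wraparound, so ranges of side/2 or more simply cover the whole torus.

The engine's jitted kernels and this class share the same neighbor-offset
tables, so there is a single definition of the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional

import numpy as np

from .errors import InvariantViolation, StateCorruptionError

__all__ = ["Lattice", "Individual", "toroidal_distance", "neighbor_table",
           "chebyshev_offsets"]


def toroidal_distance(side: int, a: tuple[int, int], b: tuple[int, int]) -> int:
    """Chebyshev distance on the torus."""
    dr = abs(a[0] - b[0]) % side
    dc = abs(a[1] - b[1]) % side
    dr = min(dr, side - dr)
    dc = min(dc, side - dc)
    return max(dr, dc)


@lru_cache(maxsize=None)
def chebyshev_offsets(side: int, range_d: int) -> tuple[tuple[int, int], ...]:
    """Distinct nonzero (dr, dc) offsets within Chebyshev distance range_d.

    Wrapped duplicates are merged, so for 2*range_d + 1 >= side the result is
    every cell of the torus except the origin.
    """
    if range_d <= 0:
        raise InvariantViolation("range_d must be positive")
    offs = set()
    for dr in range(-range_d, range_d + 1):
        for dc in range(-range_d, range_d + 1):
            o = (dr % side, dc % side)
            if o != (0, 0):
                offs.add(o)
    return tuple(sorted(offs))


@lru_cache(maxsize=None)
def neighbor_table(side: int, range_d: int) -> np.ndarray:
    """int32[(side*side, n_offsets)] flat cell ids of each cell's neighborhood."""
    offs = np.array(chebyshev_offsets(side, range_d), np.int64)
    cells = np.arange(side * side)
    r = cells // side
    c = cells % side
    rows = (r[:, None] + offs[None, :, 0]) % side
    cols = (c[:, None] + offs[None, :, 1]) % side
    tab = (rows * side + cols).astype(np.int32)
    tab.setflags(write=False)
    return tab


@dataclass
class Individual:
    """A living individual as seen by the lattice and statistics layers."""

    id: int
    sex: str  # 'male' | 'female'
    age: int
    genome: object = None
    cum_defects: int = 0
    xy_modifier: float = 0.0
    partner_id: Optional[int] = None
    position: Optional[tuple[int, int]] = None


class Lattice:
    """At most one occupant per cell; occupant positions kept consistent."""

    def __init__(self, side: int = 128):
        if side <= 0:
            raise InvariantViolation("lattice side must be positive")
        self.side = int(side)
        self._cells: list[object] = [None] * (self.side * self.side)
        self._pos: dict[int, int] = {}  # id(occupant-key) -> flat cell

    def _flat(self, pos: tuple[int, int]) -> int:
        r, c = pos
        if not (0 <= r < self.side and 0 <= c < self.side):
            raise InvariantViolation(f"cell {pos} outside {self.side}x{self.side} lattice")
        return r * self.side + c

    def __len__(self) -> int:
        return len(self._pos)

    def occupant(self, pos: tuple[int, int]):
        return self._cells[self._flat(pos)]

    def position_of(self, ind) -> tuple[int, int]:
        flat = self._pos[id(ind)]
        return divmod(flat, self.side)

    def place(self, ind, pos: tuple[int, int]) -> None:
        flat = self._flat(pos)
        if self._cells[flat] is not None:
            raise StateCorruptionError(f"cell {pos} already occupied")
        if id(ind) in self._pos:
            raise StateCorruptionError("individual already placed")
        self._cells[flat] = ind
        self._pos[id(ind)] = flat
        if hasattr(ind, "position"):
            ind.position = pos

    def remove(self, ind) -> None:
        flat = self._pos.pop(id(ind), None)
        if flat is None:
            raise StateCorruptionError("individual not present on the lattice")
        self._cells[flat] = None
        if hasattr(ind, "position"):
            ind.position = None

    def neighbors_within(self, pos: tuple[int, int], range_d: int,
                         predicate: Callable | None = None) -> list:
        """Occupants within toroidal Chebyshev distance range_d of pos (pos excluded)."""
        flat = self._flat(pos)
        out = []
        for nb in neighbor_table(self.side, range_d)[flat]:
            occ = self._cells[nb]
            if occ is not None and (predicate is None or predicate(occ)):
                out.append(occ)
        return out

    def free_cells_within(self, pos: tuple[int, int], range_d: int) -> list[tuple[int, int]]:
        """Unoccupied cells within range_d of pos (pos itself excluded)."""
        flat = self._flat(pos)
        return [divmod(int(nb), self.side)
                for nb in neighbor_table(self.side, range_d)[flat]
                if self._cells[nb] is None]
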