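"""Discrete 2-D grid geometry: movement, vision, regions, placement.

Distances are Chebyshev (``max(|dx|, |dy|)``): with 8-directional
single-cell moves the number of steps between two cells equals their
Chebyshev distance, so a vision bound "< 2" means the 3x3 neighborhood
and "< 4" the 7x7 neighborhood.

The 12x12 predator-prey grid is partitioned into nine 4x4 regions
numbered row-major 0..8: region 0 is the top-left block, region 8 the
bottom-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional

import numpy as np

__all__ = [
    "Cell",
    "GridSpec",
    "AgentState",
    "distance",
    "step_toward",
    "random_step",
    "region_of",
    "region_center",
    "region_cells",
    "place_in_region",
    "random_step_in_region",
    "place_predator",
    "REGION_SIZE",
    "N_REGIONS",
]

REGION_SIZE = 4
REGIONS_PER_SIDE = 3
N_REGIONS = REGIONS_PER_SIDE * REGIONS_PER_SIDE

# 8 cardinal/diagonal unit moves
_DIRECTIONS = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]


class Cell(NamedTuple):
    x: int
    y: int


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid; flat cell index = y * width + x."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def in_bounds(self, cell: Cell) -> bool:
        return 0 <= cell.x < self.width and 0 <= cell.y < self.height

    def cell_index(self, cell: Cell) -> int:
        return cell.y * self.width + cell.x

    def cell_at(self, index: int) -> Cell:
        return Cell(index % self.width, index // self.width)


@dataclass
class AgentState:
    """Mutable per-hour state of one agent."""

    position: Cell
    vision_radius: int  # exclusive Chebyshev bound
    role: str = "cuttlefish"  # "cuttlefish" | "predator"
    hidden: bool = False
    done_for_hour: bool = False

    def __post_init__(self) -> None:
        if self.hidden and self.role != "cuttlefish":
            raise ValueError("only the cuttlefish can hide")

    def sees(self, other: Cell) -> bool:
        return distance(self.position, other) < self.vision_radius


def distance(a: Cell, b: Cell) -> int:
    """Chebyshev distance: steps needed with 8-directional moves."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def step_toward(pos: Cell, target: Cell) -> Cell:
    """One greedy 8-directional step: sign of the delta on each axis."""
    dx = target[0] - pos[0]
    dy = target[1] - pos[1]
    return Cell(pos[0] + (dx > 0) - (dx < 0), pos[1] + (dy > 0) - (dy < 0))


def random_step(pos: Cell, grid: GridSpec, rng: np.random.Generator) -> Cell:
    """Uniform step in one of 8 directions, clipped to the grid bounds."""
    dx, dy = _DIRECTIONS[rng.integers(8)]
    x = min(max(pos[0] + dx, 0), grid.width - 1)
    y = min(max(pos[1] + dy, 0), grid.height - 1)
    return Cell(x, y)


def _check_region(region: int) -> None:
    if not 0 <= region < N_REGIONS:
        raise ValueError(f"region id must be in 0..{N_REGIONS - 1}, got {region}")


def region_of(cell: Cell) -> int:
    """Region id (row-major 0..8) of a cell on the 12x12 grid."""
    return (cell[1] // REGION_SIZE) * REGIONS_PER_SIDE + cell[0] // REGION_SIZE


def region_center(region: int) -> Cell:
    """A fixed interior cell of the region (floor convention: offset +1,+1)."""
    _check_region(region)
    bx, by = region % REGIONS_PER_SIDE, region // REGIONS_PER_SIDE
    return Cell(bx * REGION_SIZE + 1, by * REGION_SIZE + 1)


def region_cells(region: int) -> List[Cell]:
    """The 16 cells of one 4x4 region."""
    _check_region(region)
    bx, by = region % REGIONS_PER_SIDE, region // REGIONS_PER_SIDE
    return [
        Cell(bx * REGION_SIZE + i, by * REGION_SIZE + j)
        for j in range(REGION_SIZE)
        for i in range(REGION_SIZE)
    ]


def place_in_region(region: int, rng: np.random.Generator) -> Cell:
    """Uniform random cell within one region."""
    _check_region(region)
    bx, by = region % REGIONS_PER_SIDE, region // REGIONS_PER_SIDE
    return Cell(
        bx * REGION_SIZE + int(rng.integers(REGION_SIZE)),
        by * REGION_SIZE + int(rng.integers(REGION_SIZE)),
    )


def random_step_in_region(pos: Cell, region: int, rng: np.random.Generator) -> Cell:
    """Uniform 8-directional step, clipped to the region's 4x4 block."""
    _check_region(region)
    bx, by = region % REGIONS_PER_SIDE, region // REGIONS_PER_SIDE
    dx, dy = _DIRECTIONS[rng.integers(8)]
    x = min(max(pos[0] + dx, bx * REGION_SIZE), bx * REGION_SIZE + REGION_SIZE - 1)
    y = min(max(pos[1] + dy, by * REGION_SIZE), by * REGION_SIZE + REGION_SIZE - 1)
    return Cell(x, y)


def place_predator(rng: np.random.Generator, *, x_max: int = 5, height: int = 12) -> Cell:
    """Uniform placement on the left side of the grid (x <= x_max)."""
    return Cell(int(rng.integers(x_max + 1)), int(rng.integers(height)))
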