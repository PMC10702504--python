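"""Regular km grids and per-cell-day scalar fields.

All spatial data in the package lives on flat Euclidean km grids: cell (r, c)
of a grid with origin (x0, y0) has its center at
``(x0 + (c + 0.5) * cell_km, y0 + (r + 0.5) * cell_km)``, rows indexed from 0
row-major.  Cell ids are ``r * n_cols + c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class GridDefinition:
    """A regular grid of square cells, ``cell_km`` km on a side."""

    n_rows: int
    n_cols: int
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent_km(self) -> tuple[float, float]:
        """(width, height) of the domain in km."""
        return (self.n_cols * self.cell_km, self.n_rows * self.cell_km)

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_km

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_km

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centers in row-major cell-id order."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell id containing each (x, y) point; points are clipped to the domain."""
        c = np.clip(((np.asarray(x) - self.origin[0]) / self.cell_km).astype(int), 0, self.n_cols - 1)
        r = np.clip(((np.asarray(y) - self.origin[1]) / self.cell_km).astype(int), 0, self.n_rows - 1)
        return r * self.n_cols + c

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_km": self.cell_km,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridDefinition":
        return cls(d["n_rows"], d["n_cols"], d["cell_km"], tuple(d["origin"]))


@dataclass
class CellDayField:
    """One scalar field indexed by (day, row, col); NaN marks missing values.

    ``values`` has shape (n_days, n_rows, n_cols).  Day-static fields (e.g.
    population) use n_days == 1 and broadcast where needed.
    """

    grid: GridDefinition
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        if self.values.shape[1:] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def day(self, d: int) -> np.ndarray:
        return self.values[d]

    def flat(self) -> np.ndarray:
        """(n_days, n_cells) view in cell-id order."""
        return self.values.reshape(self.n_days, -1)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy(self) -> "CellDayField":
        return CellDayField(self.grid, self.values.copy(), self.units, self.name)


def save_field(path: Path, f: CellDayField) -> None:
    np.save(path, f.values)


def load_field(path: Path, grid: GridDefinition, units: str = "", name: str = "") -> CellDayField:
    return CellDayField(grid, np.load(path), units=units, name=name)


def save_grid(path: Path, grid: GridDefinition) -> None:
    Path(path).write_text(json.dumps(grid.to_dict(), indent=2))


def load_grid(path: Path) -> GridDefinition:
    return GridDefinition.from_dict(json.loads(Path(path).read_text()))
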