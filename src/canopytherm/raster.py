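"""Minimal raster containers and grid I/O.

Grids are plain 2-D numpy arrays with a cell size in metres. Float grids use
NaN as the nodata sentinel; categorical grids use 0. Two on-disk forms are
supported: a delimited text grid with a one-line header (human-readable, used
for fixtures and tests) and single-band TIFF via :mod:`tifffile`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "LandCover",
    "LandCoverMap",
    "read_text_grid",
    "write_text_grid",
    "read_tiff_grid",
    "write_tiff_grid",
]


@dataclass
class RasterGrid:
    """A 2-D field of values with square cells.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata cells.
    cell_size
        Side length of one cell in metres (> 0).
    """

    data: np.ndarray
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.data.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        return ~np.isnan(self.data)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    def like(self, data: np.ndarray) -> "RasterGrid":
        """New grid with the same geometry and different values."""
        return RasterGrid(data, cell_size=self.cell_size)


def congruent(*grids) -> None:
    """Raise ValueError unless all grids share shape and cell size."""
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape:
            raise ValueError(f"grid shapes differ: {first.shape} vs {g.shape}")
        if not np.isclose(g.cell_size, first.cell_size):
            raise ValueError(
                f"cell sizes differ: {first.cell_size} vs {g.cell_size}"
            )


class LandCover(IntEnum):
    """Five-class urban land-cover legend."""

    WATER = 1
    TREE_CANOPY = 2
    GRASSLAND = 3
    BARE_LAND = 4
    IMPERVIOUS = 5


#: nodata value for categorical grids
NO_CLASS = 0


@dataclass
class LandCoverMap:
    """Categorical grid over the five-class legend, geometry as RasterGrid."""

    grid: np.ndarray
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.grid.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        known = {NO_CLASS} | {int(c) for c in LandCover}
        present = set(np.unique(self.grid).tolist())
        if not present <= known:
            raise ValueError(f"unknown land-cover codes: {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def valid(self) -> np.ndarray:
        return self.grid != NO_CLASS

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    def class_mask(self, cls: LandCover) -> np.ndarray:
        return self.grid == int(cls)

    def class_area_hm2(self, cls: LandCover) -> float:
        """Planimetric class area in hectares (1 hm² = 10 000 m²)."""
        return self.class_mask(cls).sum() * self.cell_area_m2 / 1e4


# ---------------------------------------------------------------------------
# text-grid I/O: '# cell_size=<m> nodata=<v>' header then whitespace rows
# ---------------------------------------------------------------------------

def write_text_grid(path, grid: RasterGrid, fmt: str = "%.6g") -> None:
    header = f"cell_size={grid.cell_size!r} nodata=nan"
    np.savetxt(path, grid.data, fmt=fmt, header=header)


def read_text_grid(path) -> RasterGrid:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    cell_size = 30.0
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("cell_size="):
                cell_size = float(tok.split("=", 1)[1])
    data = np.loadtxt(path, ndmin=2)
    return RasterGrid(data, cell_size=cell_size)


def write_tiff_grid(path, grid: RasterGrid) -> None:
    import tifffile

    meta = {"cell_size": grid.cell_size}
    tifffile.imwrite(path, grid.data.astype(np.float32),
                     description=json.dumps(meta))


def read_tiff_grid(path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell_size = 30.0
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                cell_size = float(json.loads(desc.value).get("cell_size", 30.0))
            except (ValueError, AttributeError, TypeError):
                pass
    return RasterGrid(np.asarray(data, dtype=float), cell_size=cell_size)
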