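"""Raster containers shared by every stage of the pipeline.

A :class:`LandUseRaster` is the categorical substrate (class codes on a
regular square grid); :class:`FactorRaster` holds one continuous resistance
factor aligned to it.  Grids use image conventions: row 0 is the northern
edge, ``origin`` is the map coordinate of the top-left corner, and cell
centres sit half a cell in from the edges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: land-use class codes used by the synthetic generator and the defaults
DEFAULT_CLASS_TABLE = {
    1: "cropland",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "built",
    6: "barren",
}

FACTOR_NAMES = (
    "dem",
    "slope",
    "ndvi",
    "mndwi",
    "lucc",
    "pop_density",
    "water_density",
    "road_density",
)


class AlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


class ConfigError(ValueError):
    """Invalid user-supplied configuration."""


@dataclass
class LandUseRaster:
    """Categorical land-use grid.

    Parameters
    ----------
    values
        Integer class-code matrix (rows x cols).
    cell_size
        Side length of a square cell in metres.
    origin
        ``(x0, y0)`` map coordinates of the top-left raster corner.
    nodata
        Reserved code for missing cells (never a legal class).
    class_table
        Mapping from class code to class name.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = 0
    class_table: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TABLE)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ConfigError("raster must be a 2-D matrix with rows, cols >= 1")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        present = set(np.unique(self.values).tolist()) - {self.nodata}
        unknown = present - set(self.class_table)
        if unknown:
            raise ConfigError(f"codes {sorted(unknown)} missing from class_table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def landscape_area_m2(self) -> float:
        """Total non-nodata area, the A_L of the connectivity index."""
        return float(self.valid_mask().sum()) * self.cell_area_m2

    def cell_centroid(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def copy_with(self, values: np.ndarray) -> "LandUseRaster":
        return dataclasses.replace(self, values=np.asarray(values))


@dataclass
class FactorRaster:
    """One continuous resistance factor aligned to a land-use raster."""

    values: np.ndarray
    name: str
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.name not in FACTOR_NAMES:
            raise ConfigError(f"unknown factor name {self.name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def check_aligned(reference: LandUseRaster, *others) -> None:
    """Raise :class:`AlignmentError` unless all rasters share the grid."""
    for other in others:
        if other.shape != reference.shape:
            raise AlignmentError(
                f"shape mismatch: {other.shape} vs {reference.shape}"
            )
        if not np.isclose(other.cell_size, reference.cell_size):
            raise AlignmentError("cell_size mismatch")
        if not np.allclose(other.origin, reference.origin):
            raise AlignmentError("origin mismatch")


# ---------------------------------------------------------------------------
# writers

def write_tiff(path, values: np.ndarray, *, cell_size: float, origin) -> None:
    """Write a single-band TIFF; grid geometry goes in the image description."""
    import json

    import tifffile

    meta = {"cell_size": cell_size, "origin": list(origin)}
    tifffile.imwrite(path, np.asarray(values), description=json.dumps(meta))


def write_ascii_grid(path, values: np.ndarray, *, cell_size: float, origin) -> None:
    """Write an ESRI ASCII grid (plain-text raster interchange format)."""
    values = np.asarray(values)
    rows, cols = values.shape
    x0, y0 = origin
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {x0}\nyllcorner {y0 - rows * cell_size}\n"
        f"cellsize {cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in values:
            fh.write(" ".join(format(v) for v in row.tolist()) + "\n")
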