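"""Minimal georeferenced raster container and ESRI ASCII grid I/O.

Grids are stored as float64 arrays in raster order (row 0 = northern edge)
with NaN marking nodata in memory; the on-disk sentinel (default -9999) is
translated on read/write.  The transform is the ESRI lower-left-corner
convention: cell (row, col) covers
x in [xll + col*cs, xll + (col+1)*cs), y in (ytop - (row+1)*cs, ytop - row*cs]
so cell membership is half-open on the right/bottom edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridTransform", "RasterSurface", "read_ascii_grid", "write_ascii_grid"]


class RasterError(ValueError):
    pass


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of a north-up grid: lower-left corner + cell size."""

    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise RasterError(f"cellsize must be positive, got {self.cellsize}")


@dataclass
class RasterSurface:
    """One single-band georeferenced grid; NaN cells are nodata."""

    grid: np.ndarray
    transform: GridTransform = field(default_factory=lambda: GridTransform(0.0, 0.0, 70.0))
    crs_label: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise RasterError(f"grid must be 2-D, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    def copy_with(self, grid: np.ndarray) -> "RasterSurface":
        if grid.shape != self.grid.shape:
            raise RasterError(
                f"replacement grid shape {grid.shape} != {self.grid.shape}"
            )
        return RasterSurface(
            grid=np.asarray(grid, dtype=float),
            transform=self.transform,
            crs_label=self.crs_label,
            nodata=self.nodata,
        )

    def same_georeference(self, other: "RasterSurface") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a map coordinate to (row, col), or None if off the grid."""
        cs = self.transform.cellsize
        nrows, ncols = self.shape
        col = int(np.floor((x - self.transform.xllcorner) / cs))
        ytop = self.transform.yllcorner + nrows * cs
        row = int(np.floor((ytop - y) / cs))
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        cs = self.transform.cellsize
        nrows = self.shape[0]
        x = self.transform.xllcorner + (col + 0.5) * cs
        y = self.transform.yllcorner + (nrows - row - 0.5) * cs
        return x, y

    def value_at(self, x: float, y: float) -> float | None:
        """Grid value at a map coordinate; None when off-grid, NaN for nodata."""
        cell = self.cell_of(x, y)
        if cell is None:
            return None
        return float(self.grid[cell])


def require_coregistered(*surfaces: RasterSurface, names: list[str] | None = None) -> None:
    """Raise unless all surfaces share shape and transform."""
    first = surfaces[0]
    for i, s in enumerate(surfaces[1:], start=1):
        if not first.same_georeference(s):
            a = names[0] if names else "surface 0"
            b = names[i] if names else f"surface {i}"
            raise RasterError(
                f"surfaces {a!r} and {b!r} are not co-registered: "
                f"{first.shape}/{first.transform} vs {s.shape}/{s.transform}"
            )


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> RasterSurface:
    """Read a single-band ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterError(f"{path}: missing header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != nrows * ncols:
        raise RasterError(
            f"{path}: expected {nrows * ncols} cells, found {values.size}"
        )
    grid = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    grid[grid == nodata] = np.nan
    return RasterSurface(
        grid=grid,
        transform=GridTransform(header["xllcorner"], header["yllcorner"], header["cellsize"]),
        nodata=nodata,
    )


def write_ascii_grid(surface: RasterSurface, path: str | Path) -> None:
    """Write a RasterSurface as an ESRI ASCII grid, NaN -> nodata sentinel."""
    path = Path(path)
    nrows, ncols = surface.shape
    t = surface.transform
    grid = np.where(np.isnan(surface.grid), surface.nodata, surface.grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.xllcorner!r}\n")
        fh.write(f"yllcorner {t.yllcorner!r}\n")
        fh.write(f"cellsize {t.cellsize!r}\n")
        fh.write(f"NODATA_value {surface.nodata!r}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
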