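"""Georeferenced single-variable grids on an equal-area projection.

A :class:`RasterGrid` is the in-memory raster container used throughout the
package: a 2-D array plus cell size, origin and a nodata sentinel.  Row 0 is
the northernmost row; x increases eastward, y northward.  Continuous layers
are float with nodata ``-9999``; categorical layers are unsigned integer with
nodata ``255``.

I/O goes through two codecs: single-band TIFF (via :mod:`tifffile`, with the
georeferencing stored as JSON in the ImageDescription tag) and the ESRI ASCII
grid text format for small, human-readable artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

NODATA_FLOAT = -9999.0
NODATA_INT = 255


@dataclass
class RasterGrid:
    """One variable on an equal-area grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Cell values; row 0 is the top (northern) row.
    cell_size_m : float
        Cell edge length in metres (equal-area, square cells).
    origin : (float, float)
        (x, y) of the grid's lower-left corner in metres.
    nodata : float or int
        Sentinel marking invalid cells.
    """

    data: np.ndarray
    cell_size_m: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA_FLOAT
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (and finite)."""
        if np.issubdtype(self.data.dtype, np.floating):
            return np.isfinite(self.data) & (self.data != self.nodata)
        return self.data != self.nodata

    def is_aligned(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size_m == other.cell_size_m
            and self.origin == other.origin
        )

    def require_aligned(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.is_aligned(other):
            raise ValueError(
                f"misaligned {what}: {self.shape}@{self.cell_size_m}m/{self.origin} "
                f"vs {other.shape}@{other.cell_size_m}m/{other.origin}"
            )

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); point-in-cell lookup."""
        rows, cols = self.shape
        col = int(np.floor((x - self.origin[0]) / self.cell_size_m))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size_m))
        row = rows - 1 - row_from_bottom
        if not (0 <= row < rows and 0 <= col < cols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def coords_of(self, row: np.ndarray, col: np.ndarray):
        """Centre coordinates (x, y) of the given cells."""
        rows = self.shape[0]
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size_m
        y = self.origin[1] + (rows - np.asarray(row) - 0.5) * self.cell_size_m
        return x, y

    def like(self, data: np.ndarray, name: str = "", nodata=None) -> "RasterGrid":
        """New grid with the same geometry but different data."""
        return RasterGrid(
            data,
            cell_size_m=self.cell_size_m,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            name=name,
        )

    # -- I/O ----------------------------------------------------------------
    def write_tiff(self, path) -> None:
        meta = {
            "cell_size_m": self.cell_size_m,
            "origin": list(self.origin),
            "nodata": float(self.nodata),
            "name": self.name,
        }
        if np.issubdtype(self.data.dtype, np.floating):
            arr = self.data.astype(np.float32)
        else:
            arr = self.data.astype(np.uint8)
        tifffile.imwrite(str(path), arr, description=json.dumps(meta))

    @classmethod
    def read_tiff(cls, path) -> "RasterGrid":
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or "{}"
        meta = json.loads(desc)
        nodata = meta.get("nodata", NODATA_FLOAT)
        if not np.issubdtype(arr.dtype, np.floating):
            nodata = int(nodata)
        return cls(
            arr,
            cell_size_m=float(meta.get("cell_size_m", 100.0)),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            nodata=nodata,
            name=meta.get("name", ""),
        )

    def write_ascii(self, path) -> None:
        """ESRI ASCII grid (text) — for small artifacts and fixtures."""
        rows, cols = self.shape
        header = (
            f"ncols {cols}\nnrows {rows}\n"
            f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n"
            f"cellsize {self.cell_size_m}\nNODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        return cls(
            data,
            cell_size_m=header["cellsize"],
            origin=(header["xllcorner"], header["yllcorner"]),
            nodata=header["nodata_value"],
        )
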