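"""Lightweight georeferenced single-band raster.

The package's grids (DTM, CHM, derived surfaces, class maps, segment labels)
all share one container: a 2-D row-major, north-up array with an upper-left
origin, square cells and a nodata sentinel.  Persistence uses the ESRI ASCII
grid format (``.asc``), a plain-text interchange format every desktop GIS
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """Single-band north-up raster.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 is the northern edge.
    origin : (float, float)
        x, y of the *upper-left corner* of the grid, in metres.
    cell_size : float
        Square cell edge length in metres.
    nodata : float
        Sentinel for missing cells.
    crs : str
        Free-text coordinate system label (local metric frame by default).
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = NODATA_DEFAULT
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing the point (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def rowcol_to_xy(self, row, col):
        """Centre coordinates of cell (row, col); accepts arrays."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-centre coordinates."""
        nrows, ncols = self.shape
        rows, cols = np.mgrid[0:nrows, 0:ncols]
        return self.rowcol_to_xy(rows, cols)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin < y <= ymax

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "Raster":
        """New raster on the same grid with different values."""
        return replace(self, values=np.asarray(values))


# -- ASCII grid I/O -------------------------------------------------------

def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    nrows, ncols = raster.shape
    xll = raster.origin[0]
    yll = raster.origin[1] - nrows * raster.cell_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6f")


def read_ascii_grid(path, crs: str = "local-metric") -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Raster(
        values=values,
        origin=origin,
        cell_size=cell,
        nodata=header.get("nodata_value", NODATA_DEFAULT),
        crs=crs,
    )
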