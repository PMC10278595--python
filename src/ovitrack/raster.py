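"""Digital elevation model container and plain-text raster I/O.

The DEM is held as a regular grid of elevations in the pipeline's metric
CRS and serialised as an ESRI ASCII grid (``.asc``), a simple
whitespace-delimited text format understood by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# plausible terrestrial elevation bounds (Dead Sea shore .. above Everest)
ELEV_MIN_M = -430.0
ELEV_MAX_M = 9000.0


@dataclass
class DemRaster:
    """Single-band elevation raster.

    ``values`` is a (nrows, ncols) array ordered north-to-south (row 0 is
    the top of the map), matching the ASCII-grid convention; ``x0, y0`` is
    the lower-left corner of the lower-left cell.
    """

    x0: float
    y0: float
    cell_m: float
    values: np.ndarray
    crs: str = "metric"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DEM values must be a 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered area."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_m,
            self.y0 + self.nrows * self.cell_m,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell elevation lookup; NaN outside the extent or on
        nodata cells.  No interpolation: a fix gets the elevation of the
        cell it falls in, matching the raster's native granularity."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, np.nan)
        inside = self.contains(x, y)
        col = np.floor((x[inside] - self.x0) / self.cell_m).astype(int)
        row = (self.nrows - 1) - np.floor(
            (y[inside] - self.y0) / self.cell_m
        ).astype(int)
        vals = self.values[row, col]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[inside] = vals
        return out


def write_ascii_grid(dem: DemRaster, path) -> None:
    header = (
        f"ncols {dem.ncols}\n"
        f"nrows {dem.nrows}\n"
        f"xllcorner {dem.x0:.6f}\n"
        f"yllcorner {dem.y0:.6f}\n"
        f"cellsize {dem.cell_m:.6f}\n"
        f"NODATA_value {dem.nodata:g}\n"
    )
    body = np.where(np.isnan(dem.values), dem.nodata, dem.values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.3f")


def read_ascii_grid(path, crs: str = "metric") -> DemRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared shape")
    nodata = header.get("nodata_value", -9999.0)
    return DemRaster(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_m=header["cellsize"],
        values=values,
        crs=crs,
        nodata=nodata,
    )
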