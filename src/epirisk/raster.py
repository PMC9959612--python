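"""Minimal regular-grid raster container with ESRI ASCII-grid text I/O.

Rasters here are planar (projected, metric) grids: an origin at the lower-left
corner, a square cell size in meters, and a value matrix whose row 0 is the
NORTHERNMOST row (the ASCII-grid convention). Density surfaces and the
synthetic population / night-light layers all use this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "DensitySurface"]


@dataclass
class Raster:
    origin_x: float
    origin_y: float  # lower-left corner
    cell_size: float
    values: np.ndarray  # shape (nrows, ncols), row 0 = northernmost

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped like ``values``."""
        nrows, ncols = self.values.shape
        xs = self.origin_x + (np.arange(ncols) + 0.5) * self.cell_size
        # row 0 is the top row
        ys = self.origin_y + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def total(self) -> float:
        """Integral of the surface: sum(values) * cell area."""
        return float(np.nansum(self.values)) * self.cell_size**2

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.origin_x!r}\n"
            f"yllcorner {self.origin_y!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                meta[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        vals = np.loadtxt(lines[n_header:])
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            origin_x=meta["xllcorner"],
            origin_y=meta["yllcorner"],
            cell_size=meta["cellsize"],
            values=vals,
        )


@dataclass
class DensitySurface(Raster):
    """A raster whose values are a per-area density; records the bandwidth."""

    bandwidth: float = field(default=float("nan"))
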