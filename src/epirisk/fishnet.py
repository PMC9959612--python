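"""Regular square analysis grid ("fishnet") and zonal attachment of layers.

The fishnet tiles the bounding box of a study boundary with axis-aligned
square cells (1 km by default), anchored at the box's lower-left corner;
cells that do not intersect the boundary are dropped. All five risk
indicators are aggregated onto these cells:

* raster layers (population, night light) by the mean or sum of raster cells
  whose centers fall inside the fishnet cell;
* road segments (closeness / betweenness values) by the length-weighted mean
  of the segment portions clipped to the cell;
* density surfaces by the mean of surface cells with centers inside the cell.

Cells with no contributing data get the value 0 and are flagged, so the
downstream entropy weighting always sees a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep
from shapely.strtree import STRtree

from .raster import Raster

__all__ = ["Fishnet", "make_fishnet", "attach_raster", "attach_lines", "attach_surface"]


@dataclass
class Fishnet:
    boundary: BaseGeometry
    cell_size_m: float
    origin: tuple[float, float]  # lower-left anchor of the grid
    rows: np.ndarray  # per retained cell, row index (0 = southernmost)
    cols: np.ndarray
    attributes: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.attributes = pd.DataFrame(
            {
                "cell_id": np.arange(len(self.rows)),
                "row": self.rows,
                "col": self.cols,
            }
        )

    def __len__(self) -> int:
        return len(self.rows)

    def cell_polygon(self, i: int):
        x0 = self.origin[0] + self.cols[i] * self.cell_size_m
        y0 = self.origin[1] + self.rows[i] * self.cell_size_m
        return box(x0, y0, x0 + self.cell_size_m, y0 + self.cell_size_m)

    def cell_index(self, x, y) -> np.ndarray:
        """Retained-cell index containing each point, -1 if outside."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin[0]) / self.cell_size_m).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size_m).astype(int)
        lut = {(r, c): i for i, (r, c) in enumerate(zip(self.rows, self.cols))}
        return np.array([lut.get(rc, -1) for rc in zip(row, col)])

    def centers(self) -> np.ndarray:
        xs = self.origin[0] + (self.cols + 0.5) * self.cell_size_m
        ys = self.origin[1] + (self.rows + 0.5) * self.cell_size_m
        return np.column_stack([xs, ys])


def make_fishnet(boundary: BaseGeometry, cell_size_m: float = 1000.0) -> Fishnet:
    """Tile the boundary's bounding box and keep cells intersecting it.

    Cell ordering is row-major from the lower-left anchor (south to north,
    west to east) and stable across runs.
    """
    if boundary is None or boundary.is_empty:
        raise ValueError("empty study boundary")
    if cell_size_m <= 0:
        raise ValueError("cell size must be positive")
    minx, miny, maxx, maxy = boundary.bounds
    if maxx <= minx or maxy <= miny:
        raise ValueError("degenerate study boundary")
    ncols = int(np.ceil((maxx - minx) / cell_size_m - 1e-12))
    nrows = int(np.ceil((maxy - miny) / cell_size_m - 1e-12))
    prepared = prep(boundary)
    rows, cols = [], []
    for r in range(nrows):
        y0 = miny + r * cell_size_m
        for c in range(ncols):
            x0 = minx + c * cell_size_m
            cell = box(x0, y0, x0 + cell_size_m, y0 + cell_size_m)
            # retain on genuine (positive-area) overlap; a cell that merely
            # touches the boundary along an edge is dropped by the "sorting"
            if prepared.intersects(cell) and boundary.intersection(cell).area > 0:
                rows.append(r)
                cols.append(c)
    return Fishnet(
        boundary=boundary,
        cell_size_m=cell_size_m,
        origin=(minx, miny),
        rows=np.asarray(rows, dtype=int),
        cols=np.asarray(cols, dtype=int),
    )


def _bin_points(fishnet: Fishnet, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return fishnet.cell_index(x, y)


def attach_raster(
    fishnet: Fishnet,
    raster: Raster,
    statistic: str = "mean",
    name: str | None = None,
) -> np.ndarray:
    """Zonal statistic of raster cells whose centers fall in each fishnet cell.

    NaN raster cells (nodata) are excluded. Cells with no raster centers get
    0 and are flagged in ``attributes["<name>_empty"]``.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    if raster.cell_size > fishnet.cell_size_m + 1e-9:
        raise ValueError("raster resolution is coarser than the fishnet cell")
    cx, cy = raster.cell_centers()
    vals = raster.values.ravel()
    ok = ~np.isnan(vals)
    idx = _bin_points(fishnet, cx.ravel()[ok], cy.ravel()[ok])
    vals = vals[ok]
    inside = idx >= 0
    sums = np.bincount(idx[inside], weights=vals[inside], minlength=len(fishnet))
    counts = np.bincount(idx[inside], minlength=len(fishnet))
    if statistic == "mean":
        out = np.divide(sums, counts, out=np.zeros(len(fishnet)), where=counts > 0)
    else:
        out = sums
    empty = counts == 0
    if name:
        fishnet.attributes[name] = out
        fishnet.attributes[f"{name}_empty"] = empty
    return out


def attach_lines(
    fishnet: Fishnet,
    lines,
    values: np.ndarray,
    name: str | None = None,
) -> np.ndarray:
    """Length-weighted mean of segment values over each cell.

    ``lines`` is a sequence of LineStrings (or coordinate arrays); each
    carries one value. Segments are clipped to the cells; a cell crossed by
    no road gets 0 and is flagged.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("segment values must be finite")
    geoms = [
        g if isinstance(g, LineString) else LineString(np.asarray(g, dtype=float))
        for g in lines
    ]
    if len(geoms) != len(values):
        raise ValueError("lines/values length mismatch")

    weighted = np.zeros(len(fishnet))
    lengths = np.zeros(len(fishnet))
    tree = STRtree(geoms)
    for i in range(len(fishnet)):
        cell = fishnet.cell_polygon(i)
        for j in tree.query(cell):
            piece = geoms[j].intersection(cell)
            if piece.is_empty:
                continue
            L = piece.length
            if L > 0:
                weighted[i] += L * values[j]
                lengths[i] += L
    out = np.divide(weighted, lengths, out=np.zeros(len(fishnet)), where=lengths > 0)
    empty = lengths == 0
    if name:
        fishnet.attributes[name] = out
        fishnet.attributes[f"{name}_empty"] = empty
    return out


def attach_surface(fishnet: Fishnet, surface: Raster, name: str | None = None):
    """Mean of density-surface cells with centers inside each fishnet cell."""
    return attach_raster(fishnet, surface, statistic="mean", name=name)
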