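"""Kernel density surfaces for POI point sets and their functional blend.

The density estimator is the planar quartic (biweight) kernel evaluated on a
regular grid:

    f(s) = sum_i w_i * (3 / (pi r^2)) * (1 - d_i^2 / r^2)^2   for d_i < r,

where r is the search radius (bandwidth). Each kernel integrates to its
point weight, so the surface integral over a grid that contains all kernels
equals the total point weight. The default bandwidth is the GIS
rule of thumb

    H = 0.9 * min( sqrt(1/ln 2) * Dm, SD ) * n^(-0.2),

built from the median distance Dm and the standard distance SD of the point
set about its mean center.

Per-category surfaces are blended into the functional mixed density by a
cellwise weighted sum with nonnegative weights summing to 1 (the
public-dependence category weights in the full pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import DensitySurface

__all__ = [
    "PointSet",
    "standard_distance",
    "median_distance",
    "rule_of_thumb_radius",
    "kde_surface",
    "mixed_density",
]


@dataclass
class PointSet:
    """Planar points with optional nonnegative weights and category labels."""

    xy: np.ndarray  # (n, 2) meters
    weights: np.ndarray | None = None
    categories: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.shape[0] < 1 or self.xy.shape[1] != 2:
            raise ValueError("need at least one (x, y) point")
        if self.weights is None:
            self.weights = np.ones(len(self.xy))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("point weights must be >= 0")
            if len(self.weights) != len(self.xy):
                raise ValueError("weights length mismatch")

    def __len__(self) -> int:
        return len(self.xy)

    def mean_center(self) -> np.ndarray:
        return np.average(self.xy, axis=0, weights=self.weights)


def standard_distance(points: PointSet) -> float:
    """Root mean squared distance of the points about their mean center."""
    c = points.mean_center()
    d2 = np.sum((points.xy - c) ** 2, axis=1)
    return float(math.sqrt(np.average(d2, weights=points.weights)))


def median_distance(points: PointSet) -> float:
    """Median Euclidean distance of the points from their mean center."""
    c = points.mean_center()
    d = np.hypot(*(points.xy - c).T)
    return float(np.median(d))


def rule_of_thumb_radius(points: PointSet) -> float:
    """Rule-of-thumb KDE search radius H = 0.9 min(sqrt(1/ln2) Dm, SD) n^-0.2.

    Degenerate inputs (fewer than two points, or all points coincident) have
    no usable dispersion; an explicit bandwidth must be supplied instead.
    """
    n = len(points)
    if n < 2:
        raise ValueError("rule-of-thumb radius needs n >= 2; pass a bandwidth")
    sd = standard_distance(points)
    dm = median_distance(points)
    h = 0.9 * min(math.sqrt(1.0 / math.log(2.0)) * dm, sd) * n ** (-0.2)
    if h <= 0:
        raise ValueError(
            "degenerate point set (zero dispersion); pass an explicit bandwidth"
        )
    return h


def kde_surface(
    points: PointSet,
    bandwidth: float,
    origin: tuple[float, float],
    cell_size: float,
    shape: tuple[int, int],
) -> DensitySurface:
    """Quartic-kernel density surface evaluated at grid cell centers.

    ``origin`` is the lower-left corner of the grid; ``shape`` is
    (nrows, ncols). Values are per-area densities (1/m^2 times total point
    weight within each kernel).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("empty grid")
    r2 = bandwidth * bandwidth
    norm = 3.0 / (math.pi * r2)

    xs = origin[0] + (np.arange(ncols) + 0.5) * cell_size
    ys_top_down = origin[1] + (nrows - np.arange(nrows) - 0.5) * cell_size
    values = np.zeros((nrows, ncols))

    # per-point accumulation over its compact support only
    for (px, py), w in zip(points.xy, points.weights):
        if w == 0:
            continue
        i_lo = np.searchsorted(xs, px - bandwidth, side="left")
        i_hi = np.searchsorted(xs, px + bandwidth, side="right")
        if i_lo >= i_hi:
            continue
        dy2 = (ys_top_down - py) ** 2
        rows = np.nonzero(dy2 < r2)[0]
        if rows.size == 0:
            continue
        dx2 = (xs[i_lo:i_hi] - px) ** 2
        u = 1.0 - (dy2[rows, None] + dx2[None, :]) / r2
        np.maximum(u, 0.0, out=u)
        values[rows[:, None], np.arange(i_lo, i_hi)[None, :]] += w * norm * u * u

    return DensitySurface(
        origin_x=origin[0],
        origin_y=origin[1],
        cell_size=cell_size,
        values=values,
        bandwidth=bandwidth,
    )


def mixed_density(
    surfaces: dict[str, DensitySurface],
    weights: dict[str, float],
    tol: float = 1e-6,
) -> DensitySurface:
    """Cellwise weighted sum of per-category density surfaces.

    All surfaces must share one grid and the weights must already sum to 1;
    the blend never renormalizes silently.
    """
    if not surfaces:
        raise ValueError("no surfaces to blend")
    if set(surfaces) != set(weights):
        raise ValueError("surface and weight keys differ")
    w = np.array([weights[k] for k in surfaces])
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights sum to {w.sum():.6f}, expected 1")
    ref = next(iter(surfaces.values()))
    for s in surfaces.values():
        if not ref.same_grid(s):
            raise ValueError("surfaces are not on the same grid")
    values = np.zeros_like(ref.values)
    for k, s in surfaces.items():
        values += weights[k] * s.values
    return DensitySurface(
        origin_x=ref.origin_x,
        origin_y=ref.origin_y,
        cell_size=ref.cell_size,
        values=values,
        bandwidth=ref.bandwidth,
    )
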