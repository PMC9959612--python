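"""Composite risk scoring, five-grade classification, spatial structure.

The five normalized indicators are combined cellwise with the entropy-method
weights into a composite score in [0, 1]. Scores are classified into five
risk grades by geometric intervals: class widths form a geometric series
w_m = w_1 * g^(m-1) spanning [min, max], with the common ratio g chosen by a
deterministic 1-D search that balances the per-class counts (g = 1 recovers
equal intervals; g > 1 narrows the classes at the low end, which suits the
right-skewed score distributions typical of urban risk surfaces). Class 1 is
the HIGHEST-risk grade; a score exactly on a break goes to the riskier class.

The connected components of class-1 cells define the epidemic-disaster
spatial structure: the largest component is the "main" risk area, elongated
chains are "belts", other sizeable components are "secondary" areas and the
rest are "points". Validation assigns observed high-risk sites to the class
of their containing cell and reports the coverage of classes 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fishnet import Fishnet
from .weighting import WeightVector

__all__ = [
    "RiskMap",
    "SpatialStructure",
    "SiteValidation",
    "composite_score",
    "geometric_interval_breaks",
    "classify",
    "spatial_structure",
    "validate_sites",
]


@dataclass
class RiskMap:
    fishnet: Fishnet
    scores: np.ndarray  # per retained cell, [0, 1]
    classes: np.ndarray  # 1 (highest risk) .. k
    breaks: np.ndarray  # ascending upper edges of the low->high intervals

    @property
    def k(self) -> int:
        return len(self.breaks)

    def to_frame(self) -> pd.DataFrame:
        df = self.fishnet.attributes[["cell_id", "row", "col"]].copy()
        df["score"] = self.scores
        df["risk_class"] = self.classes
        return df


@dataclass
class SpatialStructure:
    components: pd.DataFrame  # label, n_cells, elongation, length, kind
    counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        kinds = ("main", "secondary", "belt", "point")
        self.counts = {k: int((self.components["kind"] == k).sum()) for k in kinds}


@dataclass
class SiteValidation:
    class_counts: dict[int, int]
    n_outside: int
    coverage_top2: float

    @property
    def n_in_grid(self) -> int:
        return sum(self.class_counts.values())


def composite_score(matrix, weights: WeightVector | np.ndarray) -> np.ndarray:
    """Weighted sum of normalized indicators: score_i = sum_j D_j x_ij."""
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    if x.ndim != 2 or x.shape[1] != len(w):
        raise ValueError(
            f"indicator matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, "
            f"weights have {len(w)}"
        )
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return x @ w


def _breaks_for_ratio(lo: float, hi: float, g: float, k: int) -> np.ndarray:
    """Ascending interior+top break values for geometric widths with ratio g."""
    m = np.arange(1, k + 1)
    if abs(g - 1.0) < 1e-12:
        cum = m / k
    else:
        cum = (g**m - 1.0) / (g**k - 1.0)
    return lo + (hi - lo) * cum


def geometric_interval_breaks(
    values: np.ndarray,
    k: int = 5,
    g: float | None = None,
    g_range: tuple[float, float] = (0.125, 8.0),
    n_grid: int = 241,
) -> np.ndarray:
    """Geometric-interval class breaks over [min, max].

    Class widths form the geometric series w_1 * g^(m-1) with
    w_1 = (max - min)(g - 1)/(g^k - 1). When ``g`` is not forced, it is
    selected from a deterministic log-spaced grid over ``g_range`` (always
    containing g = 1, the equal-interval limit) by minimizing the variance of
    per-class counts; ties go to the smallest g. Fewer than k distinct values
    fall back to quantile breaks with a warning.

    Returns the k ascending upper edges of the low-to-high intervals (the
    last equals the maximum).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to classify")
    lo, hi = float(v.min()), float(v.max())
    if len(np.unique(v)) < k:
        import warnings

        warnings.warn(
            f"fewer than {k} distinct values; falling back to quantile breaks",
            stacklevel=2,
        )
        qs = np.quantile(v, np.linspace(0, 1, k + 1)[1:])
        return qs

    if g is not None:
        return _breaks_for_ratio(lo, hi, g, k)

    candidates = np.unique(
        np.concatenate(
            [np.geomspace(g_range[0], g_range[1], n_grid), [1.0]]
        )
    )
    best_g = None
    best_var = np.inf
    for gc in candidates:
        breaks = _breaks_for_ratio(lo, hi, gc, k)
        counts = np.bincount(_interval_index(v, breaks), minlength=k)
        var = float(np.var(counts))
        if var < best_var - 1e-12 or (
            abs(var - best_var) <= 1e-12 and (best_g is None or gc < best_g)
        ):
            best_var = var
            best_g = gc
    return _breaks_for_ratio(lo, hi, float(best_g), k)


def _interval_index(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """0-based interval index from the low side; a value exactly on a break
    belongs to the interval above it (the riskier side)."""
    idx = np.searchsorted(breaks[:-1], values, side="right")
    return idx


def classify(scores: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Risk classes 1..k with class 1 = highest scores."""
    breaks = np.asarray(breaks, dtype=float)
    if np.any(np.diff(breaks) < 0):
        raise ValueError("breaks must be ascending")
    k = len(breaks)
    idx = _interval_index(np.asarray(scores, dtype=float), breaks)
    return (k - idx).astype(int)


def spatial_structure(
    riskmap: RiskMap,
    secondary_min_cells: int = 5,
    belt_ratio: float = 4.0,
    belt_min_cells: int = 8,
    connectivity: int = 8,
) -> SpatialStructure:
    """Label the connected components of class-1 cells.

    Components are 8-connected by default. The largest is ``main``;
    elongated ones (principal-axis extent ratio >= ``belt_ratio`` and major
    length >= ``belt_min_cells``) are ``belt``; remaining components with at
    least ``secondary_min_cells`` cells are ``secondary``; the rest are
    ``point``.
    """
    fn = riskmap.fishnet
    nrows = int(fn.rows.max()) + 1 if len(fn) else 0
    ncols = int(fn.cols.max()) + 1 if len(fn) else 0
    grid = np.zeros((nrows, ncols), dtype=bool)
    mask = riskmap.classes == 1
    grid[fn.rows[mask], fn.cols[mask]] = True

    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_comp = ndimage.label(grid, structure=structure)

    rows = []
    for lab in range(1, n_comp + 1):
        rr, cc = np.nonzero(labels == lab)
        n_cells = len(rr)
        elong, length = _elongation(rr, cc)
        rows.append(
            {"label": lab, "n_cells": n_cells, "elongation": elong, "length": length}
        )
    comp = pd.DataFrame(rows, columns=["label", "n_cells", "elongation", "length"])
    kinds = []
    if len(comp):
        main_label = comp.loc[comp["n_cells"].idxmax(), "label"]
        for _, r in comp.iterrows():
            if r["label"] == main_label:
                kinds.append("main")
            elif r["elongation"] >= belt_ratio and r["length"] >= belt_min_cells:
                kinds.append("belt")
            elif r["n_cells"] >= secondary_min_cells:
                kinds.append("secondary")
            else:
                kinds.append("point")
    comp["kind"] = kinds
    return SpatialStructure(components=comp)


def _elongation(rr: np.ndarray, cc: np.ndarray) -> tuple[float, float]:
    """Principal-axis extent ratio and major length (in cells) of a component."""
    pts = np.column_stack([cc, rr]).astype(float)
    if len(pts) == 1:
        return 1.0, 1.0
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    proj = pts @ evecs[:, ::-1]  # column 0 = major axis
    extent = proj.max(axis=0) - proj.min(axis=0) + 1.0
    major, minor = float(extent[0]), float(extent[1])
    if minor <= 0:
        return np.inf, major
    return major / minor, major


def validate_sites(sites: np.ndarray, riskmap: RiskMap) -> SiteValidation:
    """Assign each site the risk class of its containing fishnet cell."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    k = riskmap.k
    class_counts = {c: 0 for c in range(1, k + 1)}
    n_outside = 0
    if sites.size:
        idx = riskmap.fishnet.cell_index(sites[:, 0], sites[:, 1])
        for i in idx:
            if i < 0:
                n_outside += 1
            else:
                class_counts[int(riskmap.classes[i])] += 1
    n_in = sum(class_counts.values())
    top2 = class_counts.get(1, 0) + class_counts.get(2, 0)
    coverage = top2 / n_in if n_in else 0.0
    return SiteValidation(
        class_counts=class_counts, n_outside=n_outside, coverage_top2=coverage
    )
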