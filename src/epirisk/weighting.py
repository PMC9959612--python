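"""Indicator and category weighting.

Two weighting schemes feed the risk overlay:

* **Public-dependence category weights** — a Likert survey (1-5) scores how
  much the public depends on each of 13 POI subcategories. A subcategory's
  dependence index rescales its mean linearly so that a neutral mean of 3
  maps to 0 and the maximum of 5 maps to 1. A functional category's weight
  is the mean of its subcategory means, normalized across the six categories
  so the weights sum to 1. These weights blend the per-category kernel
  density surfaces into the functional mixed density.

* **Entropy weights** — objective indicator weights from the dispersion of
  the (min-max normalized) indicator columns across fishnet cells:
  p_ij = x_ij / sum_i x_ij,  E_j = -(1/ln n) sum_i p_ij ln p_ij  (0 ln 0 := 0),
  D_j = (1 - E_j) / (k - sum_j E_j). A more dispersed (lower-entropy) column
  carries more information and receives a larger weight; the weights sum
  to 1 identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import CATEGORIES, SUBCATEGORY_PARENT

__all__ = [
    "SurveyTable",
    "WeightVector",
    "dependence_index",
    "category_weights",
    "minmax_normalize",
    "entropy_weights",
]


@dataclass
class SurveyTable:
    """Likert survey summary: one row per POI subcategory.

    Columns: category, subcategory, mean (1-5), sd, n; the dependence column
    is derived on construction.
    """

    table: pd.DataFrame

    REQUIRED = ("category", "subcategory", "mean", "sd", "n")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"survey table missing columns: {missing}")
        means = self.table["mean"].to_numpy(dtype=float)
        if np.any((means < 1) | (means > 5)):
            raise ValueError("Likert means must lie in [1, 5]")
        self.table = self.table.copy()
        self.table["dependence"] = [dependence_index(m) for m in means]

    @classmethod
    def from_means(
        cls, means: dict[str, float], sd: dict[str, float] | None = None, n: int = 0
    ) -> "SurveyTable":
        rows = [
            {
                "category": SUBCATEGORY_PARENT[sub],
                "subcategory": sub,
                "mean": m,
                "sd": 0.0 if sd is None else sd.get(sub, 0.0),
                "n": n,
            }
            for sub, m in means.items()
        ]
        return cls(pd.DataFrame(rows))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveyTable":
        return cls(pd.read_csv(path))

    def means(self) -> dict[str, float]:
        return dict(zip(self.table["subcategory"], self.table["mean"]))


def dependence_index(mean: float) -> float:
    """Public-dependence index of a Likert mean: clip((mean - 3) / 2, 0, 1)."""
    if not 1.0 <= mean <= 5.0:
        raise ValueError(f"Likert mean {mean} outside [1, 5]")
    return float(np.clip((mean - 3.0) / 2.0, 0.0, 1.0))


def category_weights(survey: SurveyTable) -> dict[str, float]:
    """Functional-category weights: mean of subcategory means, normalized.

    Every category present must carry at least one subcategory mean; the
    returned weights sum to 1.
    """
    grouped = survey.table.groupby("category")["mean"].mean()
    if (grouped <= 0).any() or grouped.isna().any():
        raise ValueError("every category needs at least one subcategory mean")
    total = grouped.sum()
    # keep canonical category order where applicable
    keys = [c for c in CATEGORIES if c in grouped.index] + [
        c for c in grouped.index if c not in CATEGORIES
    ]
    return {c: float(grouped[c] / total) for c in keys}


def minmax_normalize(
    column: np.ndarray, orientation: str = "positive"
) -> tuple[np.ndarray, bool]:
    """Min-max rescale a column to [0, 1].

    positive: (e - min) / (max - min); negative: (max - e) / (max - min).
    A constant column is degenerate: it returns all zeros and a flag.
    """
    e = np.asarray(column, dtype=float)
    if e.size == 0:
        raise ValueError("empty column")
    if orientation not in ("positive", "negative"):
        raise ValueError("orientation must be 'positive' or 'negative'")
    lo, hi = float(e.min()), float(e.max())
    if hi == lo:
        return np.zeros_like(e), True
    if orientation == "positive":
        return (e - lo) / (hi - lo), False
    return (hi - e) / (hi - lo), False


@dataclass
class WeightVector:
    """Entropy-method output: per-indicator weights and entropy diagnostics."""

    weights: np.ndarray
    entropies: np.ndarray
    columns: list[str] | None = None

    def as_dict(self) -> dict[str, float]:
        cols = self.columns or [f"col{j}" for j in range(len(self.weights))]
        return dict(zip(cols, map(float, self.weights)))


def entropy_weights(
    matrix: np.ndarray | pd.DataFrame, degenerate_warn: bool = True
) -> WeightVector:
    """Entropy-method weights of a normalized indicator matrix.

    Rows are spatial cells, columns are indicators already normalized to
    [0, 1]. An all-zero (degenerate) column carries no information: its
    entropy is set to 1 and its weight is 0.
    """
    columns = None
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (cells x indicators)")
    n, k = x.shape
    if n < 2:
        raise ValueError("entropy weights need at least 2 rows")
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("matrix must be min-max normalized to [0, 1]")

    col_sums = x.sum(axis=0)
    entropies = np.ones(k)
    log_n = np.log(n)
    for j in range(k):
        if col_sums[j] <= 0:
            if degenerate_warn:
                warnings.warn(
                    f"degenerate all-zero indicator column {j}; weight set to 0",
                    stacklevel=2,
                )
            continue  # E_j = 1 -> weight 0
        p = x[:, j] / col_sums[j]
        nz = p > 0
        entropies[j] = -float(np.sum(p[nz] * np.log(p[nz]))) / log_n

    denom = k - entropies.sum()
    if denom <= 0:
        raise ValueError("all indicator columns are degenerate")
    weights = (1.0 - entropies) / denom
    return WeightVector(weights=weights, entropies=entropies, columns=columns)
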