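"""Synthetic-city generator with planted spatial structure.

Emulates the input stack of the urban epidemic-risk workflow — road
centerlines, a fine population raster, a coarser night-light raster,
categorized POIs, a Likert dependence survey and validation point sites —
on an abstract planar extent in meters, with known ("truth") hotspot
centers so that downstream stages can be tested for parameter recovery.

What is planted, in the generator's documented draw order:

1. hotspot centers (uniform in the interior of the extent, kept at least
   three sigma apart by rejection);
2. a connected grid of roads at a fixed pitch, plus diagonal arterials
   routed through the lattice point nearest each hotspot (through-routes
   with high traversal potential);
3. population raster (100 m cells): base + Gaussian hotspot gains, times
   multiplicative lognormal noise;
4. night-light raster (500 m cells): same construction, its own parameters;
5. POIs: a mixture of uniform background and isotropic Gaussian clusters at
   the hotspots; categories i.i.d. from the configured proportions
   (defaults are the published six-category inventory shares), subcategories
   from their conditional shares within the category;
6. survey responses: per respondent x subcategory, integer Likert scores
   1 + Binomial(4, (mean-1)/4), whose expectation equals the target mean;
7. validation sites: 85% near hotspots (Gaussian truncated at two sigma),
   15% uniform background.

Everything is drawn from one seeded generator, so a config plus seed fully
determines the city.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import taxonomy
from .raster import Raster
from .weighting import SurveyTable

__all__ = ["SyntheticCityConfig", "SyntheticCity", "generate_city", "generate_survey"]


def _default_props() -> dict[str, float]:
    return taxonomy.category_proportions()


def _default_means() -> dict[str, float]:
    return dict(taxonomy.SURVEY_MEANS)


@dataclass
class SyntheticCityConfig:
    extent_m: tuple[float, float] = (8000.0, 8000.0)
    road_grid_pitch_m: float = 1000.0
    n_arterials: int = 3
    n_hotspots: int = 3
    hotspot_centers: list[tuple[float, float]] | None = None
    hotspot_sigma_m: float = 700.0
    n_poi: int = 2000
    poi_category_props: dict[str, float] = field(default_factory=_default_props)
    poi_hotspot_frac: float = 0.7
    pop_base: float = 20.0
    pop_hotspot_gain: float = 400.0
    pop_cell_m: float = 100.0
    light_base: float = 5.0
    light_hotspot_gain: float = 60.0
    light_cell_m: float = 500.0
    noise_sigma: float = 0.2
    n_sites: int = 100
    site_hotspot_frac: float = 0.85
    survey_means: dict[str, float] = field(default_factory=_default_means)
    n_respondents: int = 204
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        for name, v in [
            ("extent width", w),
            ("extent height", h),
            ("road_grid_pitch_m", self.road_grid_pitch_m),
            ("hotspot_sigma_m", self.hotspot_sigma_m),
            ("pop_cell_m", self.pop_cell_m),
            ("light_cell_m", self.light_cell_m),
        ]:
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name, v in [
            ("n_poi", self.n_poi),
            ("n_hotspots", self.n_hotspots),
            ("n_sites", self.n_sites),
            ("n_arterials", self.n_arterials),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        props = np.array(list(self.poi_category_props.values()))
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("poi_category_props must be >= 0 and sum to 1")
        for sub, m in self.survey_means.items():
            if not 1.0 <= m <= 5.0:
                raise ValueError(f"survey mean for {sub} outside [1, 5]: {m}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "extent_m" in raw:
            raw["extent_m"] = tuple(raw["extent_m"])
        if raw.get("hotspot_centers"):
            raw["hotspot_centers"] = [tuple(c) for c in raw["hotspot_centers"]]
        return cls(**raw)


@dataclass
class SyntheticCity:
    config: SyntheticCityConfig
    roads: list[np.ndarray]  # polylines, each (k, 2)
    population: Raster
    night_light: Raster
    pois: pd.DataFrame  # x, y, category, subcategory
    survey: SurveyTable
    sites: np.ndarray  # (n, 2)
    truth_hotspots: np.ndarray  # (n_hotspots, 2); metadata, never a pipeline input


# --------------------------------------------------------------------------


def _draw_hotspots(config: SyntheticCityConfig, rng: np.random.Generator):
    if config.hotspot_centers is not None:
        centers = np.asarray(config.hotspot_centers, dtype=float)
        if len(centers) != config.n_hotspots:
            raise ValueError("hotspot_centers length != n_hotspots")
        return centers
    w, h = config.extent_m
    sigma = config.hotspot_sigma_m
    margin = min(max(2.0 * sigma, 0.1 * min(w, h)), 0.4 * min(w, h))
    centers: list[np.ndarray] = []
    min_sep = 3.0 * sigma
    for _ in range(config.n_hotspots):
        for _attempt in range(200):
            c = rng.uniform([margin, margin], [w - margin, h - margin])
            if all(np.hypot(*(c - p)) >= min_sep for p in centers):
                break
        centers.append(c)
    return np.array(centers) if centers else np.zeros((0, 2))


def _grid_roads(config: SyntheticCityConfig) -> list[np.ndarray]:
    w, h = config.extent_m
    pitch = config.road_grid_pitch_m
    nx = int(np.floor(w / pitch + 1e-9))
    ny = int(np.floor(h / pitch + 1e-9))
    roads = []
    for j in range(ny + 1):
        for i in range(nx):
            roads.append(
                np.array([[i * pitch, j * pitch], [(i + 1) * pitch, j * pitch]])
            )
    for i in range(nx + 1):
        for j in range(ny):
            roads.append(
                np.array([[i * pitch, j * pitch], [i * pitch, (j + 1) * pitch]])
            )
    return roads


def _arterials(
    config: SyntheticCityConfig, centers: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Diagonal through-routes anchored at the lattice point nearest a hotspot."""
    w, h = config.extent_m
    pitch = config.road_grid_pitch_m
    nx = int(np.floor(w / pitch + 1e-9))
    ny = int(np.floor(h / pitch + 1e-9))
    roads: list[np.ndarray] = []
    used: set[tuple[int, int]] = set()
    for k in range(config.n_arterials):
        if len(centers):
            cx, cy = centers[k % len(centers)]
        else:
            cx, cy = rng.uniform([0, 0], [w, h])
        ai = int(round(cx / pitch))
        aj = int(round(cy / pitch))
        slope = 1 if k % 2 == 0 else -1
        # diagonal identity: j - slope*i is constant along the route
        key = (slope, aj - slope * ai)
        if key in used:
            ai += 1
            key = (slope, aj - slope * ai)
        used.add(key)
        pts = []
        for i in range(nx + 1):
            j = aj + slope * (i - ai)
            if 0 <= j <= ny:
                pts.append((i, j))
        for (i0, j0), (i1, j1) in zip(pts, pts[1:]):
            roads.append(
                np.array(
                    [[i0 * pitch, j0 * pitch], [i1 * pitch, j1 * pitch]], dtype=float
                )
            )
    return roads


def _hotspot_field(
    xs: np.ndarray, ys: np.ndarray, centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of unit-amplitude isotropic Gaussians on a meshgrid (xs, ys)."""
    out = np.zeros((len(ys), len(xs)))
    for cx, cy in centers:
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma**2))
        out += gy[:, None] * gx[None, :]
    return out


def _intensity_raster(
    config: SyntheticCityConfig,
    centers: np.ndarray,
    cell: float,
    base: float,
    gain: float,
    rng: np.random.Generator,
) -> Raster:
    w, h = config.extent_m
    ncols = max(1, int(np.ceil(w / cell - 1e-9)))
    nrows = max(1, int(np.ceil(h / cell - 1e-9)))
    xs = (np.arange(ncols) + 0.5) * cell
    ys_top_down = (nrows - np.arange(nrows) - 0.5) * cell
    signal = base + gain * _hotspot_field(xs, ys_top_down, centers, config.hotspot_sigma_m)
    noise = rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=signal.shape)
    return Raster(origin_x=0.0, origin_y=0.0, cell_size=cell, values=signal * noise)


def _draw_pois(
    config: SyntheticCityConfig, centers: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    w, h = config.extent_m
    n = config.n_poi
    sigma = config.hotspot_sigma_m

    if len(centers) and config.poi_hotspot_frac > 0:
        clustered = rng.random(n) < config.poi_hotspot_frac
    else:
        clustered = np.zeros(n, dtype=bool)
    xy = rng.uniform([0, 0], [w, h], size=(n, 2))
    idx = np.nonzero(clustered)[0]
    if idx.size:
        which = rng.integers(0, len(centers), size=idx.size)
        pts = centers[which] + rng.normal(0.0, sigma, size=(idx.size, 2))
        # resample stragglers so every POI stays inside the extent
        bad = ~(
            (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        )
        while np.any(bad):
            k = int(bad.sum())
            pts[bad] = centers[rng.integers(0, len(centers), size=k)] + rng.normal(
                0.0, sigma, size=(k, 2)
            )
            bad = ~(
                (pts[:, 0] >= 0)
                & (pts[:, 0] <= w)
                & (pts[:, 1] >= 0)
                & (pts[:, 1] <= h)
            )
        xy[idx] = pts

    cats = list(config.poi_category_props)
    probs = np.array([config.poi_category_props[c] for c in cats])
    cat_idx = rng.choice(len(cats), size=n, p=probs / probs.sum())
    category = np.array(cats)[cat_idx]

    # conditional subcategory shares within each category (inventory shares)
    sub_by_cat: dict[str, tuple[list[str], np.ndarray]] = {}
    for c in cats:
        subs = [s for s, p in taxonomy.SUBCATEGORY_PARENT.items() if p == c]
        if subs:
            counts = np.array([taxonomy.SUBCATEGORY_COUNTS[s] for s in subs], float)
            sub_by_cat[c] = (subs, counts / counts.sum())
    subcategory = np.empty(n, dtype=object)
    for c in cats:
        mask = category == c
        k = int(mask.sum())
        if k == 0:
            continue
        if c in sub_by_cat:
            subs, p = sub_by_cat[c]
            subcategory[mask] = np.array(subs)[rng.choice(len(subs), size=k, p=p)]
        else:
            subcategory[mask] = c
    return pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "category": category, "subcategory": subcategory}
    )


def _draw_sites(
    config: SyntheticCityConfig, centers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    w, h = config.extent_m
    n = config.n_sites
    sigma = config.hotspot_sigma_m
    xy = np.empty((n, 2))
    for i in range(n):
        if len(centers) and rng.random() < config.site_hotspot_frac:
            c = centers[rng.integers(0, len(centers))]
            while True:
                p = c + rng.normal(0.0, sigma, size=2)
                if (
                    np.hypot(*(p - c)) <= 2.0 * sigma
                    and 0 <= p[0] <= w
                    and 0 <= p[1] <= h
                ):
                    break
            xy[i] = p
        else:
            xy[i] = rng.uniform([0, 0], [w, h])
    return xy


def generate_survey(
    config: SyntheticCityConfig, rng: np.random.Generator | None = None
) -> tuple[SurveyTable, SurveyTable]:
    """Simulate Likert responses; returns (sampled table, exact target table).

    Each response is one of the two integers bracketing the target mean,
    mixed so the expectation equals the target exactly (an integer target
    yields that value deterministically, so a target of 5 gives all-5
    responses). The adjacent-integer mixture keeps the per-item standard
    error small enough that the n=204 sample mean stays within 0.15 of the
    target.
    """
    if config.n_respondents < 2:
        raise ValueError("n_respondents must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    for sub, mu in config.survey_means.items():
        lo = int(np.floor(mu))
        frac = mu - lo
        resp = lo + (rng.random(config.n_respondents) < frac).astype(int)
        rows.append(
            {
                "category": taxonomy.SUBCATEGORY_PARENT.get(sub, sub),
                "subcategory": sub,
                "mean": float(resp.mean()),
                "sd": float(resp.std(ddof=1)),
                "n": config.n_respondents,
            }
        )
    sampled = SurveyTable(pd.DataFrame(rows))
    exact = SurveyTable.from_means(config.survey_means, n=config.n_respondents)
    return sampled, exact


def generate_city(config: SyntheticCityConfig) -> SyntheticCity:
    """Generate the full synthetic city; deterministic given config + seed."""
    rng = np.random.default_rng(config.seed)
    centers = _draw_hotspots(config, rng)
    roads = _grid_roads(config) + _arterials(config, centers, rng)
    population = _intensity_raster(
        config, centers, config.pop_cell_m, config.pop_base, config.pop_hotspot_gain, rng
    )
    night_light = _intensity_raster(
        config,
        centers,
        config.light_cell_m,
        config.light_base,
        config.light_hotspot_gain,
        rng,
    )
    pois = _draw_pois(config, centers, rng)
    survey, _ = generate_survey(config, rng)
    sites = _draw_sites(config, centers, rng)
    return SyntheticCity(
        config=config,
        roads=roads,
        population=population,
        night_light=night_light,
        pois=pois,
        survey=survey,
        sites=sites,
        truth_hotspots=centers,
    )
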