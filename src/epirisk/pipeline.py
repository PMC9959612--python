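"""End-to-end orchestration: synthetic city (or files) -> risk map.

Stage order mirrors the assessment workflow: generate/load inputs ->
road-network centralities -> per-category kernel densities -> survey-derived
category weights -> functional mixed density -> fishnet aggregation of the
five indicators -> min-max normalization -> entropy weights -> weighted
composite -> geometric-interval classification -> spatial structure ->
site validation. One YAML config (and its seed) fully determines every
numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import geojson_io
from .density import PointSet, kde_surface, mixed_density, rule_of_thumb_radius
from .fishnet import Fishnet, attach_lines, attach_raster, attach_surface, make_fishnet
from .overlay import (
    RiskMap,
    SiteValidation,
    SpatialStructure,
    classify,
    composite_score,
    geometric_interval_breaks,
    spatial_structure,
    validate_sites,
)
from .raster import Raster
from .road_network import DistanceSpec, RadiusSpec, betweenness, build_graph, closeness
from .synthetic_city import SyntheticCity, SyntheticCityConfig, generate_city
from .weighting import SurveyTable, WeightVector, category_weights, entropy_weights, minmax_normalize

logger = logging.getLogger("epirisk")

INDICATORS = ("pop", "light", "nqpd", "tpbt", "mixdens")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``synthetic`` or ``inputs``."""

    synthetic: SyntheticCityConfig | None = None
    inputs: dict[str, str] | None = None  # roads/population/night_light/pois/survey/sites/extent
    cell_size_m: float = 1000.0
    radius: float = float("inf")
    distance_mode: str = "hybrid"
    angular_weight_m_per_deg: float = 1.0
    snap_tol_m: float = 0.5
    kde_bandwidth_m: float | None = None  # None -> rule of thumb on pooled POIs
    kde_cell_m: float | None = None  # None -> bandwidth / 10, capped to the fishnet cell
    raster_statistic: str = "mean"
    n_classes: int = 5
    secondary_min_cells: int = 5
    belt_ratio: float = 4.0
    belt_min_cells: int = 8
    connectivity: int = 8
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            syn.setdefault("seed", raw.get("seed", 0))
            if "extent_m" in syn:
                syn["extent_m"] = tuple(syn["extent_m"])
            raw["synthetic"] = SyntheticCityConfig(**syn)
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


@dataclass
class RiskAssessmentResult:
    indicator_table: pd.DataFrame
    category_weights: dict[str, float]
    weight_vector: WeightVector
    riskmap: RiskMap
    structure: SpatialStructure
    validation: SiteValidation | None
    provenance: dict = field(default_factory=dict)
    city: SyntheticCity | None = None


def _load_inputs(config: RunConfig):
    paths = config.inputs
    roads, _ = geojson_io.read_lines(paths["roads"])
    population = Raster.read_ascii(paths["population"])
    night_light = Raster.read_ascii(paths["night_light"])
    pois = geojson_io.read_points(paths["pois"])
    survey = SurveyTable.read_csv(paths["survey"])
    sites = None
    if paths.get("sites"):
        pts = geojson_io.read_points(paths["sites"])
        sites = pts[["x", "y"]].to_numpy()
    extent = paths.get("extent")
    if extent:
        boundary = box(0.0, 0.0, float(extent[0]), float(extent[1]))
    else:
        xs = pois["x"]
        ys = pois["y"]
        boundary = box(xs.min(), ys.min(), xs.max(), ys.max())
    return roads, population, night_light, pois, survey, sites, boundary


def run_pipeline(config: RunConfig) -> RiskAssessmentResult:
    """Execute the full risk-assessment chain and return all stage outputs."""
    city = None
    if config.synthetic is not None:
        logger.info("stage synth: generating synthetic city (seed=%s)", config.synthetic.seed)
        city = generate_city(config.synthetic)
        roads = city.roads
        population, night_light = city.population, city.night_light
        pois, survey, sites = city.pois, city.survey, city.sites
        w, h = config.synthetic.extent_m
        boundary = box(0.0, 0.0, w, h)
    else:
        logger.info("stage load: reading inputs")
        roads, population, night_light, pois, survey, sites, boundary = _load_inputs(config)

    # --- road-network centralities ---------------------------------------
    graph = build_graph(roads, snap_tol_m=config.snap_tol_m)
    radius = RadiusSpec(config.radius)
    dist_spec = DistanceSpec(config.distance_mode, config.angular_weight_m_per_deg)
    logger.info(
        "stage network: %d segments, %d junctions, mode=%s radius=%s",
        graph.n_segments,
        graph.n_junctions,
        dist_spec.mode,
        radius.radius,
    )
    nqpd = closeness(graph, radius, dist_spec)
    tpbt = betweenness(graph, radius, dist_spec)

    # --- survey -> category weights --------------------------------------
    cat_weights = category_weights(survey)
    logger.info("stage weights: category weights %s", cat_weights)

    # --- per-category KDE and functional mixed density -------------------
    all_points = PointSet(pois[["x", "y"]].to_numpy())
    bandwidth = config.kde_bandwidth_m or rule_of_thumb_radius(all_points)
    minx, miny, maxx, maxy = boundary.bounds
    cell = config.kde_cell_m or min(bandwidth / 10.0, config.cell_size_m)
    shape = (
        int(np.ceil((maxy - miny) / cell)),
        int(np.ceil((maxx - minx) / cell)),
    )
    logger.info(
        "stage kde: bandwidth=%.1f m, cell=%.1f m, grid=%s", bandwidth, cell, shape
    )
    surfaces = {}
    for cat in cat_weights:
        pts = pois.loc[pois["category"] == cat, ["x", "y"]].to_numpy()
        if len(pts) == 0:
            pts = np.empty((0, 2))
            surfaces[cat] = kde_surface(
                PointSet(np.array([[minx - 10 * bandwidth, miny - 10 * bandwidth]])),
                bandwidth,
                (minx, miny),
                cell,
                shape,
            )
        else:
            surfaces[cat] = kde_surface(
                PointSet(pts), bandwidth, (minx, miny), cell, shape
            )
    mixed = mixed_density(surfaces, cat_weights)

    # --- fishnet aggregation ----------------------------------------------
    fn = make_fishnet(boundary, config.cell_size_m)
    logger.info("stage grid: %d cells of %.0f m", len(fn), config.cell_size_m)
    attach_raster(fn, population, config.raster_statistic, name="pop")
    attach_raster(fn, night_light, config.raster_statistic, name="light")
    attach_lines(fn, roads, nqpd, name="nqpd")
    attach_lines(fn, roads, tpbt, name="tpbt")
    attach_surface(fn, mixed, name="mixdens")
    indicator_table = fn.attributes[["cell_id", "row", "col", *INDICATORS]].copy()

    # --- normalization, entropy weights, composite ------------------------
    norm = {}
    for col in INDICATORS:
        norm[col], degenerate = minmax_normalize(
            indicator_table[col].to_numpy(), "positive"
        )
        if degenerate:
            logger.warning("indicator %s is constant across cells", col)
    norm_df = pd.DataFrame(norm)
    wv = entropy_weights(norm_df)
    logger.info("stage entropy: weights %s", wv.as_dict())
    scores = composite_score(norm_df, wv)

    breaks = geometric_interval_breaks(scores, k=config.n_classes)
    classes = classify(scores, breaks)
    riskmap = RiskMap(fishnet=fn, scores=scores, classes=classes, breaks=breaks)
    structure = spatial_structure(
        riskmap,
        secondary_min_cells=config.secondary_min_cells,
        belt_ratio=config.belt_ratio,
        belt_min_cells=config.belt_min_cells,
        connectivity=config.connectivity,
    )
    logger.info("stage overlay: structure %s", structure.counts)

    validation = validate_sites(sites, riskmap) if sites is not None else None
    if validation is not None:
        logger.info(
            "stage validate: per-class %s, coverage(1-2)=%.3f",
            validation.class_counts,
            validation.coverage_top2,
        )

    provenance = {
        "config_digest": config.digest(),
        "seed": config.synthetic.seed if config.synthetic else config.seed,
        "n_segments": graph.n_segments,
        "n_cells": len(fn),
        "kde_bandwidth_m": float(bandwidth),
    }
    result = RiskAssessmentResult(
        indicator_table=indicator_table,
        category_weights=cat_weights,
        weight_vector=wv,
        riskmap=riskmap,
        structure=structure,
        validation=validation,
        provenance=provenance,
        city=city,
    )
    if config.out_dir:
        _write_artifacts(config, result, roads, nqpd, tpbt, graph)
    return result


def _write_artifacts(config: RunConfig, result, roads, nqpd, tpbt, graph) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geojson_io.write_lines(
        out / "roads_centrality.geojson",
        roads,
        [
            {"id": i, "length_m": graph.segments[i].length, "nqpd": float(nqpd[i]), "tpbt": float(tpbt[i])}
            for i in range(len(roads))
        ],
    )
    pd.DataFrame(
        {
            "segment_id": np.arange(len(roads)),
            "length_m": [s.length for s in graph.segments],
            "nqpd": nqpd,
            "tpbt": tpbt,
        }
    ).to_csv(out / "roads_centrality.csv", index=False)
    df = result.riskmap.to_frame()
    full = result.indicator_table.merge(df, on=["cell_id", "row", "col"])
    full.to_csv(out / "riskmap.csv", index=False)
    geojson_io.write_fishnet(out / "riskmap.geojson", result.riskmap.fishnet, full)
    result.structure.components.to_csv(out / "structure.csv", index=False)
    pd.DataFrame(
        {
            "indicator": list(result.weight_vector.as_dict()),
            "weight": list(result.weight_vector.as_dict().values()),
            "entropy": result.weight_vector.entropies,
        }
    ).to_csv(out / "entropy_weights.csv", index=False)
    pd.DataFrame(
        [{"category": c, "weight": w} for c, w in result.category_weights.items()]
    ).to_csv(out / "category_weights.csv", index=False)
    if result.validation is not None:
        pd.DataFrame(
            [
                {"risk_class": c, "n_sites": n}
                for c, n in result.validation.class_counts.items()
            ]
        ).to_csv(out / "site_validation.csv", index=False)
    report = out / "run_report.txt"
    v = result.validation
    report.write_text(
        "epidemic-risk assessment run\n"
        f"provenance: {result.provenance}\n"
        f"entropy weights: {result.weight_vector.as_dict()}\n"
        f"category weights: {result.category_weights}\n"
        f"structure: {result.structure.counts}\n"
        + (
            f"site coverage classes 1-2: {v.coverage_top2:.3f} ({v.class_counts})\n"
            if v is not None
            else ""
        )
    )
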