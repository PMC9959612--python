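"""GeoJSON readers/writers for roads, points and fishnet cells.

Coordinates are planar meters (a projected CRS is assumed for real data;
the synthetic city uses abstract metric coordinates). GeoJSON is plain
JSON, so the stdlib encoder is used directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _feature(geometry: dict, properties: dict) -> dict:
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def _collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_lines(
    path: str | Path, polylines, properties: list[dict] | None = None
) -> None:
    feats = []
    for i, pl in enumerate(polylines):
        coords = np.asarray(getattr(pl, "coords", pl), dtype=float).tolist()
        props = properties[i] if properties else {"id": i}
        feats.append(_feature({"type": "LineString", "coordinates": coords}, props))
    Path(path).write_text(json.dumps(_collection(feats)))


def read_lines(path: str | Path) -> tuple[list[np.ndarray], list[dict]]:
    data = json.loads(Path(path).read_text())
    polylines, props = [], []
    for feat in data["features"]:
        geom = feat["geometry"]
        if geom["type"] == "LineString":
            polylines.append(np.asarray(geom["coordinates"], dtype=float))
            props.append(feat.get("properties") or {})
        elif geom["type"] == "MultiLineString":
            for part in geom["coordinates"]:
                polylines.append(np.asarray(part, dtype=float))
                props.append(feat.get("properties") or {})
    return polylines, props


def write_points(path: str | Path, df: pd.DataFrame) -> None:
    """Point features from a DataFrame with x, y and property columns."""
    prop_cols = [c for c in df.columns if c not in ("x", "y")]
    feats = [
        _feature(
            {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            {c: getattr(r, c) for c in prop_cols},
        )
        for r in df.itertuples(index=False)
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def read_points(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        if feat["geometry"]["type"] != "Point":
            continue
        x, y = feat["geometry"]["coordinates"][:2]
        rows.append({"x": x, "y": y, **(feat.get("properties") or {})})
    return pd.DataFrame(rows)


def write_fishnet(path: str | Path, fishnet, extra: pd.DataFrame | None = None) -> None:
    """Fishnet cells as Polygon features carrying the attribute table."""
    table = fishnet.attributes if extra is None else extra
    feats = []
    for i in range(len(fishnet)):
        poly = fishnet.cell_polygon(i)
        props = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in table.iloc[i].items()
        }
        feats.append(
            _feature(
                {
                    "type": "Polygon",
                    "coordinates": [list(map(list, poly.exterior.coords))],
                },
                props,
            )
        )
    Path(path).write_text(json.dumps(_collection(feats)))
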