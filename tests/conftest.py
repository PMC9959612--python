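import numpy as np
import pytest

from epirisk import RunConfig, SyntheticCityConfig, run_pipeline
from epirisk.road_network import build_graph


@pytest.fixture(scope="session")
def unit_path_graph():
    """Three collinear unit segments A-B-C sharing endpoints."""
    polys = [
        np.array([[0.0, 0.0], [1.0, 0.0]]),
        np.array([[1.0, 0.0], [2.0, 0.0]]),
        np.array([[2.0, 0.0], [3.0, 0.0]]),
    ]
    return build_graph(polys, snap_tol_m=1e-6)


@pytest.fixture(scope="session")
def default_city_result():
    """One full pipeline run on the default synthetic city (seed 1)."""
    return run_pipeline(RunConfig(synthetic=SyntheticCityConfig(seed=1)))


def random_road_graph(rng: np.random.Generator, n_segments: int):
    """Random connected straight-segment network for oracle comparisons.

    Random points in a square joined by a random spanning tree plus a few
    extra chords; segment weights are random in [0.5, 2].
    """
    n_pts = max(3, n_segments // 2 + 2)
    pts = rng.uniform(0, 10, size=(n_pts, 2))
    edges = set()
    order = rng.permutation(n_pts)
    for i in range(1, n_pts):
        j = order[rng.integers(0, i)]
        edges.add(tuple(sorted((int(order[i]), int(j)))))
    while len(edges) < n_segments:
        a, b = rng.integers(0, n_pts, size=2)
        if a != b:
            edges.add(tuple(sorted((int(a), int(b)))))
        if len(edges) >= n_pts * (n_pts - 1) // 2:
            break
    edges = sorted(edges)[:n_segments]
    polys = [np.array([pts[a], pts[b]]) for a, b in edges]
    weights = rng.uniform(0.5, 2.0, size=len(polys))
    return build_graph(polys, snap_tol_m=1e-9, weights=weights)
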