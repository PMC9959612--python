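"""Road-graph construction and centrality unit/property tests."""

import math

import numpy as np
import pytest

from epirisk.road_network import (
    INFINITE,
    DistanceSpec,
    RadiusSpec,
    betweenness,
    build_graph,
    closeness,
    segment_distance,
)

from _brute_force import brute_betweenness, brute_closeness, geodesics


class TestBuildGraph:
    def test_collinear_path(self, unit_path_graph):
        g = unit_path_graph
        assert g.n_junctions == 4
        assert g.n_segments == 3
        assert g.is_connected()

    def test_crossing_without_shared_endpoint_stays_disconnected(self):
        g = build_graph(
            [np.array([[0.0, -1.0], [0.0, 1.0]]), np.array([[-1.0, 0.0], [1.0, 0.0]])],
            snap_tol_m=0.01,
        )
        assert g.n_junctions == 4
        assert g.n_segments == 2
        assert not g.is_connected()
        assert segment_distance(g, 0, 1) == math.inf

    def test_snap_tolerance_merges_nearby_endpoints(self):
        g = build_graph(
            [np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([[1.4, 0.0], [2.0, 0.0]])],
            snap_tol_m=0.5,
        )
        assert g.n_junctions == 3
        assert g.is_connected()

    def test_rejects_empty_and_zero_length(self):
        with pytest.raises(ValueError):
            build_graph([])
        with pytest.raises(ValueError, match="zero-length"):
            build_graph([np.array([[1.0, 1.0], [1.0, 1.0]])])


class TestSegmentDistance:
    def test_metric_path_midpoint_convention(self, unit_path_graph):
        assert segment_distance(unit_path_graph, 0, 2) == pytest.approx(2.0, abs=1e-9)
        assert segment_distance(unit_path_graph, 0, 1) == pytest.approx(1.0, abs=1e-9)

    def test_self_distance_zero(self, unit_path_graph):
        for x in range(3):
            assert segment_distance(unit_path_graph, x, x) == 0.0

    def test_right_angle_hybrid(self):
        g = build_graph(
            [np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([[1.0, 0.0], [1.0, 1.0]])],
            snap_tol_m=1e-6,
        )
        d = segment_distance(g, 0, 1, DistanceSpec("hybrid", 1.0))
        assert d == pytest.approx(91.0, abs=1e-9)
        assert segment_distance(g, 0, 1, DistanceSpec("angular")) == pytest.approx(
            90.0, abs=1e-9
        )

    def test_unknown_segment_raises(self, unit_path_graph):
        with pytest.raises(KeyError):
            segment_distance(unit_path_graph, 0, 99)


class TestCloseness:
    def test_unit_path_hand_enumeration(self, unit_path_graph):
        nqpd = closeness(unit_path_graph)
        assert nqpd == pytest.approx([1.5, 2.0, 1.5], abs=1e-9)

    def test_single_segment_empty_sum(self):
        g = build_graph([np.array([[0.0, 0.0], [1.0, 0.0]])])
        assert closeness(g) == pytest.approx([0.0])

    def test_radius_filter(self, unit_path_graph):
        nqpd = closeness(unit_path_graph, RadiusSpec(1.0))
        assert nqpd[0] == pytest.approx(1.0, abs=1e-9)
        assert nqpd[1] == pytest.approx(2.0, abs=1e-9)

    def test_monotone_in_radius(self, unit_path_graph):
        prev = np.zeros(3)
        for r in (0.5, 1.0, 1.5, 2.0, INFINITE):
            cur = closeness(unit_path_graph, RadiusSpec(r))
            assert np.all(cur >= prev - 1e-12)
            prev = cur


class TestBetweenness:
    def test_unit_path_hand_enumeration(self, unit_path_graph):
        tpbt = betweenness(unit_path_graph)
        assert tpbt == pytest.approx([2 / 3, 4 / 3, 2 / 3], abs=1e-9)

    def test_single_segment(self):
        g = build_graph([np.array([[0.0, 0.0], [1.0, 0.0]])])
        assert betweenness(g) == pytest.approx([0.0])


class TestProperties:
    def test_relabeling_permutes_results(self):
        rng = np.random.default_rng(7)
        from conftest import random_road_graph

        g = random_road_graph(rng, 8)
        polys = [s.coords for s in g.segments]
        w = [s.weight for s in g.segments]
        perm = rng.permutation(len(polys))
        g2 = build_graph(
            [polys[i] for i in perm], snap_tol_m=1e-9, weights=[w[i] for i in perm]
        )
        for f in (closeness, betweenness):
            a = f(g)
            b = f(g2)
            assert b == pytest.approx(a[perm], abs=1e-9)

    def test_scale_covariance(self):
        rng = np.random.default_rng(11)
        from conftest import random_road_graph

        g = random_road_graph(rng, 7)
        c = 3.7
        g2 = build_graph(
            [s.coords * c for s in g.segments],
            snap_tol_m=1e-9,
            weights=[s.weight for s in g.segments],
        )
        assert closeness(g2) == pytest.approx(closeness(g) / c, rel=1e-9)
        assert betweenness(g2) == pytest.approx(betweenness(g), abs=1e-9)

    @pytest.mark.parametrize("mode", ["metric", "angular", "hybrid"])
    def test_matches_brute_force_small(self, unit_path_graph, mode):
        spec = DistanceSpec(mode, 0.5)
        if mode == "angular":
            # collinear segments sit at zero angular distance: both the
            # solver and the oracle exclude them, with a warning
            with pytest.warns(UserWarning, match="zero network distance"):
                nqpd = closeness(unit_path_graph, dist_spec=spec)
        else:
            nqpd = closeness(unit_path_graph, dist_spec=spec)
        assert nqpd == pytest.approx(
            brute_closeness(unit_path_graph, mode=mode, w_ang=0.5), abs=1e-9
        )
        assert betweenness(unit_path_graph, dist_spec=spec) == pytest.approx(
            brute_betweenness(unit_path_graph, mode=mode, w_ang=0.5), abs=1e-9
        )

    def test_distance_matches_route_enumeration(self):
        rng = np.random.default_rng(3)
        from conftest import random_road_graph

        g = random_road_graph(rng, 9)
        for mode in ("metric", "angular", "hybrid"):
            for x, y in [(0, g.n_segments - 1), (1, 3)]:
                d_expected, _ = geodesics(g, x, y, mode=mode, w_ang=1.0)
                d = segment_distance(g, x, y, DistanceSpec(mode, 1.0))
                if math.isinf(d_expected):
                    assert math.isinf(d)
                else:
                    assert d == pytest.approx(d_expected, abs=1e-9)
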