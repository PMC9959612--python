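"""Segment-based road-network centrality (sDNA-style closeness and betweenness).

The road network is modelled the way spatial design network analysis does:
the unit of analysis is the road *segment* (a polyline between junctions), not
the junction. Two segments are adjacent when they share a junction, and the
cost of moving between them is measured midpoint-to-midpoint along the
network, under one of three distance modes:

``metric``
    network length in meters; each terminal segment contributes half its
    length, each intermediate segment its full length.
``angular``
    cumulative angular change in degrees: the turn angle at every junction
    crossed plus the interior direction changes of curved polylines.
``hybrid``
    metric + ``angular_weight_m_per_deg`` x angular.

Two radius-limited centralities are computed per segment *x*:

* closeness ``NQPD(x) = sum_{y: d(x,y) <= R} W(y) / d(x,y)`` — the
  weight-over-distance sum across all segments reachable within the search
  radius R (discrete analysis: the in-radius membership P(y) is 0/1);
* betweenness ``TPBt(x) = sum_y sum_{z in R_y} OD(y,z,x) W(z) / TotalWeight(y)``
  — a normalized count of inter-segment geodesics passing through x, where
  OD is 1 when x is strictly interior to the y-z geodesic, 0.5 when x is an
  endpoint of the pair (x = y or x = z), and equal-cost geodesics split OD
  equally. TotalWeight(y) sums the weights of all segments within radius of
  y, y itself included.

Junction turn costs and segment interior curvature are derived from geometry
at build time. Shortest paths and the geodesic-tie bookkeeping run on a
directed midpoint expansion of the segment graph (nodes are "entering s via
end e" / "leaving s via end e" states), which forbids mid-segment U-turns by
construction; geodesic multiplicities are accumulated with a Brandes-style
dependency sweep. Every expanded edge carries a jitter of 1e-13 so that the
tight-edge DAG stays acyclic in the presence of zero-cost transitions
(collinear continuations under the angular metric); the jitter is far below
the 1e-9 tie tolerance and does not affect reported values.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoadGraph",
    "RadiusSpec",
    "DistanceSpec",
    "CentralityResult",
    "INFINITE",
    "build_graph",
    "segment_distance",
    "closeness",
    "betweenness",
]

#: sentinel for an unbounded search radius (global analysis)
INFINITE = math.inf

_EDGE_JITTER = 1e-13
_TIE_TOL = 1e-9
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class RadiusSpec:
    """Search radius in the units of the active distance mode (m or deg)."""

    radius: float = INFINITE

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be positive (use INFINITE for global)")

    @property
    def finite(self) -> bool:
        return math.isfinite(self.radius)


@dataclass(frozen=True)
class DistanceSpec:
    mode: str = "metric"  # metric | angular | hybrid
    angular_weight_m_per_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("metric", "angular", "hybrid"):
            raise ValueError(f"unknown distance mode {self.mode!r}")
        if self.angular_weight_m_per_deg < 0:
            raise ValueError("angular_weight_m_per_deg must be >= 0")


@dataclass
class _Segment:
    coords: np.ndarray  # (k, 2) polyline vertices
    length: float
    weight: float
    # interior angular change (deg) of each half, split at the arc midpoint
    half_turn: tuple[float, float] = (0.0, 0.0)


@dataclass
class RoadGraph:
    """Snapped segment graph: segments, junctions, and geometric turn costs."""

    segments: list[_Segment]
    junction_coords: np.ndarray  # (m, 2)
    seg_junctions: np.ndarray  # (n, 2) junction index of each segment end

    def __post_init__(self) -> None:
        m = len(self.junction_coords)
        self.junction_segments: list[list[tuple[int, int]]] = [[] for _ in range(m)]
        for s, (j0, j1) in enumerate(self.seg_junctions):
            self.junction_segments[j0].append((s, 0))
            self.junction_segments[j1].append((s, 1))

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_coords)

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.segments])

    def is_connected(self) -> bool:
        if self.n_segments == 0:
            return False
        seen = {0}
        stack = [0]
        adj: list[set[int]] = [set() for _ in range(self.n_segments)]
        for members in self.junction_segments:
            for s, _ in members:
                for t, _ in members:
                    if s != t:
                        adj[s].add(t)
        while stack:
            s = stack.pop()
            for t in adj[s]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return len(seen) == self.n_segments

    def turn_deg(self, s: int, end_s: int, t: int, end_t: int) -> float:
        """Turn angle (deg) when exiting segment s via ``end_s`` onto t via ``end_t``.

        0 for a straight continuation, 180 for a full reversal; symmetric in
        the (segment, end) pair.
        """
        v_in = _end_direction(self.segments[s].coords, end_s, incoming=True)
        v_out = _end_direction(self.segments[t].coords, end_t, incoming=False)
        return _angle_deg(v_in, v_out)


@dataclass
class CentralityResult:
    nqpd: np.ndarray
    tpbt: np.ndarray
    radius: RadiusSpec = field(default_factory=RadiusSpec)
    distance: DistanceSpec = field(default_factory=DistanceSpec)


# --------------------------------------------------------------------------
# geometry helpers


def _polyline_length(coords: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(coords, axis=0).T)))


def _end_direction(coords: np.ndarray, end: int, incoming: bool) -> np.ndarray:
    """Unit direction at a segment end.

    ``incoming=True``: direction of travel when arriving at that end.
    ``incoming=False``: direction of travel when departing from that end.
    """
    if end == 0:
        v = coords[0] - coords[1] if incoming else coords[1] - coords[0]
    else:
        v = coords[-1] - coords[-2] if incoming else coords[-2] - coords[-1]
    n = np.hypot(*v)
    return v / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _half_interior_turns(coords: np.ndarray) -> tuple[float, float]:
    """Cumulative |direction change| (deg) on each side of the arc midpoint."""
    if len(coords) == 2:
        return (0.0, 0.0)
    seg_vec = np.diff(coords, axis=0)
    seg_len = np.hypot(*seg_vec.T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    half = cum[-1] / 2.0
    turn0 = turn1 = 0.0
    for i in range(1, len(coords) - 1):
        a = _angle_deg(seg_vec[i - 1] / seg_len[i - 1], seg_vec[i] / seg_len[i])
        if cum[i] <= half:
            turn0 += a
        else:
            turn1 += a
    return (turn0, turn1)


# --------------------------------------------------------------------------
# graph construction


def build_graph(
    polylines,
    snap_tol_m: float = 0.5,
    weights=None,
) -> RoadGraph:
    """Snap polyline endpoints into junctions and build the segment graph.

    Endpoints within ``snap_tol_m`` of each other merge into one junction
    (single-linkage). Geometric crossings that share no endpoint are NOT
    split — the graph is deliberately not planarized, matching segment-based
    network analysis practice. Zero-length polylines are rejected.
    """
    coords_list = []
    for pl in polylines:
        c = np.asarray(getattr(pl, "coords", pl), dtype=float)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] != 2:
            raise ValueError("each polyline needs >= 2 (x, y) vertices")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinates in polyline")
        coords_list.append(c)
    if not coords_list:
        raise ValueError("empty polyline collection")

    lengths = [_polyline_length(c) for c in coords_list]
    bad = [i for i, L in enumerate(lengths) if L <= 0]
    if bad:
        raise ValueError(f"zero-length polylines at indices {bad}")

    if weights is None:
        weights = np.ones(len(coords_list))
    weights = np.asarray(weights, dtype=float)

    # single-linkage clustering of endpoints within the snap tolerance
    endpoints = np.array([c[0] for c in coords_list] + [c[-1] for c in coords_list])
    n_pts = len(endpoints)
    parent = list(range(n_pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    from scipy.spatial import cKDTree

    tree = cKDTree(endpoints)
    for i, j in tree.query_pairs(snap_tol_m):
        union(i, j)

    roots: dict[int, int] = {}
    labels = np.empty(n_pts, dtype=int)
    for i in range(n_pts):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    n_j = len(roots)
    junction_coords = np.zeros((n_j, 2))
    counts = np.zeros(n_j)
    for i, lab in enumerate(labels):
        junction_coords[lab] += endpoints[i]
        counts[lab] += 1
    junction_coords /= counts[:, None]

    n_seg = len(coords_list)
    seg_junctions = np.column_stack([labels[:n_seg], labels[n_seg:]])

    segments = [
        _Segment(
            coords=c,
            length=L,
            weight=float(w),
            half_turn=_half_interior_turns(c),
        )
        for c, L, w in zip(coords_list, lengths, weights)
    ]
    return RoadGraph(segments, junction_coords, seg_junctions)


# --------------------------------------------------------------------------
# midpoint-expanded directed search graph
#
# node encoding (int):  4*s + k  where k = 0: "entered s via end 0",
# 1: "entered s via end 1", 2: "about to exit s via end 0",
# 3: "about to exit s via end 1".  A full traversal of s entering at end e
# visits IN(s, e) -> OUT(s, 1-e).  The virtual source of a run is node -1.


def _IN(s: int, e: int) -> int:
    return 4 * s + e


def _OUT(s: int, e: int) -> int:
    return 4 * s + 2 + e


def _mode_costs(graph: RoadGraph, dist: DistanceSpec):
    """Per-mode half-segment cost and turn-cost scale."""
    mode = dist.mode
    w_ang = dist.angular_weight_m_per_deg

    def half(s: int, e: int) -> float:
        seg = graph.segments[s]
        if mode == "metric":
            return seg.length / 2.0
        if mode == "angular":
            return seg.half_turn[e]
        return seg.length / 2.0 + w_ang * seg.half_turn[e]

    if mode == "metric":
        turn_scale = 0.0
    elif mode == "angular":
        turn_scale = 1.0
    else:
        turn_scale = w_ang
    return half, turn_scale


def _build_adjacency(graph: RoadGraph, dist: DistanceSpec):
    """Directed adjacency of the midpoint expansion: node -> [(node, w)]."""
    half, turn_scale = _mode_costs(graph, dist)
    adj: dict[int, list[tuple[int, float]]] = {}

    def add(u: int, v: int, w: float) -> None:
        adj.setdefault(u, []).append((v, w + _EDGE_JITTER))

    for s in range(graph.n_segments):
        # internal edges: no mid-segment U-turns
        add(_IN(s, 0), _OUT(s, 1), 0.0)
        add(_IN(s, 1), _OUT(s, 0), 0.0)
    for members in graph.junction_segments:
        for s, e_s in members:
            for t, e_t in members:
                if s == t:
                    continue
                turn = graph.turn_deg(s, e_s, t, e_t) if turn_scale else 0.0
                add(
                    _OUT(s, e_s),
                    _IN(t, e_t),
                    half(s, e_s) + turn_scale * turn + half(t, e_t),
                )
    return adj


def _shortest_dists(adj, source: int, cutoff: float) -> dict[int, float]:
    """Plain Dijkstra from the midpoint of ``source``; both exit directions
    of the source segment start at distance 0."""
    dist: dict[int, float] = {}
    heap: list[tuple[float, int]] = []
    for e in (0, 1):
        v = _OUT(source, e)
        dist[v] = 0.0
        heapq.heappush(heap, (0.0, v))
    done: set[int] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, w in adj.get(u, ()):
            nd = d + w
            if nd <= cutoff and nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _tight_dag(adj, dist: dict[int, float]):
    """Tight-edge DAG of the shortest-path forest and its topological order.

    An edge (u, v) is tight when d(u) + w == d(v) within the tie tolerance;
    geodesic counts (sigma) are propagated in topological order so that
    equal-cost geodesics are enumerated exactly regardless of float noise in
    the individual edge sums.
    """
    preds: dict[int, list[int]] = {v: [] for v in dist}
    succs: dict[int, list[int]] = {v: [] for v in dist}
    indeg: dict[int, int] = {v: 0 for v in dist}
    for u, du in dist.items():
        for v, w in adj.get(u, ()):
            dv = dist.get(v)
            if dv is not None and abs(du + w - dv) <= _TIE_TOL:
                preds[v].append(u)
                succs[u].append(v)
                indeg[v] += 1

    # Kahn topological sort; sources of the DAG are the run's start nodes
    queue = [v for v, k in indeg.items() if k == 0]
    order: list[int] = []
    while queue:
        u = queue.pop()
        order.append(u)
        for v in succs[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    if len(order) != len(dist):  # pragma: no cover - degenerate geometry
        raise RuntimeError("tight-edge graph is cyclic (degenerate geometry)")

    sigma: dict[int, float] = {}
    for v in order:
        if not preds[v]:
            sigma[v] = 1.0
        else:
            sigma[v] = sum(sigma[u] for u in preds[v])
    return preds, order, sigma


def _arrival(dist: dict[int, float], z: int) -> float:
    d0 = dist.get(_IN(z, 0), math.inf)
    d1 = dist.get(_IN(z, 1), math.inf)
    return min(d0, d1)


def _cutoff(radius: RadiusSpec) -> float:
    if not radius.finite:
        return math.inf
    return radius.radius + _TIE_TOL * (1.0 + radius.radius)


def segment_distance(
    graph: RoadGraph, x: int, y: int, dist_spec: DistanceSpec | None = None
) -> float:
    """Least-cost midpoint-to-midpoint network distance between segments.

    d(x, x) = 0; unreachable pairs return +inf.
    """
    dist_spec = dist_spec or DistanceSpec()
    n = graph.n_segments
    if not (0 <= x < n and 0 <= y < n):
        raise KeyError(f"segment id out of range (n={n})")
    if x == y:
        return 0.0
    adj = _build_adjacency(graph, dist_spec)
    dist = _shortest_dists(adj, x, math.inf)
    return _arrival(dist, y)


def closeness(
    graph: RoadGraph,
    radius: RadiusSpec | None = None,
    dist_spec: DistanceSpec | None = None,
) -> np.ndarray:
    """Radius-limited closeness NQPD for every segment."""
    radius = radius or RadiusSpec()
    dist_spec = dist_spec or DistanceSpec()
    if graph.n_segments == 0:
        raise ValueError("empty graph")
    adj = _build_adjacency(graph, dist_spec)
    cut = _cutoff(radius)
    W = graph.weights()
    out = np.zeros(graph.n_segments)
    zero_hits = 0
    for x in range(graph.n_segments):
        dist = _shortest_dists(adj, x, cut)
        acc = 0.0
        for y in range(graph.n_segments):
            if y == x:
                continue
            d = _arrival(dist, y)
            if d > cut:
                continue
            if d <= _ZERO_TOL:
                zero_hits += 1
                continue
            acc += W[y] / d
        out[x] = acc
    if zero_hits:
        warnings.warn(
            f"{zero_hits} segment pair(s) at zero network distance "
            "excluded from closeness",
            stacklevel=2,
        )
    return out


def betweenness(
    graph: RoadGraph,
    radius: RadiusSpec | None = None,
    dist_spec: DistanceSpec | None = None,
) -> np.ndarray:
    """Radius-limited betweenness TPBt for every segment.

    Equal-cost geodesics split the origin-destination count equally; the
    strictly-interior contribution is accumulated with a Brandes dependency
    sweep over the midpoint expansion, and each (y, z) pair credits 0.5 to
    both of its endpoint segments.
    """
    radius = radius or RadiusSpec()
    dist_spec = dist_spec or DistanceSpec()
    n = graph.n_segments
    if n == 0:
        raise ValueError("empty graph")
    adj = _build_adjacency(graph, dist_spec)
    cut = _cutoff(radius)
    W = graph.weights()
    tpbt = np.zeros(n)

    for y in range(n):
        dist = _shortest_dists(adj, y, cut)
        preds, order, sigma = _tight_dag(adj, dist)

        targets: list[int] = []
        for z in range(n):
            if z != y and _arrival(dist, z) <= cut:
                targets.append(z)
        total_weight = W[y] + sum(W[z] for z in targets)
        if not targets or total_weight <= 0:
            continue

        # per-expanded-node geodesic-endpoint mass
        base: dict[int, float] = {}
        for z in targets:
            g = W[z] / total_weight
            dz = _arrival(dist, z)
            nodes = [
                _IN(z, f)
                for f in (0, 1)
                if dist.get(_IN(z, f), math.inf) <= dz + _TIE_TOL
            ]
            s_tot = sum(sigma[v] for v in nodes)
            for v in nodes:
                base[v] = base.get(v, 0.0) + g * sigma[v] / s_tot
            # endpoint OD convention: x = y and x = z each get 0.5
            tpbt[y] += 0.5 * g
            tpbt[z] += 0.5 * g

        delta: dict[int, float] = {}
        for w_node in reversed(order):
            dw = delta.get(w_node, 0.0) + base.get(w_node, 0.0)
            if dw == 0.0:
                continue
            for u in preds[w_node]:
                delta[u] = delta.get(u, 0.0) + sigma[u] / sigma[w_node] * dw

        # a geodesic traverses segment s fully iff it passes an OUT node of s
        for s in range(n):
            if s == y:
                continue
            tpbt[s] += delta.get(_OUT(s, 0), 0.0) + delta.get(_OUT(s, 1), 0.0)

    return tpbt


def centrality(
    graph: RoadGraph,
    radius: RadiusSpec | None = None,
    dist_spec: DistanceSpec | None = None,
) -> CentralityResult:
    """Convenience wrapper computing both centralities."""
    radius = radius or RadiusSpec()
    dist_spec = dist_spec or DistanceSpec()
    return CentralityResult(
        nqpd=closeness(graph, radius, dist_spec),
        tpbt=betweenness(graph, radius, dist_spec),
        radius=radius,
        distance=dist_spec,
    )
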