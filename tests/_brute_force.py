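"""Independent brute-force oracle for segment-network centralities.

Enumerates ALL segment-simple routes between segment midpoints by exhaustive
depth-first search with cost pruning, entirely independent of the package's
Dijkstra/dependency-sweep implementation. A route is a sequence of
(segment, entry_end) steps; its cost is assembled directly from segment
lengths, per-half interior turns and the junction turn table. Closeness and
betweenness are then computed from the literal definitions: a sum of
weight/distance over in-radius pairs, and an average over the enumerated
equal-cost geodesics of each ordered pair (interior segments count 1,
endpoints 0.5, ties split equally).
"""

from __future__ import annotations

import math

TOL = 1e-9


def _half_cost(graph, s, e, mode, w_ang):
    seg = graph.segments[s]
    if mode == "metric":
        return seg.length / 2.0
    if mode == "angular":
        return seg.half_turn[e]
    return seg.length / 2.0 + w_ang * seg.half_turn[e]


def _full_cost(graph, s, mode, w_ang):
    return _half_cost(graph, s, 0, mode, w_ang) + _half_cost(graph, s, 1, mode, w_ang)


def _turn_cost(graph, s, e_s, t, e_t, mode, w_ang):
    if mode == "metric":
        return 0.0
    turn = graph.turn_deg(s, e_s, t, e_t)
    return turn if mode == "angular" else w_ang * turn


def geodesics(graph, x, y, mode="metric", w_ang=1.0):
    """(best_cost, list of geodesic segment sequences) from x to y.

    Each geodesic is the tuple of segment ids visited, x and y included.
    Ties within 1e-9 of the optimum are all returned; x == y gives cost 0.
    """
    if x == y:
        return 0.0, [(x,)]
    best = [math.inf]
    found: list[tuple[float, tuple[int, ...]]] = []

    def step(s, entry_end, cost, seq, used):
        if cost > best[0] + TOL:
            return
        exit_end = 1 - entry_end
        junction = graph.seg_junctions[s][exit_end]
        for t, e_t in graph.junction_segments[junction]:
            if t in used:
                continue
            c = cost + _turn_cost(graph, s, exit_end, t, e_t, mode, w_ang)
            if t == y:
                c_final = c + _half_cost(graph, t, e_t, mode, w_ang)
                if c_final < best[0] - TOL:
                    best[0] = c_final
                found.append((c_final, tuple(seq) + (t,)))
            else:
                c_on = c + _full_cost(graph, t, mode, w_ang)
                if c_on <= best[0] + TOL:
                    step(t, e_t, c_on, seq + [t], used | {t})

    for exit_end in (0, 1):
        step(x, 1 - exit_end, _half_cost(graph, x, exit_end, mode, w_ang), [x], {x})

    routes = [seq for c, seq in found if c <= best[0] + TOL]
    return best[0], routes


def brute_closeness(graph, radius=math.inf, mode="metric", w_ang=1.0):
    n = graph.n_segments
    w = [seg.weight for seg in graph.segments]
    out = [0.0] * n
    cut = radius + TOL * (1.0 + radius) if math.isfinite(radius) else math.inf
    for x in range(n):
        for y in range(n):
            if y == x:
                continue
            d, _ = geodesics(graph, x, y, mode, w_ang)
            if d <= cut and d > 1e-12:
                out[x] += w[y] / d
    return out


def brute_betweenness(graph, radius=math.inf, mode="metric", w_ang=1.0):
    n = graph.n_segments
    w = [seg.weight for seg in graph.segments]
    cut = radius + TOL * (1.0 + radius) if math.isfinite(radius) else math.inf
    dist = [[math.inf] * n for _ in range(n)]
    routes = [[None] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a != b:
                dist[a][b], routes[a][b] = geodesics(graph, a, b, mode, w_ang)
    out = [0.0] * n
    for y in range(n):
        targets = [z for z in range(n) if z != y and dist[y][z] <= cut]
        total_weight = w[y] + sum(w[z] for z in targets)
        for z in targets:
            g = w[z] / total_weight
            out[y] += 0.5 * g
            out[z] += 0.5 * g
            rts = routes[y][z]
            for seq in rts:
                for s in seq[1:-1]:
                    out[s] += g / len(rts)
    return out
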