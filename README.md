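# epirisk

Spatial risk zoning for person-to-person epidemic disasters in large cities.

During a human-to-human epidemic, the places most likely to seed and spread
infection are the places where people concentrate: dense residential areas,
bright commercial districts at night, through-traffic corridors and clusters
of everyday facilities. `epirisk` turns that idea into a reproducible
quantitative pipeline. It computes five spatial indicators, aggregates them
onto a 1 km analysis grid ("fishnet"), combines them with objective
entropy-method weights, and classifies the composite into five risk grades
whose top grade defines the city's epidemic-risk spatial structure.

The five indicators:

| indicator | meaning | source layer |
|---|---|---|
| `pop` | daytime crowd density | population raster (~100 m) |
| `light` | night-time activity | night-light raster (~500 m) |
| `nqpd` | road closeness (accessibility of a segment) | road centerlines |
| `tpbt` | road betweenness (through-traffic potential) | road centerlines |
| `mixdens` | functional mixed kernel density of POIs | categorized POI points |

## The models at the core

**Segment-network centrality.** The road network is analysed per segment
(sDNA-style), with distances measured midpoint-to-midpoint along the network
under a metric, angular (cumulative turn degrees) or hybrid cost. Within a
search radius R,

    NQPD(x) = Σ_{y : d(x,y) ≤ R}  W(y) / d(x,y)

    TPBt(x) = Σ_y Σ_{z ∈ R_y}  OD(y,z,x) · W(z) / TotalWeight(y)

where OD(y,z,x) is 1 when x lies strictly on the y–z geodesic, 0.5 when
x is y or z, equal-cost geodesics split OD equally, and TotalWeight(y) sums
the segment weights reachable from y (y included). The solver is verified
against exhaustive geodesic enumeration to 1e-9.

**Kernel density.** Each POI category gets a quartic-kernel density surface

    f(s) = Σ_i w_i · 3/(π r²) · (1 − d_i²/r²)²,   d_i < r

with the rule-of-thumb radius
`H = 0.9 · min( sqrt(1/ln 2)·Dm, SD ) · n^(−0.2)` (Dm = median distance,
SD = standard distance of the points about their mean center). The six
category surfaces are blended into the functional mixed density using
survey-derived public-dependence weights: a category's weight is the mean of
its subcategories' Likert means, normalized across the six categories.

**Entropy weighting and classification.** Each indicator column is min-max
normalized; with p_ij = x_ij / Σ_i x_ij,

    E_j = −(1/ln n) Σ_i p_ij ln p_ij ,    D_j = (1 − E_j) / (k − Σ_j E_j)

so that more dispersed indicators carry more weight and Σ D_j = 1. The
composite score Σ_j D_j x_ij is cut into five grades by geometric intervals
(class widths follow a geometric series; the common ratio is selected by a
deterministic search balancing class counts). Class 1 — the highest risk —
is decomposed into 8-connected components labelled *main* (largest),
*belt* (elongated chains), *secondary* and *point*.

Because the original study's inputs (population grid, night lights, OSM
roads, commercial POI database, outbreak site list) are proprietary, the
package ships a synthetic-city generator that plants known hotspots into
every layer, so the whole chain is testable end-to-end: a correct pipeline
must rediscover the planted hotspots as class-1 cells.

## Worked example

```python
from epirisk import RunConfig, SyntheticCityConfig, run_pipeline

res = run_pipeline(RunConfig(synthetic=SyntheticCityConfig(seed=1)))
print(res.weight_vector.as_dict())
print(res.structure.counts)
print(res.validation.coverage_top2)
```

prints (seed 1, default 8 km × 8 km city, 64 fishnet cells, 163 road
segments, KDE bandwidth 483.2 m):

```
{'pop': 0.339, 'light': 0.295, 'nqpd': 0.0599, 'tpbt': 0.0974, 'mixdens': 0.2086}
{'main': 1, 'secondary': 0, 'belt': 0, 'point': 0}
0.92
```

Reading: the entropy method puts the most weight on population density
(0.339) because it is the most spatially concentrated indicator in this
city; the class-1 cells form a single main risk area around the planted
hotspots; and 92 of the 100 simulated outbreak sites fall in risk classes
1–2 — the same kind of site-overlap check used to validate the risk map
against observed high-risk locations.

The same run is available from the shell:

```bash
epirisk assess --config run.yaml     # full chain from one YAML config
epirisk synth --seed 1 --out-dir city/        # write the synthetic layers
epirisk network --roads city/roads.geojson --radius N --metric hybrid
epirisk weights --survey city/survey.csv
```

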