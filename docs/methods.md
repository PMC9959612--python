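# Methods

This note documents the models implemented in `epirisk`, the choices made
where the methodology is genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Segment-based network centrality

The unit of analysis is the road segment. Polyline endpoints within a snap
tolerance (default 0.5 m) merge into junctions by single-linkage clustering;
geometric crossings without a shared endpoint are deliberately **not**
planarized (an overpass is not an intersection), and duplicate parallel
segments are retained. Turn costs between adjacent segments are computed
from geometry: the angle (degrees, 0–180) between the incoming and outgoing
travel directions at the junction; curved polylines additionally carry the
cumulative direction change of each half of the segment.

Distance between two segments is the least-cost route between their
**midpoints**. The methodology leaves the section-distance convention
unstated; midpoint-to-midpoint is the standard segment-analysis convention
and is isolated in one place so it can be swapped. Each terminal segment
contributes half its length (and half-interior turn), intermediate segments
their full cost. Three modes are supported: `metric` (meters), `angular`
(degrees of turn) and `hybrid` (meters + `angular_weight_m_per_deg` ×
degrees, default 1.0 — the hybrid scale is not standardized, so it is a
config parameter).

Closeness NQPD sums W(y)/d(x,y) over in-radius segments (discrete analysis,
P = 1). Pairs at zero distance (coincident midpoints; any collinear pair in
the angular metric) are excluded with a warning, since 1/d diverges.

Betweenness TPBt needs geodesic multiplicities. The implementation expands
the network into a directed graph of "entered segment s via end e" /
"leaving s via end e" states, which structurally forbids mid-segment
U-turns, runs Dijkstra per source, extracts the tight-edge DAG (edges with
d(u) + w = d(v) within 1e-9), and accumulates the per-pair origin–destination
mass with a Brandes-style dependency sweep. Conventions, all unit-tested
against an independent exhaustive-enumeration oracle:

* OD = 1 for strictly interior segments, 0.5 for each endpoint of the pair,
  ties split equally among equal-cost geodesics;
* TotalWeight(y) includes y itself;
* every expanded edge carries a 1e-13 jitter so zero-cost transitions
  (straight-through continuations under the angular metric) cannot create
  cycles in the tight-edge DAG; the jitter is three orders of magnitude
  below the tie tolerance and does not affect reported values.

A search radius may be finite (meters or degrees, matching the mode) or
infinite (global analysis, the default used by the pipeline).

## Kernel density and the functional mix

The KDE kernel is the planar quartic (biweight), `3/(π r²)(1 − d²/r²)²`,
evaluated at grid cell centers — the kernel used by the standard GIS
point-density tools this workflow descends from; each kernel integrates to
its point weight, giving the mass-conservation test its exact target. The
bandwidth defaults to the rule of thumb
`H = 0.9·min(sqrt(1/ln 2)·Dm, SD)·n^(−0.2)`; in the pipeline one bandwidth
is computed from the pooled POI set and shared by all six category surfaces
(a single radius is also what the original workflow reports), which also
guarantees a common grid for the blend. Degenerate point sets (n < 2 or all
coincident) raise instead of guessing a bandwidth. The KDE grid cell
defaults to bandwidth/10, capped at the fishnet cell size.

The functional mixed density is a cellwise weighted sum of the six category
surfaces. Weights come from the Likert dependence survey: dependence index
`clip((mean − 3)/2, 0, 1)` (the linear rescale that reproduces 12 of the 13
published dependence values exactly; the transportation row prints 1.000
where the rescale gives 0.981 — treated as a printing/capping anomaly), and
category weight = mean of subcategory means normalized across the six
categories. Weight sums are validated, never silently renormalized.

## Fishnet aggregation

The fishnet tiles the boundary's bounding box with square cells (default
1000 m), anchored at the lower-left corner, ordered row-major; cells whose
overlap with the boundary has zero area are dropped. Attachment rules:

* rasters and density surfaces: statistic (default mean; sum available)
  over raster cells whose **centers** fall in the fishnet cell, nodata
  excluded — center-point inclusion makes the sum statistic exactly
  conservative;
* road segments: length-weighted mean of segment values over the pieces
  clipped to the cell (invariant to splitting segments);
* cells with no contributing data get 0 plus a `*_empty` flag, so the
  entropy step always sees a complete matrix.

Mean (not sum) is the default for population and night light because both
layers are density-like; the choice is a config switch.

## Entropy weights, composite, classification

All five indicators are treated as risk-increasing (positive orientation)
and min-max normalized per column; constant columns are flagged degenerate.
Entropy uses `p_ij = x_ij / Σ_i x_ij` without the common +ε shift
(`0·ln 0 := 0`); an all-zero column gets entropy 1 and weight 0. Weights
`D_j = (1 − E_j)/(k − Σ E_j)` sum to 1 identically. The composite is the
weighted sum of normalized indicators, bounded in [0, 1].

Geometric-interval classification: the proprietary implementation in
desktop GIS is undocumented, so the package uses a transparent stand-in
with the same intent — class widths form a geometric series
`w_m = w_1·g^(m−1)` spanning [min, max]; g is selected from a log-spaced
grid over [1/8, 8] (always containing g = 1, the equal-interval limit) by
minimizing the variance of per-class counts, ties to the smallest g. For
right-skewed score distributions this yields g > 1: narrow classes at the
low end, wide at the top. Boundary scores go to the riskier class; class 1
is the highest risk. Fewer than k distinct values fall back to quantile
breaks with a warning.

Spatial structure: 8-connected components of class-1 cells (diagonal
contact at 1 km cell scale is continuity; 4-connectivity is a config
option). The largest component is *main*; components whose principal-axis
extent ratio ≥ 4 and major length ≥ 8 cells are *belt*; others with ≥ 5
cells are *secondary*; the rest are *point*. The belt test precedes the
secondary test so an elongated 12-cell chain is a belt, not a secondary
area. Thresholds are configuration with these defaults; the source
methodology gives only the qualitative description.

Site validation assigns each observed high-risk site the class of its
containing cell and reports per-class counts plus the coverage fraction of
classes 1–2.

## Synthetic city: what it emulates

Defaults: 8 km × 8 km extent, 1 km road grid plus 3 diagonal arterials
routed through the hotspots, 3 hotspots (isotropic Gaussian, σ = 700 m) at
least 3σ apart, population raster 100 m cells (base 20, hotspot gain 400),
night light 500 m cells (base 5, gain 60), multiplicative lognormal noise
(σ = 0.2), 2000 POIs (70% clustered at hotspots, categories at the
published six-category inventory shares), 204 survey respondents, 100
validation sites (85% within 2σ of a hotspot, 15% uniform). One seeded
generator drives all draws in a documented order, so a config plus seed is
bit-reproducible.

Survey responses are the adjacent-integer mixture around each target mean:
exact expectation, standard deviation ≤ 0.5, so the n = 204 sample mean
stays within 0.15 of the target with large margin. Real Likert items are
noisier (published sds run up to ~1.3); the generator trades that realism
for a tight contract on the sample mean.

What passing tests show: the pipeline recovers planted, well-separated,
isotropic hotspots whose signal appears coherently in all five layers, at
desk scale (64 cells). What they do not show: performance on real cities —
anisotropic density ridges, coastline-constrained networks, heavy-tailed
POI clustering, registration error between layers and non-stationary noise
are all absent from the generator. The 20-seed recovery study (seeds 0–19)
gives 100% hotspot-cell class-1 recovery and mean class-1∪2 site coverage
0.855; the coverage figure sits close to its 0.85 design floor because 15%
of sites are uniform background by construction.

## Numerical choices and limitations

* Tie tolerance for equal-cost geodesics: 1e-9 (absolute, plus 1e-12
  relative on the radius test); edge jitter 1e-13.
* Radius tests are inclusive (d ≤ R within tolerance).
* Problem sizes in the shipped studies (64-cell fishnet, ~160 segments,
  2000 POIs, 20 seeds) were chosen so the full study runs in seconds while
  every stage still has non-trivial spatial structure.
* The betweenness tie-count equates geodesics with directed
  (segment, entry-end) sequences; routes re-traversing a segment are
  assumed never cost-optimal, which holds for positive lengths and
  non-degenerate geometry.
* No one-way streets, turn restrictions, continuous-space P(y), adaptive
  KDE bandwidths, network-constrained KDE or dasymetric population
  reallocation. Real-data ingestion expects a projected metric CRS;
  geographic coordinates are out of scope.
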