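# Methods

## Problem and model

The package estimates, for each health facility, the population that can
reach it within a travel cutoff over the actual transport network, and the
population that cannot reach any facility (the underserved). Three data
models carry the computation:

* **RoadNetwork** — an undirected planar graph in projected meters. Edges
  carry a physical length, a travel-mode set (`walk`, `drive`, `ferry`) and a
  class label (road, path, ferry line, railway, river). The graph is
  undirected: one-way restrictions, timetables, congestion and elevation are
  out of scope. Edge weight is length in meters for every mode; a time
  cutoff can be expressed by converting minutes to meters with a per-mode
  speed before calling the engine.
* **PopulationGrid** — a raster of non-negative integer person counts per
  cell (default 100 m), stratified by age band × sex using the WorldPop band
  convention (0, 1–4, 5–9, …, 80+). The per-cell total is always recomputed
  as the sum over strata and never trusted from disk.
* **CatchmentArea** — the covered edge portions within the cutoff plus the
  polygon obtained by buffering them.

## Catchment construction

A facility is snapped to the nearest point of the nearest mode-traversable
edge (ties by smallest edge id, for reproducibility). Facilities farther
than `max_snap_m` (default 500 m) from every traversable edge raise a
per-facility error that batch runs collect rather than propagate; a facility
whose nearest anchor is an isolated node degenerates to a buffer-radius disc
at that node. The off-network gap between facility and snap point is *not*
charged against the cutoff — standard service-area semantics.

Reachability splits the snapped edge at the snap offset into two traversable
half-edges joined at a temporary virtual node (never persisted) and runs
Dijkstra bounded by the cutoff. For an edge (u, v) of length L the covered
portion is the union of `[0, min(L, cutoff − d(u))]` from the u end and
`[max(0, L − (cutoff − d(v))), L]` from the v end (negative budgets are
empty); the source edge additionally receives the direct interval
`[offset − cutoff, offset + cutoff] ∩ [0, L]`, since travel there does not
pass through an endpoint.

Polygonization buffers every covered sub-segment, plus a disc at the snap
point, and dissolves the union. The buffer radius defaults to half the
raster cell size (50 m for a 100 m grid), tying polygon thickness directly
to raster resolution; buffers use round caps with 32-segment circles, fixed
for determinism. The straight-line baseline disc uses a finer 256-segment
approximation so its area matches πr² to well under 0.1% — it exists only
for comparison, and the network polygon is always contained in the disc of
radius cutoff + buffer + snap distance because network distance dominates
Euclidean distance.

## Zonal overlay and assignment

The default inclusion rule is **center**: a cell contributes its full count
iff its center lies inside the polygon, with a boundary center counting as
inside. This convention is what makes conservation exact: for any polygon
set, covered-by-union plus underserved equals the grid total as integers,
and polygons that tile the grid leave zero underserved. A **fraction** rule
(count × intersected area / cell area) is provided for area-weighted
analyses; it equals the center rule when polygon edges lie on cell
boundaries.

Overlapping catchments force a reporting choice the method itself does not
make, so both semantics are implemented and labelled in every output:

* **independent** (default) — each facility is credited with the zonal
  population of its own polygon; people in overlaps count toward every
  covering facility. Per-facility sums therefore bound the union population
  from above.
* **exclusive** — each covered cell goes to the covering facility with the
  smallest network distance from the cell center to the facility snap point,
  ties broken by smallest facility id. Facility populations plus the
  underserved total then partition the grid exactly.

The cell-to-facility distance for exclusive assignment is computed from the
facility's reachability tree: the minimum over anchors (the snap point at
distance 0 and every reached node at its network distance) of network
distance plus the straight-line hop from anchor to cell center. On the
covered network this equals true network distance; for off-network cell
centers it degrades to the Euclidean distance to the snap point — a
documented approximation, adequate at the half-cell buffer scale.

Case points are assigned by the same rule; per-facility rates are
cases / population × rate_basis (default 100,000), with zero-population
facilities reporting a missing rate rather than dividing by zero.

## Summary and resource arithmetic

Group rows report N, total, mean, sample SD (divisor N−1), min and max of
per-facility populations. The pooled variance of combined rows is
`[Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m)²]/(N−1)`; this convention was chosen because it is
the one under which published continental pilot rows pool exactly to their
printed grand-total row, which the acceptance script recomputes. Display
rounding is nearest integer, half away from zero; all arithmetic runs on
unrounded values and rounds only at output.

The resource formulas are this package's minimal parameterization of the
resource-estimation section of a standard six-part microplan (the other five
sections — cold chain, operations, supervision, recording, monitoring — are
named placeholders only):

* target = covered population summed over the configured target strata;
* doses = ⌈target × doses_per_person⌉;
* vials = ⌈doses × (1 + wastage_fraction) / vial_doses⌉;
* teams = ⌈doses / (team_daily_throughput × campaign_days)⌉.

All are integer, non-negative, monotone in the target population, and totals
are per-facility sums.

## Synthetic data: what it emulates and what it does not

The generator stands in for three external sources: a dasymetric population
raster (WorldPop-like), an OSM-like transport network, and a facility master
list. One seed drives independent per-component sub-streams (settlements,
network, grid, facilities, cases), so regenerating one component never
shifts another.

* **Population**: cell totals are Poisson with rate
  λ(cell) = background + Σₖ A·exp(−dₖ²/2σ²) over uniformly placed settlement
  centers (defaults: A = 50 persons/cell peak, σ = 500 m, background = 0.05
  persons/cell on a 100 m grid — a small rural town scale); strata are a
  multinomial split of each total using a smooth declining age pyramid
  (band weight ∝ width × exp(−0.02 × mid-age), sexes even). Counts are
  integer and non-negative by construction; a negative-binomial
  (overdispersed) option is deliberately out of scope.
* **Network**: a jittered lattice with ~10% diagonal shortcuts rather than a
  random geometric graph, so shortest paths measurably exceed straight-line
  distances — the regime in which network catchments differ most from
  straight-line discs. Components beyond the largest are rewired onto it via
  nearest node pairs until at least 90% of nodes are connected (the
  construction ends fully connected). Edge mix: 78% road (walk|drive),
  20% footpath (walk), 2% ferry.
* **Facilities**: cells drawn with probability proportional to population,
  placed on the nearest network point plus a small offset well inside the
  snap radius — facilities sit in settlements near roads and are snappable
  by construction.
* **Cases**: per catchment, Poisson with mean rate × population/1,000,
  placed uniformly inside the polygon by rejection sampling.

What passing tests on this data do **not** show: real road networks have
heavy-tailed edge lengths, bridges and barriers; real gridded populations
have spatial autocorrelation from covariate models, not independent Poisson
noise; real facility lists are incomplete and mislocated. Results on
synthetic scenes validate the pipeline's arithmetic and invariants, not the
accuracy of any real-world coverage estimate.

## Numerical choices and degenerate inputs

* Interval unions merge sub-ranges closer than 1e-12 m; generated edge
  lengths equal Euclidean endpoint distances to 1e-9.
* Snapping and assignment ties break by smallest edge/facility id.
* Geometry determinism is asserted as symmetric-difference area < 1e-6 m²,
  since vertex order may legitimately differ.
* Degenerate inputs: zero-area extents, non-positive cutoffs/buffers, empty
  mode sets, self-loops, dangling edge endpoints and negative counts are
  rejected with typed errors; an isolated source yields a tree containing
  only the virtual source; empty coverage writes header-only CSVs.
* Problem sizes in the test-suite and acceptance script (2.5–10 km extents,
  30–100 network nodes, 3–5 facilities, 2 strata where the pyramid is not
  under test, 50 random scenes, 200 oracle graphs, 200 case-simulation
  seeds) were chosen so each statistical check has at least 3-standard-error
  resolution while the whole suite completes in seconds.

## Known limitations

* The exclusive-assignment distance is exact only on the covered network;
  off-network cells use the Euclidean fallback described above.
* The fraction rule loops over candidate cells in Python; it is intended for
  polygon-scale queries, not whole-continent rasters.
* Geographic (lat/lon) rasters must be projected to planar meters before
  ingestion; the manifest records but does not enforce this.
* No GeoTIFF/netCDF ingestion; the Esri ASCII grid is the reference dialect.
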