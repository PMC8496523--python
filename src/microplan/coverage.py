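"""Link population to facilities through catchments; underserved areas; case rates.

Two assignment semantics are offered because overlapping catchments force a
choice the method itself does not make:

``independent``
    Each facility is credited with the full zonal population of its own
    polygon. People inside two overlapping catchments count toward both
    facilities, so per-facility sums can exceed the union population.
    This is the default for reporting.

``exclusive``
    Every covered cell is credited to exactly one covering facility — the
    one with the smallest network distance from the cell center to the
    facility's snap point, ties broken by smallest facility_id. Together
    with the underserved cells this partitions the grid, so facility
    populations plus the underserved total equal the grid total exactly
    (center rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import ConsistencyError, InvalidConfigError
from .grid import PopulationGrid, center_mask, uncovered_cells, zonal_population


@dataclass
class FacilityCoverage:
    facility_id: str
    population_total: float
    population_by_stratum: dict
    n_cells: int
    assignment: str


@dataclass
class CoverageResult:
    per_facility: list
    underserved_total: int
    underserved_by_stratum: dict
    underserved_mask: np.ndarray
    assignment: str
    cutoff_m: float
    mode: str
    rule: str = "center"


def make_distance_lookup(network, catchments) -> "NetworkAnchorLookup":
    """Build the default cell-to-facility network distance lookup."""
    return NetworkAnchorLookup(network, catchments)


class NetworkAnchorLookup:
    """Default distance lookup built from a network and its catchments.

    Anchors each facility at its snap point (distance 0) and every node its
    reachability tree reached (at its network distance); the distance to a
    query point is min over anchors of network distance + Euclidean hop.
    """

    def __init__(self, network, catchments):
        self._anchors = {}
        for c in catchments:
            if c.tree is None or c.source is None:
                raise InvalidConfigError(
                    f"catchment {c.facility_id!r} lacks a reachability tree; "
                    "exclusive assignment needs network-built catchments")
            xs, ys, ds = [c.source.snapped_x], [c.source.snapped_y], [0.0]
            for node_id, d in c.tree.node_distance.items():
                nx_, ny_ = network.node_xy(node_id)
                xs.append(nx_)
                ys.append(ny_)
                ds.append(d)
            self._anchors[c.facility_id] = (np.asarray(xs), np.asarray(ys), np.asarray(ds))

    def __call__(self, facility_id: str, x: float, y: float) -> float:
        xs, ys, ds = self._anchors[facility_id]
        return float(np.min(np.hypot(xs - x, ys - y) + ds))


def compute_coverage(catchments, grid: PopulationGrid, assignment: str = "independent",
                     distance_lookup=None, rule: str = "center") -> CoverageResult:
    """Per-facility population under the chosen assignment rule.

    ``exclusive`` requires a ``distance_lookup(facility_id, x, y) -> meters``
    callable (see :func:`make_distance_lookup`).
    """
    if assignment not in ("independent", "exclusive"):
        raise InvalidConfigError(f"unknown assignment {assignment!r}")
    cutoff = catchments[0].cutoff_m if catchments else float("nan")
    mode = catchments[0].mode if catchments else ""
    mask_und, und_total, und_by = uncovered_cells(grid, [c.polygon for c in catchments])

    per_facility = []
    if assignment == "independent":
        for c in sorted(catchments, key=lambda c: c.facility_id):
            z = zonal_population(grid, c.polygon, rule=rule)
            per_facility.append(FacilityCoverage(
                facility_id=c.facility_id, population_total=z.population_total,
                population_by_stratum=z.population_by_stratum,
                n_cells=z.n_cells, assignment=assignment))
    else:
        if distance_lookup is None:
            raise InvalidConfigError("exclusive assignment requires a distance_lookup")
        owner = _exclusive_owner_grid(catchments, grid, distance_lookup)
        ordered = sorted(catchments, key=lambda c: c.facility_id)
        for c in ordered:
            sel = owner == c.facility_id
            by = {k: int(arr[sel].sum()) for k, arr in grid.strata.items()}
            per_facility.append(FacilityCoverage(
                facility_id=c.facility_id, population_total=sum(by.values()),
                population_by_stratum=by, n_cells=int(sel.sum()), assignment=assignment))
    return CoverageResult(per_facility=per_facility, underserved_total=und_total,
                          underserved_by_stratum=und_by, underserved_mask=mask_und,
                          assignment=assignment, cutoff_m=cutoff, mode=mode, rule=rule)


def _exclusive_owner_grid(catchments, grid, distance_lookup) -> np.ndarray:
    """Per-cell owning facility id under the exclusive rule ('' = uncovered)."""
    owner = np.full((grid.nrows, grid.ncols), "", dtype=object)
    best = np.full((grid.nrows, grid.ncols), np.inf)
    X, Y = grid.cell_centers()
    for c in sorted(catchments, key=lambda c: c.facility_id):
        m = center_mask(grid, c.polygon)
        rows, cols = np.nonzero(m)
        for r, col in zip(rows, cols):
            d = distance_lookup(c.facility_id, X[r, col], Y[r, col])
            # strict < keeps the smallest facility_id on ties (sorted order)
            if d < best[r, col]:
                best[r, col] = d
                owner[r, col] = c.facility_id
    return owner


def identify_underserved(catchments, grid: PopulationGrid):
    """Population outside every catchment: (mask, total, by-stratum)."""
    return uncovered_cells(grid, [c.polygon for c in catchments])


# ---------------------------------------------------------------------------
# Case points
# ---------------------------------------------------------------------------

@dataclass
class CasePointSet:
    """Point events (cases, doses, ...) with optional facility assignment."""

    points: list  # of (x, y, dict attributes)
    assigned_facility: list = field(default_factory=list)  # facility_id or None

    def __len__(self):
        return len(self.points)


@dataclass
class CaseRateResult:
    per_facility: dict  # facility_id -> {case_count, population_total, rate or None}
    rate_basis: float


def assign_cases(cases: CasePointSet, catchments, distance_lookup=None) -> CasePointSet:
    """Assign each point to its exclusive-rule facility, or None if uncovered.

    Points inside exactly one polygon go to that facility; points in overlap
    zones go to the facility with smallest network distance (ties by id).
    """
    assigned = []
    ordered = sorted(catchments, key=lambda c: c.facility_id)
    for (x, y, _attrs) in cases.points:
        covering = [c for c in ordered if shapely.intersects_xy(c.polygon, x, y)]
        if not covering:
            assigned.append(None)
        elif len(covering) == 1 or distance_lookup is None:
            assigned.append(covering[0].facility_id)
        else:
            best = min(covering, key=lambda c: (distance_lookup(c.facility_id, x, y), c.facility_id))
            assigned.append(best.facility_id)
    return CasePointSet(points=list(cases.points), assigned_facility=assigned)


def case_rates(assigned_cases: CasePointSet, coverage: CoverageResult,
               rate_basis: float = 100_000.0) -> CaseRateResult:
    """Per-facility case rate = cases / population x rate_basis.

    Facilities with zero population report a missing (None) rate rather than
    dividing by zero.
    """
    counts = {fc.facility_id: 0 for fc in coverage.per_facility}
    for fid in assigned_cases.assigned_facility:
        if fid is None:
            continue
        if fid not in counts:
            raise ConsistencyError(f"case assigned to unknown facility {fid!r}")
        counts[fid] += 1
    per = {}
    for fc in coverage.per_facility:
        n = counts[fc.facility_id]
        pop = fc.population_total
        rate = None if pop == 0 else n / pop * rate_basis
        per[fc.facility_id] = {"case_count": n, "population_total": pop, "rate": rate}
    return CaseRateResult(per_facility=per, rate_basis=rate_basis)


def cases_to_geojson(cases: CasePointSet, path=None) -> dict:
    import json
    from pathlib import Path

    feats = []
    assigned = cases.assigned_facility or [None] * len(cases.points)
    for (x, y, attrs), fid in zip(cases.points, assigned):
        props = dict(attrs)
        props["assigned_facility"] = fid
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point", "coordinates": [x, y]},
                      "properties": props})
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
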