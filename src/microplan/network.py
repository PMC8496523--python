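"""Transport-network model and cutoff-bounded reachability.

The network is an undirected planar graph in projected meters. Edges carry a
physical length, a set of travel modes (``walk``, ``drive``, ``ferry``) and a
class label (road, path, ferry line, railway, river). Catchment analysis
snaps each facility onto its nearest traversable edge and runs a
single-source shortest-path search bounded by a distance cutoff, splitting
the snapped edge at the snap point so travel can start mid-edge.

Distances are network distances in meters. The off-network gap between the
facility point and its snap point is *not* charged against the cutoff by
default, matching standard service-area semantics.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import ValidationError, UnreachableFacilityError

MODES = frozenset({"walk", "drive", "ferry"})
EDGE_CLASSES = frozenset({"road", "path", "ferry_line", "railway", "river"})


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    x: float
    y: float


@dataclass(frozen=True)
class NetworkEdge:
    edge_id: str
    u: str
    v: str
    length_m: float
    modes: frozenset
    edge_class: str = "road"

    def __post_init__(self):
        if self.length_m <= 0:
            raise ValidationError(f"edge {self.edge_id!r}: length_m must be positive, got {self.length_m}")
        if self.u == self.v:
            raise ValidationError(f"edge {self.edge_id!r}: self-loop {self.u!r}")
        if not self.modes:
            raise ValidationError(f"edge {self.edge_id!r}: empty mode set")
        bad = set(self.modes) - MODES
        if bad:
            raise ValidationError(f"edge {self.edge_id!r}: unknown modes {sorted(bad)}")


class RoadNetwork:
    """Undirected transport network with per-mode shortest-path support."""

    def __init__(self, nodes: Iterable[NetworkNode], edges: Iterable[NetworkEdge]):
        self.nodes: dict[str, NetworkNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise ValidationError(f"duplicate node id {n.node_id!r}")
            if not (math.isfinite(n.x) and math.isfinite(n.y)):
                raise ValidationError(f"node {n.node_id!r}: non-finite coordinates")
            self.nodes[n.node_id] = n
        self.edges: dict[str, NetworkEdge] = {}
        dangling = []
        for e in edges:
            if e.edge_id in self.edges:
                raise ValidationError(f"duplicate edge id {e.edge_id!r}")
            for end in (e.u, e.v):
                if end not in self.nodes:
                    dangling.append((e.edge_id, end))
            self.edges[e.edge_id] = e
        if dangling:
            raise ValidationError(f"edges reference unknown nodes: {dangling}")
        self._graphs: dict[str, nx.Graph] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mode_edges(self, mode: str) -> list[NetworkEdge]:
        return [e for e in self.edges.values() if mode in e.modes]

    def graph(self, mode: str) -> nx.Graph:
        """networkx view restricted to edges traversable by ``mode`` (cached)."""
        if mode not in self._graphs:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for e in self.edges.values():
                if mode in e.modes:
                    # parallel edges: keep the shortest, Dijkstra never uses longer ones
                    if g.has_edge(e.u, e.v) and g[e.u][e.v]["length"] <= e.length_m:
                        continue
                    g.add_edge(e.u, e.v, length=e.length_m, edge_id=e.edge_id)
            self._graphs[mode] = g
        return self._graphs[mode]

    def node_xy(self, node_id: str) -> tuple[float, float]:
        n = self.nodes[node_id]
        return n.x, n.y

    def edge_point(self, edge_id: str, offset_m: float) -> tuple[float, float]:
        """Planar point at ``offset_m`` along an edge (proportional to length_m)."""
        e = self.edges[edge_id]
        t = min(max(offset_m / e.length_m, 0.0), 1.0)
        ux, uy = self.node_xy(e.u)
        vx, vy = self.node_xy(e.v)
        return ux + t * (vx - ux), uy + t * (vy - uy)


@dataclass(frozen=True)
class NetworkLocation:
    """A point anchored onto a network edge."""

    edge_id: str
    offset_m: float
    snapped_x: float
    snapped_y: float
    snap_distance_m: float


@dataclass
class ReachabilityTree:
    """Shortest-path distances from a snapped source, bounded by a cutoff.

    ``node_distance`` holds only real network nodes with distance <= cutoff;
    the temporary virtual split node never appears.
    """

    source: NetworkLocation
    cutoff_m: float
    mode: str
    node_distance: dict[str, float] = field(default_factory=dict)


def euclidean(ax: float, ay: float, bx: float, by: float) -> float:
    return math.hypot(bx - ax, by - ay)


def _point_segment(px, py, ax, ay, bx, by):
    """Distance from P to segment AB and the projection parameter t in [0,1]."""
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0.0:
        return math.hypot(px - ax, py - ay), 0.0
    t = ((px - ax) * dx + (py - ay) * dy) / L2
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy)), t


def snap_facility(network: RoadNetwork, x: float, y: float, mode: str = "walk",
                  max_snap_m: float = 500.0, facility_id: str | None = None) -> NetworkLocation:
    """Anchor a point to the nearest mode-traversable edge.

    Ties in distance are broken by the smallest edge_id for reproducibility.
    Raises :class:`UnreachableFacilityError` when the nearest traversable
    edge lies farther than ``max_snap_m``.
    """
    best = None  # (distance, edge_id, t)
    for e in sorted(network.mode_edges(mode), key=lambda e: e.edge_id):
        ux, uy = network.node_xy(e.u)
        vx, vy = network.node_xy(e.v)
        d, t = _point_segment(x, y, ux, uy, vx, vy)
        if best is None or d < best[0] - 1e-12:
            best = (d, e.edge_id, t)
    if best is None or best[0] > max_snap_m:
        raise UnreachableFacilityError(
            facility_id, snap_distance_m=None if best is None else best[0], max_snap_m=max_snap_m
        )
    d, edge_id, t = best
    e = network.edges[edge_id]
    sx, sy = network.edge_point(edge_id, t * e.length_m)
    return NetworkLocation(edge_id=edge_id, offset_m=t * e.length_m,
                           snapped_x=sx, snapped_y=sy, snap_distance_m=d)


_VIRTUAL = "__source__"


def reachability(network: RoadNetwork, source: NetworkLocation, cutoff_m: float,
                 mode: str = "walk") -> ReachabilityTree:
    """Single-source shortest-path distances within ``cutoff_m`` of the source.

    The source edge is split at ``offset_m`` into two traversable half-edges
    joined at a temporary virtual node, so a facility snapped mid-edge starts
    travel from the snap point rather than from an endpoint.
    """
    if cutoff_m <= 0:
        raise ValidationError(f"cutoff_m must be positive, got {cutoff_m}")
    g = network.graph(mode)
    e = network.edges[source.edge_id]
    if mode not in e.modes:
        raise ValidationError(f"source edge {e.edge_id!r} not traversable by mode {mode!r}")
    # splice in the virtual split node without mutating the cached graph
    h = g.copy()
    h.add_node(_VIRTUAL)
    h.add_edge(_VIRTUAL, e.u, length=source.offset_m)
    h.add_edge(_VIRTUAL, e.v, length=e.length_m - source.offset_m)
    dist = nx.single_source_dijkstra_path_length(h, _VIRTUAL, cutoff=cutoff_m, weight="length")
    dist.pop(_VIRTUAL, None)
    return ReachabilityTree(source=source, cutoff_m=cutoff_m, mode=mode, node_distance=dict(dist))


@dataclass(frozen=True)
class CoveredSegment:
    """The portion(s) of one edge reachable within the cutoff.

    Intervals are measured in meters from the edge's u endpoint, lie within
    [0, length_m], and are disjoint after union (one or two of them).
    """

    edge_id: str
    intervals: tuple  # tuple of (start_m, end_m)

    @property
    def covered_length(self) -> float:
        return sum(b - a for a, b in self.intervals)

    @property
    def fully_covered(self) -> bool:
        return len(self.intervals) == 1 and self.intervals[0][0] == 0.0


def _union_intervals(ivals):
    ivals = sorted((a, b) for a, b in ivals if b > a + 1e-12)
    out = []
    for a, b in ivals:
        if out and a <= out[-1][1] + 1e-12:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return tuple(out)


def covered_segments(network: RoadNetwork, tree: ReachabilityTree) -> list[CoveredSegment]:
    """Edge portions reachable within the cutoff, from either endpoint.

    For an edge (u, v) of length L the budget left on arrival at u is
    cutoff - d(u); coverage from the u end spans [0, min(L, budget_u)] and
    from the v end [max(0, L - budget_v), L]. The edge carrying the source
    additionally gets the direct interval around the snap offset, since
    travel there does not pass through an endpoint.
    """
    c = tree.cutoff_m
    d = tree.node_distance
    out = []
    for e in sorted(network.mode_edges(tree.mode), key=lambda e: e.edge_id):
        ivals = []
        bu = c - d[e.u] if e.u in d else -1.0
        bv = c - d[e.v] if e.v in d else -1.0
        if bu >= 0:
            ivals.append((0.0, min(e.length_m, bu)))
        if bv >= 0:
            ivals.append((max(0.0, e.length_m - bv), e.length_m))
        if e.edge_id == tree.source.edge_id:
            o = tree.source.offset_m
            ivals.append((max(0.0, o - c), min(e.length_m, o + c)))
        merged = _union_intervals(ivals)
        if merged:
            out.append(CoveredSegment(edge_id=e.edge_id, intervals=merged))
    return out


# ---------------------------------------------------------------------------
# File I/O: nodes.csv / edges.csv / GeoJSON export
# ---------------------------------------------------------------------------

def load_network(nodes_path, edges_path) -> RoadNetwork:
    """Read a network from ``nodes.csv`` and ``edges.csv``.

    Schemas: ``node_id,x,y`` and ``edge_id,u,v,length_m,modes,edge_class``
    with ``modes`` a ``|``-separated list. A missing ``length_m`` falls back
    to the Euclidean distance between the endpoints.
    """
    nodes = []
    with open(nodes_path, newline="") as fh:
        for row in csv.DictReader(fh):
            nodes.append(NetworkNode(row["node_id"], float(row["x"]), float(row["y"])))
    xy = {n.node_id: (n.x, n.y) for n in nodes}
    edges = []
    with open(edges_path, newline="") as fh:
        for row in csv.DictReader(fh):
            u, v = row["u"], row["v"]
            raw = (row.get("length_m") or "").strip()
            if raw:
                length = float(raw)
            else:
                if u not in xy or v not in xy:
                    raise ValidationError(f"edge {row['edge_id']!r} references unknown node")
                length = euclidean(*xy[u], *xy[v])
            modes = frozenset(m for m in row["modes"].split("|") if m)
            edges.append(NetworkEdge(row["edge_id"], u, v, length, modes,
                                     row.get("edge_class") or "road"))
    return RoadNetwork(nodes, edges)


def write_network(network: RoadNetwork, nodes_path, edges_path) -> None:
    with open(nodes_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "x", "y"])
        for n in sorted(network.nodes.values(), key=lambda n: n.node_id):
            w.writerow([n.node_id, repr(n.x), repr(n.y)])
    with open(edges_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["edge_id", "u", "v", "length_m", "modes", "edge_class"])
        for e in sorted(network.edges.values(), key=lambda e: e.edge_id):
            w.writerow([e.edge_id, e.u, e.v, repr(e.length_m),
                        "|".join(sorted(e.modes)), e.edge_class])


def network_to_geojson(network: RoadNetwork, path=None) -> dict:
    """Export edges as a GeoJSON FeatureCollection of LineStrings.

    Coordinates are carried in the working planar system as-is.
    """
    feats = []
    for e in sorted(network.edges.values(), key=lambda e: e.edge_id):
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(network.node_xy(e.u)), list(network.node_xy(e.v))]},
            "properties": {"edge_id": e.edge_id, "length_m": e.length_m,
                           "modes": "|".join(sorted(e.modes)), "edge_class": e.edge_class},
        })
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
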