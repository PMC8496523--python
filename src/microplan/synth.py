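"""Seeded synthetic inputs emulating the pipeline's real data sources.

Real deployments consume three external datasets: a gridded, age/sex
stratified population raster (WorldPop-style ~100 m person counts), an
OpenStreetMap-style transport network, and a master list of health-facility
points. This module generates statistically similar stand-ins so the whole
pipeline is testable offline and end to end:

* population: per-cell totals are Poisson with a rate surface made of
  Gaussian settlement bumps over a uniform background — settlement-clustered
  integer counts, zero-inflated in empty countryside — split into age/sex
  strata by a multinomial draw with pyramid proportions;
* network: a jittered lattice with random diagonal shortcuts, so network
  shortest paths measurably exceed straight-line distances (the reason
  straight-line catchments mislead); rewired until >= 90% of nodes share one
  connected component;
* facilities: sampled proportionally to local population density and placed
  adjacent to the network, like facilities in settlements near roads;
* case points: per-catchment Poisson counts at a configurable rate per 1,000
  residents, placed uniformly inside the catchment polygon.

One seed drives independent sub-streams per component, so regenerating one
component never shifts another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .coverage import CasePointSet
from .errors import InvalidConfigError
from .facility import Facility
from .grid import DEFAULT_AGE_BANDS, PopulationGrid, StratumKey, zonal_population
from .network import NetworkEdge, NetworkNode, RoadNetwork, euclidean

# fixed spawn keys for the per-component random sub-streams
_STREAMS = {"settlements": 0, "network": 1, "grid": 2, "facilities": 3, "cases": 4}


def _band_midpoint_width(band: str) -> tuple[float, float]:
    if band == "0":
        return 0.5, 1.0
    if band.endswith("+"):
        lo = float(band[:-1])
        return lo + 7.5, 15.0
    lo, hi = band.split("-")
    lo, hi = float(lo), float(hi)
    return (lo + hi + 1) / 2, hi - lo + 1


def default_pyramid(age_bands=DEFAULT_AGE_BANDS, sexes=("f", "m")) -> tuple:
    """A smooth declining age pyramid over the WorldPop band convention.

    Band weight is proportional to band width times exp(-0.02 x mid-age),
    split evenly between sexes; proportions are normalized to sum to 1.
    """
    weights = []
    for band in age_bands:
        mid, width = _band_midpoint_width(band)
        w = width * math.exp(-0.02 * mid)
        for sex in sexes:
            weights.append((band, sex, w / len(sexes)))
    total = sum(w for _, _, w in weights)
    return tuple((band, sex, w / total) for band, sex, w in weights)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study region.

    Defaults describe a 10 x 10 km region at 100 m resolution with a handful
    of Gaussian settlements (peak ~50 persons per cell, sigma 500 m) over a
    sparse rural background, a walking-connected road lattice, and facilities
    concentrated where people are.
    """

    seed: int = 0
    extent: tuple = (0.0, 0.0, 10_000.0, 10_000.0)  # xmin, ymin, xmax, ymax
    cell_size_m: float = 100.0
    n_settlements: int = 5
    settlement_amplitude: float = 50.0
    settlement_sigma_m: float = 500.0
    background_rate: float = 0.05
    pyramid: tuple = field(default_factory=default_pyramid)
    n_network_nodes: int = 100
    n_facilities: int = 5
    case_rate_per_1000: float = 10.0
    facility_snap_m: float = 250.0

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise InvalidConfigError(f"degenerate extent {self.extent}")
        if self.cell_size_m <= 0:
            raise InvalidConfigError("cell_size_m must be positive")
        if (xmax - xmin) < self.cell_size_m or (ymax - ymin) < self.cell_size_m:
            raise InvalidConfigError("extent smaller than one grid cell")
        psum = sum(p for _, _, p in self.pyramid)
        if abs(psum - 1.0) > 1e-9:
            raise InvalidConfigError(f"pyramid proportions sum to {psum}, expected 1")
        if self.n_settlements < 0 or self.n_network_nodes < 0 or self.n_facilities < 0:
            raise InvalidConfigError("counts must be non-negative")
        if self.background_rate < 0 or self.case_rate_per_1000 < 0:
            raise InvalidConfigError("rates must be non-negative")
        if self.settlement_amplitude <= 0 or self.settlement_sigma_m <= 0:
            raise InvalidConfigError("settlement amplitude and sigma must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],)))

    @property
    def grid_shape(self) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.extent
        ncols = int((xmax - xmin) // self.cell_size_m)
        nrows = int((ymax - ymin) // self.cell_size_m)
        return nrows, ncols


def settlement_locations(config: SynthConfig) -> np.ndarray:
    """(n_settlements, 2) settlement centers, uniform over the extent."""
    rng = config.rng("settlements")
    xmin, ymin, xmax, ymax = config.extent
    pts = rng.uniform((xmin, ymin), (xmax, ymax), size=(config.n_settlements, 2))
    return pts


def rate_surface(config: SynthConfig) -> np.ndarray:
    """Expected persons per cell: background plus Gaussian settlement bumps."""
    nrows, ncols = config.grid_shape
    xmin, ymin, xmax, ymax = config.extent
    cs = config.cell_size_m
    x = xmin + (np.arange(ncols) + 0.5) * cs
    y = ymin + (nrows - np.arange(nrows) - 0.5) * cs
    X, Y = np.meshgrid(x, y)
    lam = np.full((nrows, ncols), float(config.background_rate))
    s2 = 2.0 * config.settlement_sigma_m ** 2
    for sx, sy in settlement_locations(config):
        d2 = (X - sx) ** 2 + (Y - sy) ** 2
        lam += config.settlement_amplitude * np.exp(-d2 / s2)
    return lam


def generate_population_grid(config: SynthConfig) -> PopulationGrid:
    """Draw the stratified population raster.

    Cell totals are Poisson(lambda(cell)); strata are a multinomial split of
    each total with the pyramid proportions, so strata sum exactly to the
    total in every cell.
    """
    rng = config.rng("grid")
    lam = rate_surface(config)
    totals = rng.poisson(lam)
    pvals = np.array([p for _, _, p in config.pyramid])
    pvals = pvals / pvals.sum()
    split = rng.multinomial(totals.ravel(), pvals)  # (ncell, nstrata)
    strata = {}
    for j, (band, sex, _p) in enumerate(config.pyramid):
        strata[StratumKey(band, sex)] = split[:, j].reshape(totals.shape).astype(np.int64)
    xmin, ymin, _, _ = config.extent
    nrows, ncols = config.grid_shape
    return PopulationGrid(ncols=ncols, nrows=nrows, xll=xmin, yll=ymin,
                          cell_size_m=config.cell_size_m, strata=strata)


def generate_road_network(config: SynthConfig) -> RoadNetwork:
    """Jittered-lattice road network with diagonal shortcuts.

    Nodes sit on a near-square lattice covering the extent, jittered by up to
    30% of the spacing; lattice neighbors are joined by road edges and a
    random ~10% of cells gain a diagonal shortcut. Components beyond the
    largest are rewired onto it through their nearest node pair until at
    least 90% of nodes are mutually reachable (the construction ends fully
    connected). Every edge length is the exact Euclidean endpoint distance.
    Most edges carry {walk, drive}; some are foot paths; ferry edges are rare.
    """
    n = config.n_network_nodes
    if n == 0:
        return RoadNetwork([], [])
    rng = config.rng("network")
    xmin, ymin, xmax, ymax = config.extent
    w, h = xmax - xmin, ymax - ymin
    mcols = max(1, round(math.sqrt(n * w / h)))
    mrows = math.ceil(n / mcols)
    sx, sy = w / (mcols + 1), h / (mrows + 1)
    nodes = []
    index = {}
    for k in range(n):
        r, c = divmod(k, mcols)
        jx, jy = rng.uniform(-0.3, 0.3, size=2)
        x = xmin + (c + 1 + jx) * sx
        y = ymin + (r + 1 + jy) * sy
        nid = f"n{k:04d}"
        nodes.append(NetworkNode(nid, float(x), float(y)))
        index[(r, c)] = nid
    xy = {nd.node_id: (nd.x, nd.y) for nd in nodes}

    pairs = []
    for (r, c), nid in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            other = index.get((r + dr, c + dc))
            if other is not None:
                pairs.append((nid, other))
    # diagonal shortcuts exercise the straight-line-vs-network gap
    for (r, c), nid in sorted(index.items()):
        if rng.random() < 0.10:
            other = index.get((r + 1, c + 1))
            if other is not None:
                pairs.append((nid, other))

    edges = []
    for i, (u, v) in enumerate(pairs):
        length = euclidean(*xy[u], *xy[v])
        roll = rng.random()
        if roll < 0.78:
            modes, cls = frozenset({"walk", "drive"}), "road"
        elif roll < 0.98:
            modes, cls = frozenset({"walk"}), "path"
        else:
            modes, cls = frozenset({"ferry"}), "ferry_line"
        edges.append(NetworkEdge(f"e{i:04d}", u, v, length, modes, cls))

    net = RoadNetwork(nodes, edges)
    net = _rewire_connected(net, min_fraction=0.9)
    return net


def _rewire_connected(net: RoadNetwork, min_fraction: float) -> RoadNetwork:
    """Join smaller components to the largest until it holds >= min_fraction."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for e in net.edges.values():
        g.add_edge(e.u, e.v)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if not comps or len(comps[0]) >= min_fraction * len(net.nodes):
        return net
    extra = []
    main = set(comps[0])
    k = 0
    for comp in comps[1:]:
        best = None
        for a in sorted(comp):
            ax, ay = net.node_xy(a)
            for b in sorted(main):
                bx, by = net.node_xy(b)
                d = euclidean(ax, ay, bx, by)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        extra.append(NetworkEdge(f"x{k:04d}", a, b, d, frozenset({"walk", "drive"}), "road"))
        main |= set(comp)
        k += 1
    return RoadNetwork(list(net.nodes.values()), list(net.edges.values()) + extra)


def generate_facilities(network: RoadNetwork, grid: PopulationGrid,
                        config: SynthConfig) -> list[Facility]:
    """Facility points sampled where people are, adjacent to the network.

    Cells are drawn with probability proportional to their population (uniform
    when the grid is empty); each draw is placed on the nearest network point
    to the cell center, offset by a small random nudge well inside the
    snapping radius, so every facility is snappable by construction.
    """
    if config.n_facilities == 0:
        return []
    if len(network) == 0 or network.n_edges == 0:
        raise InvalidConfigError("cannot place facilities on an empty network")
    rng = config.rng("facilities")
    totals = grid.total.astype(float).ravel()
    p = totals / totals.sum() if totals.sum() > 0 else np.full(totals.size, 1.0 / totals.size)
    cells = rng.choice(totals.size, size=config.n_facilities, p=p)
    X, Y = grid.cell_centers()
    xmid = (config.extent[0] + config.extent[2]) / 2
    segs = [(e.edge_id, network.node_xy(e.u), network.node_xy(e.v))
            for e in sorted(network.edges.values(), key=lambda e: e.edge_id)]
    out = []
    for i, cell in enumerate(cells):
        cx = X.ravel()[cell]
        cy = Y.ravel()[cell]
        nx_, ny_ = _nearest_network_point(segs, cx, cy)
        r = rng.uniform(0, 0.4 * config.facility_snap_m)
        theta = rng.uniform(0, 2 * math.pi)
        x, y = nx_ + r * math.cos(theta), ny_ + r * math.sin(theta)
        group = "zone-west" if x < xmid else "zone-east"
        out.append(Facility(facility_id=f"f{i:03d}", x=float(x), y=float(y),
                            name=f"Health facility {i}", group=group))
    return out


def _nearest_network_point(segs, px, py) -> tuple[float, float]:
    best = None
    for _eid, (ax, ay), (bx, by) in segs:
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else min(1.0, max(0.0, ((px - ax) * dx + (py - ay) * dy) / L2))
        qx, qy = ax + t * dx, ay + t * dy
        d = math.hypot(px - qx, py - qy)
        if best is None or d < best[0]:
            best = (d, qx, qy)
    return best[1], best[2]


def generate_case_points(catchments: list, grid: PopulationGrid,
                         config: SynthConfig) -> CasePointSet:
    """Poisson case points inside each catchment at the configured rate.

    Per catchment the case count is Poisson with mean
    case_rate_per_1000 x covered population / 1000 (center rule), and points
    are placed uniformly inside the polygon by rejection sampling.
    """
    rng = config.rng("cases")
    points = []
    k = 0
    for c in sorted(catchments, key=lambda c: c.facility_id):
        pop = zonal_population(grid, c.polygon, rule="center").population_total
        n = int(rng.poisson(config.case_rate_per_1000 * pop / 1000.0))
        minx, miny, maxx, maxy = c.polygon.bounds
        placed = 0
        while placed < n:
            xs = rng.uniform(minx, maxx, size=max(16, 2 * (n - placed)))
            ys = rng.uniform(miny, maxy, size=xs.size)
            inside = shapely.intersects_xy(c.polygon, xs, ys)
            for x, y in zip(xs[inside], ys[inside]):
                if placed >= n:
                    break
                points.append((float(x), float(y), {"case_id": f"c{k:05d}",
                                                    "source_catchment": c.facility_id}))
                placed += 1
                k += 1
    return CasePointSet(points=points)


def generate_scene(config: SynthConfig):
    """Convenience: (network, grid, facilities) from one config."""
    network = generate_road_network(config)
    grid = generate_population_grid(config)
    facilities = generate_facilities(network, grid, config)
    return network, grid, facilities


def write_synthetic_dataset(config: SynthConfig, out_dir) -> dict:
    """Generate and write a full input set in the pipeline's file formats."""
    from pathlib import Path

    from .facility import write_facilities
    from .grid import write_grid
    from .network import write_network

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, grid, facilities = generate_scene(config)
    write_network(network, out_dir / "nodes.csv", out_dir / "edges.csv")
    manifest = write_grid(grid, out_dir / "population")
    write_facilities(facilities, out_dir / "facilities.geojson")
    return {"nodes": str(out_dir / "nodes.csv"), "edges": str(out_dir / "edges.csv"),
            "grid_manifest": str(manifest),
            "facilities": str(out_dir / "facilities.geojson")}
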