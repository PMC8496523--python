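"""Network loading, snapping, reachability and covered-segment arithmetic."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from microplan import (NetworkEdge, NetworkNode, RoadNetwork,
                       UnreachableFacilityError, ValidationError,
                       covered_segments, load_network, reachability,
                       snap_facility, write_network)
from microplan.network import NetworkLocation, _point_segment

from conftest import WALK, WALK_DRIVE, random_connected_network


# ---------------------------------------------------------------------------
# loading / validation
# ---------------------------------------------------------------------------

def test_missing_length_falls_back_to_euclidean(tmp_path):
    (tmp_path / "nodes.csv").write_text("node_id,x,y\nA,0,0\nB,3000,0\n")
    (tmp_path / "edges.csv").write_text("edge_id,u,v,length_m,modes,edge_class\ne1,A,B,,walk,road\n")
    net = load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv")
    assert net.edges["e1"].length_m == pytest.approx(3000.0)


def test_dangling_endpoint_rejected(tmp_path):
    (tmp_path / "nodes.csv").write_text("node_id,x,y\nA,0,0\n")
    (tmp_path / "edges.csv").write_text("edge_id,u,v,length_m,modes,edge_class\ne1,A,Z,10,walk,road\n")
    with pytest.raises(ValidationError):
        load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv")


@pytest.mark.parametrize("length", [0.0, -5.0])
def test_nonpositive_length_rejected(length):
    with pytest.raises(ValidationError):
        NetworkEdge("e", "A", "B", length, WALK)


def test_empty_modes_rejected():
    with pytest.raises(ValidationError):
        NetworkEdge("e", "A", "B", 10.0, frozenset())


def test_write_load_round_trip(tmp_path):
    from microplan import SynthConfig, generate_road_network
    net = generate_road_network(SynthConfig(seed=5, n_network_nodes=40, n_facilities=0))
    assert net.n_edges >= 50
    write_network(net, tmp_path / "nodes.csv", tmp_path / "edges.csv")
    back = load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv")
    assert set(back.nodes) == set(net.nodes)
    assert set(back.edges) == set(net.edges)
    for eid, e in net.edges.items():
        b = back.edges[eid]
        assert (b.u, b.v, b.modes, b.edge_class) == (e.u, e.v, e.modes, e.edge_class)
        assert b.length_m == e.length_m
    for nid, n in net.nodes.items():
        assert (back.nodes[nid].x, back.nodes[nid].y) == (n.x, n.y)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def test_snap_at_node_has_zero_distance(chain_network):
    loc = snap_facility(chain_network, 3000.0, 0.0, max_snap_m=10)
    assert loc.snap_distance_m == pytest.approx(0.0)
    assert loc.offset_m in (pytest.approx(0.0), pytest.approx(3000.0))


def test_snap_beyond_max_snap_raises(chain_network):
    with pytest.raises(UnreachableFacilityError):
        snap_facility(chain_network, 3000.0, 10_000.0, max_snap_m=500.0)


def test_snap_matches_exhaustive_segment_scan():
    rng = np.random.default_rng(42)
    net = random_connected_network(rng, 12, p_extra=0.2)  # ~30 edges
    for _ in range(25):
        px, py = rng.uniform(0, 4000, 2)
        loc = snap_facility(net, px, py, max_snap_m=1e9)
        # independent brute force over every segment
        best = math.inf
        for e in net.edges.values():
            d, _t = _point_segment(px, py, *net.node_xy(e.u), *net.node_xy(e.v))
            best = min(best, d)
        assert loc.snap_distance_m == pytest.approx(best, abs=1e-9)


def test_snap_tie_broken_by_smallest_edge_id():
    nodes = [NetworkNode("A", 0, 0), NetworkNode("B", 100, 0),
             NetworkNode("C", 0, 10), NetworkNode("D", 100, 10)]
    edges = [NetworkEdge("e2", "A", "B", 100.0, WALK), NetworkEdge("e1", "C", "D", 100.0, WALK)]
    net = RoadNetwork(nodes, edges)
    loc = snap_facility(net, 50.0, 5.0, max_snap_m=100)  # equidistant
    assert loc.edge_id == "e1"


# ---------------------------------------------------------------------------
# reachability
# ---------------------------------------------------------------------------

def source_at(net, node_id):
    """NetworkLocation at a node, on its smallest incident edge."""
    x, y = net.node_xy(node_id)
    return snap_facility(net, x, y, max_snap_m=1.0)


def test_chain_distances(chain_network):
    tree = reachability(chain_network, source_at(chain_network, "A"), 5000.0)
    assert tree.node_distance == {"A": pytest.approx(0.0), "B": pytest.approx(3000.0)}


def test_near_zero_cutoff_reaches_nothing(chain_network):
    mid = NetworkLocation(edge_id="e1", offset_m=1500.0, snapped_x=1500.0,
                          snapped_y=0.0, snap_distance_m=0.0)
    tree = reachability(chain_network, mid, 0.001)
    assert tree.node_distance == {}


def test_nonpositive_cutoff_rejected(chain_network):
    with pytest.raises(ValidationError):
        reachability(chain_network, source_at(chain_network, "A"), 0.0)


def brute_force_distances(net, source_node, cutoff, mode="walk"):
    """Independent oracle: min path length by exhaustive simple-path enumeration."""
    g = nx.Graph()
    for e in net.edges.values():
        if mode in e.modes:
            if g.has_edge(e.u, e.v):
                g[e.u][e.v]["w"] = min(g[e.u][e.v]["w"], e.length_m)
            else:
                g.add_edge(e.u, e.v, w=e.length_m)
    out = {}
    for target in g.nodes:
        if target == source_node:
            out[target] = 0.0
            continue
        best = math.inf
        for path in nx.all_simple_paths(g, source_node, target):
            best = min(best, sum(g[a][b]["w"] for a, b in itertools.pairwise(path)))
        if best <= cutoff:
            out[target] = best
    if source_node in net.nodes and 0.0 <= cutoff:
        out.setdefault(source_node, 0.0)
    return out


@pytest.mark.parametrize("trial", range(20))
def test_reachability_matches_path_enumeration(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(3, 9))
    net = random_connected_network(rng, n)
    src = f"n{int(rng.integers(0, n))}"
    cutoff = float(rng.uniform(500, 6000))
    tree = reachability(net, source_at(net, src), cutoff)
    expected = brute_force_distances(net, src, cutoff)
    assert set(tree.node_distance) == set(expected)
    for node, d in expected.items():
        assert tree.node_distance[node] == pytest.approx(d, abs=1e-6)


def test_cutoff_monotonicity_nodes_and_lengths():
    rng = np.random.default_rng(7)
    for trial in range(10):
        net = random_connected_network(rng, 10)
        src = source_at(net, "n0")
        t1 = reachability(net, src, 1500.0)
        t2 = reachability(net, src, 4000.0)
        assert set(t1.node_distance) <= set(t2.node_distance)
        cov1 = {s.edge_id: s.covered_length for s in covered_segments(net, t1)}
        cov2 = {s.edge_id: s.covered_length for s in covered_segments(net, t2)}
        for eid, L in cov1.items():
            assert L <= cov2.get(eid, 0.0) + 1e-9


def test_mode_filtering_never_shortens_walk_distances():
    nodes = [NetworkNode("A", 0, 0), NetworkNode("B", 1000, 0), NetworkNode("C", 2000, 0)]
    edges = [NetworkEdge("e1", "A", "B", 1000.0, WALK),
             NetworkEdge("e2", "B", "C", 1000.0, WALK),
             NetworkEdge("e3", "A", "C", 500.0, frozenset({"drive"}))]  # car shortcut
    net = RoadNetwork(nodes, edges)
    walk_tree = reachability(net, source_at(net, "A"), 5000.0, mode="walk")
    assert walk_tree.node_distance["C"] == pytest.approx(2000.0)  # drive edge ignored
    walk_only = RoadNetwork(list(net.nodes.values()), [edges[0], edges[1]])
    pruned = reachability(walk_only, source_at(walk_only, "A"), 5000.0, mode="walk")
    for node, d in walk_tree.node_distance.items():
        assert pruned.node_distance[node] == pytest.approx(d)


# ---------------------------------------------------------------------------
# covered segments
# ---------------------------------------------------------------------------

def test_chain_covered_segments(chain_network):
    tree = reachability(chain_network, source_at(chain_network, "A"), 5000.0)
    segs = {s.edge_id: s for s in covered_segments(chain_network, tree)}
    assert segs["e1"].fully_covered
    assert segs["e2"].intervals == ((0.0, 2000.0),)


def test_saturating_cutoff_covers_everything(chain_network):
    tree = reachability(chain_network, source_at(chain_network, "A"), 1e7)
    segs = covered_segments(chain_network, tree)
    assert len(segs) == chain_network.n_edges
    assert all(s.fully_covered for s in segs)


def test_triangle_budgets_from_both_ends(triangle_network):
    # from A with cutoff 3000: d(B) = d(C) = 2000, so edge bc (5000 m) is
    # covered 1000 m from each end
    tree = reachability(triangle_network, source_at(triangle_network, "A"), 3000.0)
    segs = {s.edge_id: s for s in covered_segments(triangle_network, tree)}
    assert segs["ab"].fully_covered and segs["ac"].fully_covered
    assert segs["bc"].intervals == (
        (pytest.approx(0.0), pytest.approx(1000.0)),
        (pytest.approx(4000.0), pytest.approx(5000.0)))


def test_midedge_source_covers_both_directions(chain_network):
    mid = NetworkLocation(edge_id="e1", offset_m=1000.0, snapped_x=1000.0,
                          snapped_y=0.0, snap_distance_m=0.0)
    tree = reachability(chain_network, mid, 500.0)
    segs = {s.edge_id: s for s in covered_segments(chain_network, tree)}
    # nothing reachable via endpoints; only the direct interval around the source
    assert list(segs) == ["e1"]
    assert segs["e1"].intervals == ((pytest.approx(500.0), pytest.approx(1500.0)),)


def test_branch_coverage_never_exceeds_cutoff():
    rng = np.random.default_rng(99)
    for _ in range(5):
        net = random_connected_network(rng, 10)
        cutoff = 2500.0
        tree = reachability(net, source_at(net, "n0"), cutoff)
        for seg in covered_segments(net, tree):
            e = net.edges[seg.edge_id]
            for a, b in seg.intervals:
                du = tree.node_distance.get(e.u, math.inf)
                dv = tree.node_distance.get(e.v, math.inf)
                # every covered point is within the cutoff from one end
                reach_a = min(du + a, dv + (e.length_m - a))
                reach_b = min(du + b, dv + (e.length_m - b))
                if e.edge_id == tree.source.edge_id:
                    o = tree.source.offset_m
                    reach_a = min(reach_a, abs(a - o))
                    reach_b = min(reach_b, abs(b - o))
                assert reach_a <= cutoff + 1e-9
                assert reach_b <= cutoff + 1e-9
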