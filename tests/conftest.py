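import math

import numpy as np
import pytest

from microplan import (NetworkEdge, NetworkNode, PopulationGrid, RoadNetwork,
                       StratumKey, SynthConfig)

WALK = frozenset({"walk"})
WALK_DRIVE = frozenset({"walk", "drive"})


@pytest.fixture
def chain_network():
    """A -- 3000 m -- B -- 3000 m -- C, all walkable."""
    nodes = [NetworkNode("A", 0.0, 0.0), NetworkNode("B", 3000.0, 0.0),
             NetworkNode("C", 6000.0, 0.0)]
    edges = [NetworkEdge("e1", "A", "B", 3000.0, WALK, "road"),
             NetworkEdge("e2", "B", "C", 3000.0, WALK, "road")]
    return RoadNetwork(nodes, edges)


@pytest.fixture
def triangle_network():
    """Triangle with side lengths 2000 / 2000 / 5000 (lengths set explicitly)."""
    nodes = [NetworkNode("A", 0.0, 0.0), NetworkNode("B", 2000.0, 0.0),
             NetworkNode("C", 0.0, 2000.0)]
    edges = [NetworkEdge("ab", "A", "B", 2000.0, WALK, "road"),
             NetworkEdge("ac", "A", "C", 2000.0, WALK, "road"),
             NetworkEdge("bc", "B", "C", 5000.0, WALK, "road")]
    return RoadNetwork(nodes, edges)


def random_connected_network(rng, n_nodes, extent=4000.0, p_extra=0.3):
    """Random connected test graph: a random spanning tree plus extra edges."""
    xs = rng.uniform(0, extent, n_nodes)
    ys = rng.uniform(0, extent, n_nodes)
    nodes = [NetworkNode(f"n{i}", float(xs[i]), float(ys[i])) for i in range(n_nodes)]
    edges = []
    k = 0
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append(NetworkEdge(f"e{k:03d}", f"n{i}", f"n{j}",
                                 math.dist((xs[i], ys[i]), (xs[j], ys[j])) + 1e-9,
                                 WALK, "road"))
        k += 1
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_extra and not any(
                    {e.u, e.v} == {f"n{i}", f"n{j}"} for e in edges):
                edges.append(NetworkEdge(f"e{k:03d}", f"n{i}", f"n{j}",
                                         math.dist((xs[i], ys[i]), (xs[j], ys[j])) + 1e-9,
                                         WALK, "road"))
                k += 1
    return RoadNetwork(nodes, edges)


TWO_STRATA = (("0-4", "f", 0.5), ("0-4", "m", 0.5))


@pytest.fixture
def small_config():
    """Small scene: 3 x 3 km at 100 m cells, two strata, fast to generate."""
    return SynthConfig(seed=11, extent=(0, 0, 3000, 3000), cell_size_m=100,
                       n_settlements=3, settlement_amplitude=30, settlement_sigma_m=400,
                       background_rate=0.1, pyramid=TWO_STRATA,
                       n_network_nodes=40, n_facilities=3)


@pytest.fixture
def uniform_grid():
    """5x5 grid of cells all equal to 4 persons, split into two strata."""
    ones = np.full((5, 5), 2, dtype=np.int64)
    return PopulationGrid(ncols=5, nrows=5, xll=0.0, yll=0.0, cell_size_m=100.0,
                          strata={StratumKey("0-4", "f"): ones.copy(),
                                  StratumKey("0-4", "m"): ones.copy()})
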