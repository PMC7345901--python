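"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from radars.repertoire import SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def default_run():
    """One 500-step simulation at the default configuration, shared read-only."""
    return run_simulation(SimulationConfig())


@pytest.fixture(scope="session")
def small_graph_fixtures():
    """Connected graphs with <= 12 nodes for exact box-covering comparisons."""
    graphs = {
        "path6": nx.path_graph(6),
        "cycle8": nx.cycle_graph(8),
        "star9": nx.star_graph(8),
        "grid3x3": nx.convert_node_labels_to_integers(nx.grid_2d_graph(3, 3)),
        "tree12": nx.balanced_tree(2, 2),
        "complete5": nx.complete_graph(5),
        "barbell": nx.barbell_graph(4, 2),
        "wheel8": nx.wheel_graph(7),
        "er12": nx.erdos_renyi_graph(12, 0.3, seed=4),
    }
    for name, g in graphs.items():
        assert nx.is_connected(g), name
    return graphs


def exact_min_box_count(graph: nx.Graph, lb: int) -> int:
    """Exhaustive minimum number of boxes of diameter < lb covering ``graph``.

    A valid box is a node set with pairwise shortest-path distance < lb, so
    the minimum cover equals the chromatic number of the auxiliary graph
    connecting nodes at distance >= lb.  Exact backtracking search; only
    feasible for small graphs (<= ~12 nodes).
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    if n == 0:
        return 0
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    aux = {
        i: {j for j in range(n) if j != i and dist[nodes[i]][nodes[j]] >= lb}
        for i in range(n)
    }
    if all(not a for a in aux.values()):
        return 1

    order = sorted(range(n), key=lambda i: -len(aux[i]))

    def colorable(k: int) -> bool:
        colors: dict[int, int] = {}

        def assign(pos: int) -> bool:
            if pos == n:
                return True
            node = order[pos]
            used = {colors[j] for j in aux[node] if j in colors}
            for c in range(k):
                if c not in used:
                    colors[node] = c
                    if assign(pos + 1):
                        return True
                    del colors[node]
                if c not in colors.values():
                    break  # symmetry: first unused color only once
            return False

        return assign(0)

    for k in itertools.count(1):
        if colorable(k):
            return k
    raise AssertionError("unreachable")
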