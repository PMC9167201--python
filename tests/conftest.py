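"""Shared fixtures and random-instance builders for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netsig.netbuild import RECEPTOR, TF, TRANSDUCER


def make_network(edges, roles) -> nx.Graph:
    g = nx.Graph()
    for node, role in roles.items():
        g.add_node(node, role=role)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def chain_network() -> nx.Graph:
    """R - A - F: the smallest receptor -> transducer -> TF cascade."""
    return make_network(
        [("R", "A"), ("A", "F")],
        {"R": RECEPTOR, "A": TRANSDUCER, "F": TF})


@pytest.fixture
def star_network() -> nx.Graph:
    """R connected to a dead-end transducer A and a TF F."""
    return make_network(
        [("R", "A"), ("R", "F")],
        {"R": RECEPTOR, "A": TRANSDUCER, "F": TF})


@pytest.fixture
def diamond_network() -> nx.Graph:
    """Two parallel routes R-A-F and R-B-F."""
    return make_network(
        [("R", "A"), ("A", "F"), ("R", "B"), ("B", "F")],
        {"R": RECEPTOR, "A": TRANSDUCER, "B": TRANSDUCER, "F": TF})


def random_role_graph(rng: np.random.Generator, max_nodes: int = 15):
    """Random connected-ish role-annotated graph with positive expression.

    Returns (network, expression dict).  At least one receptor and one TF;
    the graph may be disconnected, exercising the unreachable sentinel.
    """
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"g{i}" for i in range(n)]
    n_rec = int(rng.integers(1, max(2, n // 4) + 1))
    n_tf = int(rng.integers(1, max(2, n // 4) + 1))
    roles = {}
    for i, name in enumerate(names):
        if i < n_rec:
            roles[name] = RECEPTOR
        elif i < n_rec + n_tf:
            roles[name] = TF
        else:
            roles[name] = TRANSDUCER
    g = nx.Graph()
    for name in names:
        g.add_node(name, role=roles[name])
    p = float(rng.uniform(0.15, 0.6))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    expression = {name: float(rng.uniform(0.1, 10.0)) for name in names}
    # occasional zero-expression gene to exercise dead ends
    if rng.random() < 0.3:
        expression[names[int(rng.integers(0, n))]] = 0.0
    return g, expression
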