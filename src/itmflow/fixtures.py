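"""Deterministic fixture graphs for tests, demos and oracle comparisons.

All generators are seeded and return byte-reproducible graphs:

* ``path`` — an undirected unit-weight path (size 3 gives the a-b-c chain
  whose flow quantities have simple closed forms);
* ``parallel_paths`` — two undirected arms of unequal length between one
  source-end and one sink-end; the short arm is the unique shortest path;
* ``lattice_with_holes`` — a square lattice with 10% of nodes and 10% of the
  remaining edges removed at random, emulating a sparse interaction map;
* ``random_er`` — a connected Erdos-Renyi graph with uniform random weights
  (regenerated with an incremented seed until connected).
"""

from __future__ import annotations

import logging
import string

import networkx as nx
import numpy as np

from .errors import ValidationError
from .graph import WeightedDigraph

logger = logging.getLogger(__name__)


def _node_name(i: int, size: int) -> str:
    if size <= 26:
        return string.ascii_lowercase[i]
    return f"n{i:03d}"


def path_graph(size: int) -> WeightedDigraph:
    if size < 2:
        raise ValidationError("path fixture needs size >= 2")
    names = [_node_name(i, size) for i in range(size)]
    edges = [(names[i], names[i + 1], 1.0) for i in range(size - 1)]
    return WeightedDigraph.from_edges(edges, undirected=True)


def parallel_paths_graph(size: int) -> WeightedDigraph:
    """Arms with 2 and ``size`` internal nodes between source 's' and sink 't'."""
    if size < 3:
        raise ValidationError(
            "parallel_paths needs size >= 3 so the short arm is uniquely shortest"
        )
    short = ["p1", "p2"]
    long_ = [f"q{i + 1}" for i in range(size)]
    edges = []
    for arm in (short, long_):
        chain = ["s"] + arm + ["t"]
        edges += [(chain[i], chain[i + 1], 1.0) for i in range(len(chain) - 1)]
    return WeightedDigraph.from_edges(edges, undirected=True)


def lattice_with_holes_graph(size: int, seed: int = 0) -> WeightedDigraph:
    if size < 2:
        raise ValidationError("lattice fixture needs side length >= 2")
    rng = np.random.default_rng(seed)
    G = nx.grid_2d_graph(size, size)
    nodes = sorted(G.nodes())
    drop_n = rng.choice(len(nodes), size=max(0, len(nodes) // 10), replace=False)
    G.remove_nodes_from([nodes[i] for i in drop_n])
    edges = sorted(G.edges())
    drop_e = rng.choice(len(edges), size=max(0, len(edges) // 10), replace=False)
    G.remove_edges_from([edges[i] for i in drop_e])
    name = lambda rc: f"r{rc[0]:02d}c{rc[1]:02d}"
    return WeightedDigraph.from_edges(
        [(name(u), name(v), 1.0) for u, v in G.edges()],
        undirected=True,
        extra_nodes=[name(n) for n in G.nodes()],
    )


def random_er_graph(size: int, seed: int = 0) -> WeightedDigraph:
    """Connected G(n, p) with weights uniform on [0.5, 1.5); p ~ 4/n."""
    if size < 2:
        raise ValidationError("random_er fixture needs size >= 2")
    p = min(1.0, 4.0 / size)
    attempt = seed
    while True:
        G = nx.gnp_random_graph(size, p, seed=attempt)
        if nx.is_connected(G):
            break
        logger.info("ER draw with seed %d disconnected; retrying", attempt)
        attempt += 1
    rng = np.random.default_rng(attempt)
    edges = [
        (f"n{u:02d}", f"n{v:02d}", float(0.5 + rng.random()))
        for u, v in sorted(G.edges())
    ]
    return WeightedDigraph.from_edges(edges, undirected=True)


_KINDS = {
    "path": lambda size, seed: path_graph(size),
    "parallel_paths": lambda size, seed: parallel_paths_graph(size),
    "lattice_with_holes": lattice_with_holes_graph,
    "random_er": random_er_graph,
}


def make_fixture(kind: str, size: int, seed: int = 0) -> WeightedDigraph:
    """Build one of the named fixture graphs deterministically."""
    if kind not in _KINDS:
        raise ValidationError(f"unknown fixture kind {kind!r}; valid: {sorted(_KINDS)}")
    return _KINDS[kind](size, seed)
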