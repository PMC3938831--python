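"""Shared fixtures: small graphs and simulated data used across test modules."""

import itertools

import numpy as np
import pytest

from ripe.graph_core import WeightedDigraph


@pytest.fixture
def chain3() -> WeightedDigraph:
    """1 -> 2 -> 3."""
    return WeightedDigraph.from_edges(
        [("g1", "g2"), ("g2", "g3")], node_ids=["g1", "g2", "g3"]
    )


@pytest.fixture
def cycle3() -> WeightedDigraph:
    """a -> b -> c -> a."""
    return WeightedDigraph.from_edges(
        [("a", "b"), ("b", "c"), ("c", "a")], node_ids=["a", "b", "c"]
    )


@pytest.fixture
def diamond() -> WeightedDigraph:
    """a -> {b, c} -> d."""
    return WeightedDigraph.from_edges(
        [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")],
        node_ids=["a", "b", "c", "d"],
    )


def random_digraph(p: int, edge_prob: float, seed: int) -> WeightedDigraph:
    """Uniform random digraph (cycles allowed), used by oracle tests."""
    rng = np.random.default_rng(seed)
    w = (rng.random((p, p)) < edge_prob).astype(float)
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph([f"n{i}" for i in range(p)], w)


def all_digraphs(p: int):
    """Every labelled digraph on p nodes (no self-loops), as adjacency arrays."""
    pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        adj = np.zeros((p, p))
        for (i, j), b in zip(pairs, bits):
            adj[i, j] = b
        yield adj
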