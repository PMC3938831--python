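"""Causal-ordering enumeration and sampling, checked against brute force.

The independent oracle used throughout: run the deterministic DFS under
*every* label permutation and collect the distinct orderings.  Any ordering a
DFS can produce is produced under the labeling that ranks nodes by the
execution's discovery times, so this enumerates the full universe.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from ripe.graph_core import InfluenceMatrix, WeightedDigraph, scc_condense
from ripe.orderings import (
    CausalOrdering,
    dfs_ordering,
    exhaustive_scc_orderings,
    global_orderings,
    mc_dfs,
    read_orderings_tsv,
    write_orderings_tsv,
)

from conftest import all_digraphs, random_digraph


def permutation_universe(g: WeightedDigraph) -> set:
    """Oracle: distinct causal orderings over all label permutations."""
    return {
        dfs_ordering(g, list(perm)).sequence
        for perm in itertools.permutations(g.node_ids)
    }


# ---------------------------------------------------------------------------
# single DFS ordering
# ---------------------------------------------------------------------------


def test_chain_identity_labels_gives_chain_order(chain3):
    o = dfs_ordering(chain3, ["g1", "g2", "g3"])
    assert o.sequence == ("g1", "g2", "g3")


def test_dfs_ordering_is_deterministic_and_label_sensitive(cycle3):
    o1 = dfs_ordering(cycle3, ["a", "b", "c"])
    assert o1.sequence == dfs_ordering(cycle3, ["a", "b", "c"]).sequence
    o2 = dfs_ordering(cycle3, ["b", "c", "a"])
    assert o2.sequence == ("b", "c", "a")


def test_dfs_ordering_rejects_non_permutation(cycle3):
    with pytest.raises(ValueError, match="permutation"):
        dfs_ordering(cycle3, ["a", "b"])
    with pytest.raises(ValueError, match="permutation"):
        dfs_ordering(cycle3, ["a", "b", "b"])


def test_ordering_precedence_queries(chain3):
    o = dfs_ordering(chain3, ["g1", "g2", "g3"])
    assert o.precedes("g1", "g3") and not o.precedes("g3", "g1")
    assert o.position("g2") == 1


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------


def test_two_cycle_has_both_orderings():
    g = WeightedDigraph.from_edges([("a", "b"), ("b", "a")])
    out = exhaustive_scc_orderings(g)
    assert out.sequences() == {("a", "b"), ("b", "a")}
    assert out.exhausted


def test_three_cycle_has_exactly_the_rotations(cycle3):
    out = exhaustive_scc_orderings(cycle3)
    assert out.sequences() == {("a", "b", "c"), ("b", "c", "a"), ("c", "a", "b")}


def test_single_node_component():
    g = WeightedDigraph(["x"], np.zeros((1, 1)))
    out = exhaustive_scc_orderings(g)
    assert out.sequences() == {("x",)} and out.exhausted


def test_size_limit_error_points_to_mc_dfs():
    g = WeightedDigraph.from_edges(
        [(f"n{i}", f"n{(i + 1) % 12}") for i in range(12)]
    )
    with pytest.raises(ValueError, match="mc_dfs"):
        exhaustive_scc_orderings(g, max_size=10)


def test_rejects_non_strongly_connected_input(chain3):
    with pytest.raises(ValueError, match="strongly connected"):
        exhaustive_scc_orderings(chain3)


def _strongly_connected(adj) -> bool:
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    return nx.is_strongly_connected(g)


def test_exhaustive_equals_permutation_oracle_on_all_small_digraphs():
    """Every strongly connected digraph with <= 4 nodes: enumeration by
    backtracking over DFS executions equals the all-label-permutation
    universe."""
    checked = 0
    for p in (2, 3, 4):
        for adj in all_digraphs(p):
            if not _strongly_connected(adj):
                continue
            g = WeightedDigraph([f"n{i}" for i in range(p)], adj)
            assert exhaustive_scc_orderings(g).sequences() == permutation_universe(g)
            checked += 1
    assert checked > 100  # the 4-node case alone contributes hundreds


def test_per_scc_universe_on_general_small_digraphs():
    """On arbitrary (not necessarily connected) <= 4-node digraphs, every
    whole-graph DFS ordering restricted to one SCC is an ordering of that
    SCC's exhaustive universe.  (SCC blocks need not be contiguous in a
    whole-graph DFS, which is why per-component generation is the default.)"""
    rng = np.random.default_rng(0)
    graphs = [random_digraph(4, 0.4, seed=s) for s in range(25)]
    for g in graphs:
        part = scc_condense(g)
        universe = permutation_universe(g)
        per_scc = {}
        pos = {v: i for i, v in enumerate(g.node_ids)}
        for comp in part.components:
            members = sorted(comp, key=lambda v: pos[v])
            idx = [pos[v] for v in members]
            sub = WeightedDigraph(members, g.weights[np.ix_(idx, idx)])
            per_scc[comp] = exhaustive_scc_orderings(sub).sequences()
        for seq in universe:
            for comp in part.components:
                block = tuple(v for v in seq if v in comp)
                assert block in per_scc[comp]


# ---------------------------------------------------------------------------
# MC-DFS
# ---------------------------------------------------------------------------


def test_mc_dfs_is_deterministic_under_seed(cycle3):
    a = mc_dfs(cycle3, n_permutations=50, seed=42)
    b = mc_dfs(cycle3, n_permutations=50, seed=42)
    assert [o.sequence for o in a] == [o.sequence for o in b]
    assert not a.exhausted


def test_mc_dfs_covers_three_cycle_universe(cycle3):
    out = mc_dfs(cycle3, n_permutations=500, seed=0)
    assert out.sequences() == exhaustive_scc_orderings(cycle3).sequences()


@pytest.mark.parametrize("seed", range(5))
def test_mc_dfs_subset_of_universe_on_small_graphs(seed):
    g = random_digraph(4, edge_prob=0.45, seed=seed)
    out = mc_dfs(g, n_permutations=100, seed=seed)
    assert out.sequences() <= permutation_universe(g)


def test_mc_dfs_respects_edges_on_dag(diamond):
    out = mc_dfs(diamond, n_permutations=200, seed=1)
    for o in out:
        for u, v in diamond.edges():
            assert o.precedes(u, v)


# ---------------------------------------------------------------------------
# global (per-SCC combined) orderings
# ---------------------------------------------------------------------------


def _square_influence(g: WeightedDigraph) -> InfluenceMatrix:
    return InfluenceMatrix(g.node_ids, list(g.node_ids), g.adjacency)


def test_acyclic_influence_graph_yields_single_ordering(diamond):
    out = global_orderings(_square_influence(diamond), budget=100, seed=0)
    assert len(out) == 1 and out.exhausted
    (o,) = list(out)
    for u, v in diamond.edges():
        assert o.precedes(u, v)


def test_two_disjoint_two_cycles_give_cartesian_product():
    g = WeightedDigraph.from_edges(
        [("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")],
        node_ids=["a", "b", "c", "d"],
    )
    out = global_orderings(_square_influence(g), budget=100, seed=0)
    assert len(out) == 4 and out.exhausted
    blocks = {(seq[:2], seq[2:]) for seq in out.sequences()}
    assert len(blocks) == 4


def test_budget_truncation_returns_distinct_orderings():
    # 3 disjoint 3-cycles: universe of 27 orderings, budget 10
    edges = []
    for base in ("a", "b", "c"):
        names = [f"{base}{i}" for i in range(3)]
        edges += [(names[i], names[(i + 1) % 3]) for i in range(3)]
    g = WeightedDigraph.from_edges(edges)
    out = global_orderings(_square_influence(g), budget=10, seed=3)
    assert len(out) == 10 and not out.exhausted
    assert len(out.sequences()) == 10


def test_budget_must_be_positive(diamond):
    with pytest.raises(ValueError, match="budget"):
        global_orderings(_square_influence(diamond), budget=0)


@pytest.mark.parametrize("seed", range(4))
def test_global_orderings_respect_condensation_topo_order(seed):
    g = random_digraph(8, edge_prob=0.25, seed=seed)
    B = _square_influence(g)
    part = scc_condense(g)
    rank = {}
    for r, cidx in enumerate(part.topo_order):
        for v in part.components[cidx]:
            rank[v] = r
    out = global_orderings(B, budget=30, seed=seed)
    for o in out:
        comp_seq = [rank[v] for v in o.sequence]
        assert comp_seq == sorted(comp_seq)


def test_global_exhaustive_is_subset_of_whole_graph_universe():
    g = random_digraph(4, edge_prob=0.5, seed=11)
    out = global_orderings(_square_influence(g), budget=10_000, seed=0)
    if out.exhausted:
        assert out.sequences() <= permutation_universe(g)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_orderings_tsv_round_trip(tmp_path, cycle3):
    out = exhaustive_scc_orderings(cycle3)
    path = tmp_path / "orderings.tsv"
    write_orderings_tsv(path, out)
    back = read_orderings_tsv(path)
    assert back.sequences() == out.sequences()


def test_duplicate_orderings_rejected():
    o = CausalOrdering(("a", "b"))
    with pytest.raises(ValueError, match="duplicate"):
        from ripe.orderings import OrderingSet

        OrderingSet([o, CausalOrdering(("a", "b"))], budget=2)
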