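"""Causal orderings of an influence graph.

A *causal ordering* is the node listing produced by sorting DFS post-visit
times in descending order.  On an acyclic graph this specializes to a
topological sort; on a cyclic graph it is a linear listing in which not every
precedence implied by the edges can hold, and many distinct orderings exist.

The inference pipeline consumes a *set* of orderings.  They are produced
per strongly connected component (super-node): small components are
enumerated exhaustively by backtracking over every DFS execution; large ones
are sampled by MC-DFS, which draws random node relabelings and runs a
deterministic DFS under each.  Per-component orderings are concatenated along
one fixed topological order of the condensation and combined by Cartesian
product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .graph_core import (
    InfluenceMatrix,
    WeightedDigraph,
    _as_adjacency,
    dfs_post_order,
    scc_condense,
)

__all__ = [
    "CausalOrdering",
    "OrderingSet",
    "dfs_ordering",
    "exhaustive_scc_orderings",
    "mc_dfs",
    "global_orderings",
    "write_orderings_tsv",
    "read_orderings_tsv",
]

#: default largest SCC size still enumerated exhaustively; beyond this the
#: backtracking search grows combinatorially and MC-DFS takes over.
DEFAULT_EXHAUSTIVE_THRESHOLD = 10


@dataclass(frozen=True)
class CausalOrdering:
    """A permutation of node ids with O(1) precedence queries."""

    sequence: tuple
    source: str = "fixed"  # {exhaustive, mc_dfs, fixed}
    position_index: dict = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        seq = tuple(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(set(seq)) != len(seq):
            raise ValueError("ordering must be a permutation (no repeats)")
        object.__setattr__(
            self, "position_index", {v: i for i, v in enumerate(seq)}
        )

    def position(self, node) -> int:
        return self.position_index[node]

    def precedes(self, u, v) -> bool:
        return self.position_index[u] < self.position_index[v]

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self):
        return iter(self.sequence)


@dataclass
class OrderingSet:
    """A de-duplicated collection of causal orderings.

    ``exhausted`` is True only when the collection is provably the complete
    universe of orderings (every component enumerated exhaustively and the
    full Cartesian product retained).
    """

    orderings: list
    budget: int
    exhausted: bool = False

    def __post_init__(self) -> None:
        seqs = [o.sequence for o in self.orderings]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate orderings")

    def __len__(self) -> int:
        return len(self.orderings)

    def __iter__(self):
        return iter(self.orderings)

    def sequences(self) -> set:
        return {o.sequence for o in self.orderings}


# ---------------------------------------------------------------------------
# single deterministic DFS ordering
# ---------------------------------------------------------------------------


def dfs_ordering(g, label_order) -> CausalOrdering:
    """Causal ordering of ``g`` under one node labeling.

    DFS picks outer-loop roots and explores adjacency lists in ``label_order``
    (a permutation of the node ids); the ordering is the descending sort of
    post-visit times.  Deterministic given ``(g, label_order)``.
    """
    node_ids, adj = _as_adjacency(g)
    pos = {v: i for i, v in enumerate(node_ids)}
    label_order = list(label_order)
    if len(label_order) != len(node_ids) or set(label_order) != set(node_ids):
        raise ValueError("label_order must be a permutation of the graph nodes")
    idx_order = [pos[v] for v in label_order]
    post = dfs_post_order(adj, idx_order)
    order = np.argsort(-post, kind="stable")
    return CausalOrdering(tuple(node_ids[i] for i in order), source="fixed")


# ---------------------------------------------------------------------------
# exhaustive enumeration (backtracking over every DFS execution)
# ---------------------------------------------------------------------------


def _enumerate_dfs_orderings(adj: np.ndarray) -> set:
    """Every causal ordering reachable by *some* DFS execution.

    Backtracks over all free choices a DFS can make: which unvisited root to
    start the next tree at, and which unvisited out-neighbour to descend into.
    Returns orderings as tuples of node indices.  Exponential in the worst
    case; intended for small (sub)graphs.
    """
    p = adj.shape[0]
    nbrs = [list(np.nonzero(adj[i])[0]) for i in range(p)]
    results: set = set()
    visited = np.zeros(p, dtype=bool)
    post_seq: list = []
    stack: list = []

    def descend() -> None:
        if not stack:
            if len(post_seq) == p:
                results.add(tuple(reversed(post_seq)))
                return
            for r in range(p):
                if not visited[r]:
                    visited[r] = True
                    stack.append(r)
                    descend()
                    stack.pop()
                    visited[r] = False
            return
        node = stack[-1]
        choices = [v for v in nbrs[node] if not visited[v]]
        if not choices:
            post_seq.append(node)
            top = stack.pop()
            descend()
            stack.append(top)
            post_seq.pop()
            return
        for v in choices:
            visited[v] = True
            stack.append(v)
            descend()
            stack.pop()
            visited[v] = False

    descend()
    return results


def exhaustive_scc_orderings(
    scc_subgraph, max_size: int = DEFAULT_EXHAUSTIVE_THRESHOLD
) -> OrderingSet:
    """Complete universe of causal orderings of one strongly connected graph.

    The search is initiated at every node and backtracks over the adjacency
    choices of the traversal, so every ordering obtainable from some DFS
    execution is produced exactly once.

    Raises
    ------
    ValueError
        If the component has more than ``max_size`` nodes (use :func:`mc_dfs`)
        or is not strongly connected.
    """
    node_ids, adj = _as_adjacency(scc_subgraph)
    p = len(node_ids)
    if p > max_size:
        raise ValueError(
            f"component has {p} nodes > max_size={max_size}; "
            "use mc_dfs for large components"
        )
    if p > 1:
        part = scc_condense(scc_subgraph)
        if part.n_components != 1:
            raise ValueError("subgraph is not strongly connected")
    seqs = _enumerate_dfs_orderings(adj)
    orderings = [
        CausalOrdering(tuple(node_ids[i] for i in seq), source="exhaustive")
        for seq in sorted(seqs)
    ]
    return OrderingSet(orderings, budget=len(orderings), exhausted=True)


# ---------------------------------------------------------------------------
# MC-DFS sampling
# ---------------------------------------------------------------------------


def mc_dfs(g, n_permutations: int, seed) -> OrderingSet:
    """Sample causal orderings by DFS under random node relabelings.

    Draws ``n_permutations`` uniform random label permutations from a
    generator seeded with ``seed``, runs :func:`dfs_ordering` for each and
    de-duplicates.  Complexity O(M (p + e)).  ``exhausted`` is always
    reported False: the sample is never certified complete.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    node_ids, adj = _as_adjacency(g)
    rng = np.random.default_rng(seed)
    p = len(node_ids)
    seen: dict = {}
    for _ in range(int(n_permutations)):
        perm = rng.permutation(p)
        post = dfs_post_order(adj, list(perm))
        order = tuple(node_ids[i] for i in np.argsort(-post, kind="stable"))
        seen.setdefault(order)
    orderings = [CausalOrdering(s, source="mc_dfs") for s in seen]
    return OrderingSet(orderings, budget=int(n_permutations), exhausted=False)


# ---------------------------------------------------------------------------
# per-SCC combination
# ---------------------------------------------------------------------------


def global_orderings(
    B: InfluenceMatrix,
    budget: int,
    exhaustive_threshold: int = DEFAULT_EXHAUSTIVE_THRESHOLD,
    seed=0,
    method: str = "per_scc",
    mc_oversample: int = 4,
) -> OrderingSet:
    """Orderings of the whole influence graph.

    Condenses ``G_B``; every SCC of size <= ``exhaustive_threshold`` is
    enumerated exhaustively, larger ones are sampled by MC-DFS.  Per-SCC
    orderings are concatenated in the fixed condensation topological order
    and combined across SCCs by Cartesian product.  When the product exceeds
    ``budget``, distinct combinations are sampled uniformly by drawing
    per-SCC orderings independently.

    ``method="whole_graph"`` instead runs MC-DFS on the entire graph
    (random relabelings of all nodes at once); this can also permute
    incomparable super-node blocks.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not B.is_square:
        raise ValueError("global orderings require a square influence matrix")
    g = B.graph()
    if method == "whole_graph":
        out = mc_dfs(g, n_permutations=budget * mc_oversample, seed=seed)
        return OrderingSet(out.orderings[:budget], budget=budget, exhausted=False)
    if method != "per_scc":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    part = scc_condense(g)
    pos = {v: i for i, v in enumerate(g.node_ids)}

    per_scc: list[list[tuple]] = []
    all_exhausted = True
    for comp_idx in part.topo_order:
        members = sorted(part.components[comp_idx], key=lambda v: pos[v])
        idx = [pos[v] for v in members]
        sub = WeightedDigraph(members, g.weights[np.ix_(idx, idx)])
        if len(members) <= exhaustive_threshold:
            oset = exhaustive_scc_orderings(sub, max_size=exhaustive_threshold)
        else:
            oset = mc_dfs(
                sub,
                n_permutations=budget * mc_oversample,
                seed=rng.integers(2**31),
            )
            all_exhausted = False
        per_scc.append([o.sequence for o in oset.orderings])

    total = 1
    for block in per_scc:
        total *= len(block)
        if total > 10**9:  # avoid overflow-ish blowup; sampling path anyway
            break

    source = "exhaustive" if all_exhausted else "mc_dfs"
    if total <= budget:
        combos = [
            tuple(itertools.chain.from_iterable(choice))
            for choice in itertools.product(*per_scc)
        ]
        return OrderingSet(
            [CausalOrdering(c, source=source) for c in combos],
            budget=budget,
            exhausted=all_exhausted,
        )

    # uniform sampling without replacement over the product space
    chosen: dict = {}
    max_tries = 50 * budget
    tries = 0
    while len(chosen) < budget and tries < max_tries:
        tries += 1
        key = tuple(rng.integers(len(block)) for block in per_scc)
        chosen.setdefault(key)
    combos = [
        tuple(itertools.chain.from_iterable(block[i] for block, i in zip(per_scc, key)))
        for key in chosen
    ]
    return OrderingSet(
        [CausalOrdering(c, source="mc_dfs") for c in combos],
        budget=budget,
        exhausted=False,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_orderings_tsv(path, oset: OrderingSet) -> None:
    """One ordering per line, node ids tab-separated."""
    with open(path, "w") as fh:
        for o in oset.orderings:
            fh.write("\t".join(str(v) for v in o.sequence) + "\n")


def read_orderings_tsv(path, source: str = "fixed") -> OrderingSet:
    orderings = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                orderings.append(
                    CausalOrdering(tuple(line.split("\t")), source=source)
                )
    return OrderingSet(orderings, budget=len(orderings))
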