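"""Directed-graph data model for regulatory networks.

Conventions
-----------
Everywhere in this package, matrix entry ``(i, j)`` means the directed edge
``i -> j`` ("gene i influences/regulates gene j").  External files produced by
other tools sometimes store the transpose (entry ``(i, j)`` meaning "i is
regulated by j"); converters at I/O boundaries must transpose explicitly.

The module provides three containers:

* :class:`WeightedDigraph` -- the regulatory network itself, a ``p x p``
  real coefficient matrix over named genes;
* :class:`InfluenceMatrix` -- the binary ``k x p`` matrix recording which
  genes respond to each single-gene perturbation; when square it induces the
  directed *influence graph*;
* :class:`SCCPartition` -- strongly-connected-component condensation of a
  digraph together with one fixed topological order of the super-nodes.

plus the two graph algorithms the inference method is built on:
:func:`scc_condense` and :func:`ancestor_closure`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedDigraph",
    "InfluenceMatrix",
    "SCCPartition",
    "scc_condense",
    "ancestor_closure",
    "dfs_post_order",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_edge_list",
    "write_edge_list",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class WeightedDigraph:
    """A directed, weighted gene network.

    Parameters
    ----------
    node_ids
        Ordered gene identifiers; must be unique.
    weights
        ``p x p`` real matrix; entry ``(i, j)`` is the effect of gene ``i``
        on gene ``j`` and ``0`` means "no edge".  The diagonal must be zero
        (no self-regulation).
    """

    node_ids: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.node_ids)
        if len(set(self.node_ids)) != p:
            raise ValueError("node_ids must be unique")
        if self.weights.shape != (p, p):
            raise ValueError(
                f"weights must be {p}x{p}, got {self.weights.shape}"
            )
        if np.any(np.diagonal(self.weights) != 0):
            raise ValueError("self-loops are not allowed (nonzero diagonal)")

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary support of the weight matrix (dtype ``int8``)."""
        return (self.weights != 0).astype(np.int8)

    def index(self, node) -> int:
        return self.node_ids.index(node)

    def edges(self) -> set:
        """Directed edge set as ``(source_id, target_id)`` pairs."""
        rows, cols = np.nonzero(self.weights)
        return {(self.node_ids[i], self.node_ids[j]) for i, j in zip(rows, cols)}

    def successors(self, i: int) -> np.ndarray:
        """Indices of out-neighbours of node index ``i``."""
        return np.nonzero(self.weights[i])[0]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        node_ids: Sequence | None = None,
        default_weight: float = 1.0,
    ) -> "WeightedDigraph":
        """Build a graph from ``(source, target[, weight])`` tuples."""
        edges = [tuple(e) for e in edges]
        if node_ids is None:
            seen: dict = {}
            for e in edges:
                seen.setdefault(e[0])
                seen.setdefault(e[1])
            node_ids = list(seen)
        node_ids = list(node_ids)
        pos = {v: i for i, v in enumerate(node_ids)}
        w = np.zeros((len(node_ids), len(node_ids)))
        for e in edges:
            weight = float(e[2]) if len(e) > 2 else default_weight
            w[pos[e[0]], pos[e[1]]] = weight
        return cls(node_ids, w)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        for i, j in zip(*np.nonzero(self.weights)):
            g.add_edge(
                self.node_ids[i], self.node_ids[j], weight=self.weights[i, j]
            )
        return g


@dataclass
class InfluenceMatrix:
    """Binary influence matrix B of a perturbation screen.

    ``B[i, j] = 1`` iff perturbing gene ``perturbed_ids[i]`` changes the
    expression of gene ``target_ids[j]``.  Entries where a perturbed gene
    indexes itself are forced to zero: a knockout trivially changes its own
    gene and that carries no network information.

    When ``k = p`` (every gene perturbed, same ordering) the matrix defines
    the directed influence graph ``G_B`` with edge ``i -> j`` iff
    ``B[i, j] = 1``.
    """

    perturbed_ids: list
    target_ids: list
    B: np.ndarray

    def __post_init__(self) -> None:
        self.perturbed_ids = list(self.perturbed_ids)
        self.target_ids = list(self.target_ids)
        self.B = np.asarray(self.B)
        k, p = len(self.perturbed_ids), len(self.target_ids)
        if self.B.shape != (k, p):
            raise ValueError(f"B must be {k}x{p}, got {self.B.shape}")
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("influence matrix entries must be 0/1")
        self.B = self.B.astype(np.int8)
        tpos = {v: j for j, v in enumerate(self.target_ids)}
        for i, g in enumerate(self.perturbed_ids):
            j = tpos.get(g)
            if j is not None and self.B[i, j] != 0:
                raise ValueError("diagonal influence entries must be 0")

    @property
    def is_square(self) -> bool:
        return self.perturbed_ids == self.target_ids

    @property
    def k(self) -> int:
        return len(self.perturbed_ids)

    @property
    def p(self) -> int:
        return len(self.target_ids)

    def graph(self) -> WeightedDigraph:
        """Influence graph ``G_B`` (requires a square matrix)."""
        if not self.is_square:
            raise ValueError(
                "influence graph is only defined for a square (k = p) matrix"
            )
        return WeightedDigraph(self.target_ids, self.B.astype(float))

    def edges(self) -> set:
        rows, cols = np.nonzero(self.B)
        return {
            (self.perturbed_ids[i], self.target_ids[j])
            for i, j in zip(rows, cols)
        }

    def parents_of(self, j: int) -> np.ndarray:
        """Row indices i with ``B[i, j] = 1`` (influencers of target j)."""
        return np.nonzero(self.B[:, j])[0]


@dataclass
class SCCPartition:
    """SCC condensation of a digraph.

    ``components`` partition the node set into "super-nodes"; ``condensation``
    is the (acyclic) digraph on component indices; ``topo_order`` is one fixed
    topological order of component indices, computed deterministically as the
    descending maximum DFS post-visit time of each component, where the DFS
    visits nodes in label order.
    """

    components: list  # list of frozenset of node ids
    condensation: nx.DiGraph = field(repr=False)
    topo_order: list = field(default_factory=list)

    def component_of(self, node) -> int:
        for idx, comp in enumerate(self.components):
            if node in comp:
                return idx
        raise KeyError(node)

    @property
    def n_components(self) -> int:
        return len(self.components)


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------


def _adjacency_lists(adj: np.ndarray, label_order: Sequence[int]) -> list:
    """Out-neighbour lists, each sorted by position in ``label_order``."""
    rank = np.empty(adj.shape[0], dtype=int)
    rank[list(label_order)] = np.arange(adj.shape[0])
    return [
        sorted(np.nonzero(adj[i])[0], key=lambda v: rank[v])
        for i in range(adj.shape[0])
    ]


def dfs_post_order(
    adj: np.ndarray, label_order: Sequence[int] | None = None
) -> np.ndarray:
    """Post-visit times of an iterative DFS over a binary adjacency matrix.

    The DFS outer loop picks unvisited roots in ``label_order`` and each
    node's out-neighbours are explored in ``label_order`` as well; ties
    therefore never arise and the traversal is deterministic.  Returns an
    array ``post`` with ``post[v]`` the (1-based) post-visit time of node
    index ``v``.
    """
    p = adj.shape[0]
    if label_order is None:
        label_order = range(p)
    label_order = list(label_order)
    if sorted(label_order) != list(range(p)):
        raise ValueError("label_order must be a permutation of node indices")
    nbrs = _adjacency_lists(adj, label_order)
    post = np.zeros(p, dtype=int)
    visited = np.zeros(p, dtype=bool)
    clock = 0
    for root in label_order:
        if visited[root]:
            continue
        # stack of (node, iterator over remaining neighbours)
        stack = [(root, iter(nbrs[root]))]
        visited[root] = True
        clock += 1  # pre-visit tick
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if not visited[nxt]:
                    visited[nxt] = True
                    clock += 1
                    stack.append((nxt, iter(nbrs[nxt])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                clock += 1
                post[node] = clock
    return post


def _as_adjacency(g) -> tuple[list, np.ndarray]:
    """Accept a WeightedDigraph, square InfluenceMatrix, or nx.DiGraph."""
    if isinstance(g, WeightedDigraph):
        return g.node_ids, g.adjacency
    if isinstance(g, InfluenceMatrix):
        return g.target_ids, g.graph().adjacency
    if isinstance(g, nx.DiGraph):
        nodes = list(g.nodes)
        adj = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
        return nodes, (adj != 0).astype(np.int8)
    raise TypeError(f"unsupported graph type {type(g)!r}")


def scc_condense(g) -> SCCPartition:
    """Collapse each strongly connected component into a super-node.

    Returns the maximal SCCs, the acyclic condensation digraph on component
    indices, and one deterministic topological order of super-nodes: the
    descending maximum DFS post-visit time per component, with the DFS run in
    node-label order.  An acyclic input yields all-singleton components and
    the unique reverse-post-order listing.
    """
    node_ids, adj = _as_adjacency(g)
    if len(node_ids) == 0:
        raise ValueError("graph must have at least one node")
    nxg = nx.DiGraph()
    nxg.add_nodes_from(range(len(node_ids)))
    nxg.add_edges_from(zip(*np.nonzero(adj)))
    comps = [frozenset(c) for c in nx.strongly_connected_components(nxg)]
    comp_of = {}
    for idx, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = idx

    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(comps)))
    for i, j in zip(*np.nonzero(adj)):
        ci, cj = comp_of[i], comp_of[j]
        if ci != cj:
            cond.add_edge(ci, cj)

    # Kosaraju fact: descending max post time orders the condensation
    # topologically; DFS in label order makes it deterministic.
    post = dfs_post_order(adj)
    key = [max(post[v] for v in comp) for comp in comps]
    order = sorted(range(len(comps)), key=lambda c: -key[c])

    components = [frozenset(node_ids[v] for v in comp) for comp in comps]
    return SCCPartition(components, cond, order)


def ancestor_closure(g: WeightedDigraph) -> InfluenceMatrix:
    """True-influence matrix of a network: reachability by paths of length >= 1.

    ``B[i, j] = 1`` iff a directed path from ``i`` to ``j`` exists in ``g``;
    the diagonal is forced to zero.  This is exactly the influence matrix an
    error-free perturbation screen would measure: knocking out gene ``i``
    changes every gene downstream of it.  Works for cyclic graphs.
    """
    node_ids, adj = _as_adjacency(g)
    p = len(node_ids)
    reach = adj.astype(bool)
    # repeated squaring of the reachability relation: O(log p) products
    while True:
        step = reach.astype(np.int32)
        new = reach | ((step @ step) > 0)
        if (new == reach).all():
            break
        reach = new
    np.fill_diagonal(reach, False)
    return InfluenceMatrix(node_ids, list(node_ids), reach.astype(np.int8))


# ---------------------------------------------------------------------------
# I/O: dense TSV matrices and 3-column edge lists
# ---------------------------------------------------------------------------


def write_matrix_tsv(path, matrix: np.ndarray, row_ids, col_ids) -> None:
    """Write a dense matrix as TSV with id header row/column."""
    pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a dense TSV matrix with id header row/column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edge_list(path, g: WeightedDigraph) -> None:
    """Write ``source<TAB>target<TAB>weight`` lines (one per edge)."""
    rows, cols = np.nonzero(g.weights)
    df = pd.DataFrame(
        {
            "source": [g.node_ids[i] for i in rows],
            "target": [g.node_ids[j] for j in cols],
            "weight": g.weights[rows, cols],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path, node_ids: Sequence | None = None) -> WeightedDigraph:
    """Read a 3-column edge list TSV (weight optional, default 1)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    edges = []
    for _, row in df.iterrows():
        if "weight" in cols and not pd.isna(row.get("weight")):
            edges.append((row[cols[0]], row[cols[1]], float(row["weight"])))
        else:
            edges.append((row[cols[0]], row[cols[1]], 1.0))
    return WeightedDigraph.from_edges(edges, node_ids=node_ids)
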