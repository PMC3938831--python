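"""Synthetic benchmark data: random networks, SEM sampling, screens, noise.

The generator emulates the benchmark conditions used to validate the
inference method: sparse random DAGs with hub regulators and unregulated
source genes, linear-Gaussian structural equation models (SEM) for
steady-state expression, knockout screens simulated as do-interventions, and
controlled corruption of the influence matrix (reversed, spurious and
missing influence edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import ExpressionMatrix
from .graph_core import InfluenceMatrix, WeightedDigraph, ancestor_closure
from .influence import PerturbationScreen

__all__ = [
    "SimulationConfig",
    "random_dag",
    "random_cyclic",
    "sem_sample",
    "simulate_screen",
    "corrupt_influence",
    "fp_expected_count",
    "ideal_influence",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data protocols.

    p
        Number of genes.
    n
        Steady-state samples per draw (default 100).
    edge_weight
        Common magnitude of all regulatory coefficients (default 1.0, the
        unit-weight regime of the benchmark protocols).
    density
        Expected number of edges per node in the random graph.
    n_hubs
        Number of high-out-degree "hub" regulators planted in the DAG.
    r, r0
        Replicates per knockout condition and for the wild-type baseline.
    knockout_level
        Value the perturbed gene is clamped to (default -5 * noise_sd: a
        strong, easily detectable intervention).
    noise_sd
        SD of the SEM innovations epsilon (default 1.0).
    seed
        Seed for all randomness in the generator.
    """

    p: int
    n: int = 100
    edge_weight: float = 1.0
    density: float = 1.5
    n_hubs: int = 2
    r: int = 5
    r0: int = 5
    knockout_level: float | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.knockout_level is None:
            self.knockout_level = -5.0 * self.noise_sd


def _gene_ids(p: int) -> list:
    return [f"G{i + 1}" for i in range(p)]


def random_dag(cfg: SimulationConfig) -> WeightedDigraph:
    """Random hub-structured DAG with >= 2 unregulated source genes.

    Nodes are placed in a random causal order; each forward pair carries an
    edge with probability ``2 * density / (p - 1)`` (so the expected edge
    count is ``density * p``).  ``n_hubs`` randomly chosen non-terminal nodes
    are additionally wired to a large fraction of their downstream nodes,
    yielding the heavy-tailed out-degrees of regulatory networks.  The first
    two nodes in the causal order have their incoming edges removed so at
    least two genes are regulated by nothing.  All weights equal
    ``edge_weight``; the result is acyclic by construction.
    """
    p = cfg.p
    prob = 2.0 * cfg.density / (p - 1)
    if prob > 1:
        raise ValueError(
            f"density {cfg.density} infeasible for p={p} (edge prob > 1)"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(p)  # order[k] = node placed at causal position k
    W = np.zeros((p, p))
    upper = rng.random((p, p)) < prob
    for a in range(p):
        for b in range(a + 1, p):
            if upper[a, b]:
                W[order[a], order[b]] = cfg.edge_weight
    # hubs: boost out-degree towards downstream nodes
    if cfg.n_hubs > 0 and p > 4:
        hub_pos = rng.choice(max(1, p // 2), size=min(cfg.n_hubs, p // 2), replace=False)
        for a in hub_pos:
            downstream = order[a + 1 :]
            n_extra = max(3, int(0.2 * len(downstream)))
            targets = rng.choice(downstream, size=min(n_extra, len(downstream)), replace=False)
            W[order[a], targets] = cfg.edge_weight
    # at least two source genes: clear incoming edges of the two earliest nodes
    W[:, order[0]] = 0.0
    W[:, order[1]] = 0.0
    np.fill_diagonal(W, 0.0)
    return WeightedDigraph(_gene_ids(p), W)


def random_cyclic(
    cfg: SimulationConfig, spectral_cap: float = 0.9
) -> WeightedDigraph:
    """Random cyclic network with a well-defined stationary SEM.

    Starts from :func:`random_dag`, reverses-copies a fraction of existing
    edges as back-edges (guaranteeing at least one directed cycle), then
    rescales all weights so the spectral radius of ``|Theta|`` is at most
    ``spectral_cap`` < 1, which makes ``(I - Theta^T)`` invertible and the
    stationary covariance finite and positive definite.
    """
    if not (0 < spectral_cap < 1):
        raise ValueError("spectral_cap must lie in (0, 1)")
    rng = np.random.default_rng(cfg.seed + 1)
    g = random_dag(cfg)
    W = g.weights.copy()
    rows, cols = np.nonzero(W)
    n_back = max(1, int(round(0.1 * len(rows))))
    pick = rng.choice(len(rows), size=n_back, replace=False)
    for e in pick:
        i, j = rows[e], cols[e]
        W[j, i] = cfg.edge_weight  # back-edge closes a 2-cycle
    np.fill_diagonal(W, 0.0)
    rho = np.max(np.abs(np.linalg.eigvals(np.abs(W))))
    if rho >= spectral_cap:
        W *= spectral_cap / rho
    return WeightedDigraph(g.node_ids, W)


def _check_stable(weights: np.ndarray) -> None:
    rho = np.max(np.abs(np.linalg.eigvals(np.abs(weights))))
    if rho >= 1.0:
        raise ValueError(
            f"spectral radius of |Theta| is {rho:.3f} >= 1: SEM diverges"
        )


def sem_sample(
    g: WeightedDigraph, n: int, noise_sd: float = 1.0, seed=0
) -> ExpressionMatrix:
    """Draw n i.i.d. steady-state samples of the linear-Gaussian SEM.

    The model is ``X = Theta^T X + eps`` with ``eps ~ N(0, noise_sd^2 I)``,
    solved exactly as ``X = (I - Theta^T)^{-1} eps`` (for a DAG this equals
    propagation in topological order).  Output is zero-mean with covariance
    ``noise_sd^2 (I - Theta^T)^{-1} (I - Theta)^{-1}``.
    """
    _check_stable(g.weights)
    rng = np.random.default_rng(seed)
    p = g.n_nodes
    eps = rng.normal(scale=noise_sd, size=(n, p))
    M = np.linalg.inv(np.eye(p) - g.weights)  # X = eps @ (I - Theta)^{-1}
    return ExpressionMatrix(eps @ M, list(g.node_ids))


def simulate_screen(g: WeightedDigraph, cfg: SimulationConfig) -> PerturbationScreen:
    """Simulate a full single-gene knockout screen as do-interventions.

    For each gene i, its incoming edges are removed and its value clamped to
    ``knockout_level``; the rest of the system is sampled from the truncated
    SEM, r replicates per knockout.  Wild-type replicates come from the
    unperturbed model.  Matrices are genes x replicates.
    """
    _check_stable(g.weights)
    rng = np.random.default_rng(cfg.seed + 2)
    p = g.n_nodes
    if p != cfg.p:
        raise ValueError("graph size does not match cfg.p")
    expression = {}
    for i, gene in enumerate(g.node_ids):
        W = g.weights.copy()
        W[:, i] = 0.0  # cut incoming edges of the perturbed gene
        M = np.linalg.inv(np.eye(p) - W)
        eps = rng.normal(scale=cfg.noise_sd, size=(cfg.r, p))
        eps[:, i] = cfg.knockout_level  # clamp: X_i = knockout_level exactly
        expression[gene] = (eps @ M).T
    eps = rng.normal(scale=cfg.noise_sd, size=(cfg.r0, p))
    wildtype = (eps @ np.linalg.inv(np.eye(p) - g.weights)).T
    return PerturbationScreen(list(g.node_ids), expression, wildtype)


def fp_expected_count(fp_frac: float, p: int) -> float:
    """Expected number of spurious edges at a given false-positive level.

    False-positive levels are quoted as fractions of the ``p (p - 1) / 2``
    possible gene pairs; e.g. 1.5% on 100 genes is ~74 expected false edges.
    """
    return fp_frac * p * (p - 1) / 2.0


def corrupt_influence(
    B: InfluenceMatrix,
    reverse_frac: float = 0.0,
    fp: float = 0.0,
    fn_frac: float = 0.0,
    seed=0,
) -> InfluenceMatrix:
    """Inject structured noise into a (square) influence matrix.

    Three independent corruptions, applied in this order:

    1. *reversed directions*: a ``reverse_frac`` fraction of existing edges,
       chosen uniformly, have their direction flipped;
    2. *false negatives*: a ``fn_frac`` fraction of the (remaining original)
       edges are deleted uniformly at random;
    3. *false positives*: every absent off-diagonal pair gains an edge
       independently with probability ``E / n_non_edges``, where the expected
       count E is ``fp`` itself when ``fp >= 1``, or
       ``fp * p (p - 1) / 2`` when ``fp < 1`` (a false-positive *level*; see
       :func:`fp_expected_count`).

    All randomness comes from ``seed``.
    """
    for frac in (reverse_frac, fn_frac):
        if not (0 <= frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
    if not B.is_square:
        raise ValueError("corruption is defined for square influence matrices")
    rng = np.random.default_rng(seed)
    M = B.B.astype(np.int8).copy()
    p = M.shape[0]

    rows, cols = np.nonzero(M)
    n_edges = len(rows)
    # 1. direction reversals
    n_rev = int(round(reverse_frac * n_edges))
    if n_rev > 0:
        pick = rng.choice(n_edges, size=n_rev, replace=False)
        for e in pick:
            i, j = rows[e], cols[e]
            M[i, j] = 0
            M[j, i] = 1
    # 2. false negatives among surviving original edges
    if fn_frac > 0:
        orig = [
            (i, j) for i, j in zip(rows, cols) if M[i, j] == 1
        ]
        n_del = int(round(fn_frac * len(orig)))
        if n_del > 0:
            pick = rng.choice(len(orig), size=n_del, replace=False)
            for e in pick:
                M[orig[e]] = 0
    # 3. false positives on absent pairs
    if fp > 0:
        expected = fp if fp >= 1 else fp_expected_count(fp, p)
        absent = np.argwhere((M == 0) & ~np.eye(p, dtype=bool))
        prob = min(1.0, expected / len(absent))
        add = rng.random(len(absent)) < prob
        for i, j in absent[add]:
            M[i, j] = 1
    np.fill_diagonal(M, 0)
    return InfluenceMatrix(list(B.perturbed_ids), list(B.target_ids), M)


def ideal_influence(g: WeightedDigraph) -> InfluenceMatrix:
    """Influence matrix of a perfect screen: the ancestor closure of ``g``."""
    return ancestor_closure(g)
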