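"""Penalized per-ordering estimation: penalty, candidate sets, fits, scores."""

import numpy as np
import pytest
from scipy import stats

from ripe.estimation import (
    ExpressionMatrix,
    PenaltyConfig,
    consistent_parents,
    fit_ordering,
    fit_orderings,
    fit_two_layer,
    lambda_penalty,
    pnll_score,
)
from ripe.evaluate import prf
from ripe.graph_core import InfluenceMatrix, WeightedDigraph, ancestor_closure
from ripe.orderings import CausalOrdering
from ripe.simulate import SimulationConfig, random_dag, sem_sample


# ---------------------------------------------------------------------------
# lambda penalty
# ---------------------------------------------------------------------------


def test_lambda_matches_normal_quantile_oracle():
    lam = lambda_penalty(j_position=2, n=100, p=50, alpha=0.1)
    expected = 2.0 / np.sqrt(100) * stats.norm.ppf(1 - 0.1 / (2 * 50 * 1))
    assert lam == pytest.approx(expected, rel=1e-12)
    assert lam > 0


def test_lambda_monotonicities():
    base = lambda_penalty(3, 100, 50, 0.1)
    assert lambda_penalty(3, 400, 50, 0.1) < base  # decreasing in n
    assert lambda_penalty(3, 100, 50, 0.01) > base  # stricter alpha
    assert lambda_penalty(3, 10**8, 50, 0.1) < 1e-3  # vanishes as n grows


def test_lambda_rejects_first_position():
    with pytest.raises(ValueError, match="j_position"):
        lambda_penalty(1, 100, 50, 0.1)


# ---------------------------------------------------------------------------
# candidate parent sets
# ---------------------------------------------------------------------------


def _chain_closure():
    g = WeightedDigraph.from_edges(
        [("g1", "g2"), ("g2", "g3")], node_ids=["g1", "g2", "g3"]
    )
    return ancestor_closure(g)


def test_first_node_has_no_candidates():
    B = _chain_closure()
    o = CausalOrdering(("g1", "g2", "g3"))
    assert consistent_parents("g1", o, B) == set()


def test_chain_closure_candidates():
    B = _chain_closure()
    o = CausalOrdering(("g1", "g2", "g3"))
    assert consistent_parents("g3", o, B) == {"g1", "g2"}
    assert consistent_parents("g2", o, B) == {"g1"}


@pytest.mark.parametrize("seed", range(5))
def test_candidates_match_brute_force_filter(seed):
    rng = np.random.default_rng(seed)
    p = 8
    ids = [f"g{i}" for i in range(p)]
    M = (rng.random((p, p)) < 0.3).astype(np.int8)
    np.fill_diagonal(M, 0)
    B = InfluenceMatrix(ids, list(ids), M)
    seq = tuple(rng.permutation(ids))
    o = CausalOrdering(seq)
    for j in ids:
        expected = {
            i
            for i in ids
            if seq.index(i) < seq.index(j) and M[ids.index(i), ids.index(j)]
        }
        assert consistent_parents(j, o, B) == expected


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _ideal_setup(p, n, seed, density=1.2):
    cfg = SimulationConfig(p=p, n=n, density=density, n_hubs=2, seed=seed)
    g = random_dag(cfg)
    B = ancestor_closure(g)
    X = sem_sample(g, n=n, seed=seed + 100)
    order = CausalOrdering(
        tuple(
            sorted(
                g.node_ids,
                key=lambda v: -_post_depth(g, v),
            )
        )
    )
    return g, B, X, order


def _post_depth(g, v):
    """Longest path from v (used to build one valid topological order)."""
    i = g.index(v)
    succ = np.nonzero(g.weights[i])[0]
    if len(succ) == 0:
        return 0
    return 1 + max(_post_depth(g, g.node_ids[s]) for s in succ)


def test_all_zero_influence_gives_null_model():
    rng = np.random.default_rng(0)
    ids = ["a", "b", "c"]
    X = ExpressionMatrix(rng.normal(size=(50, 3)), ids)
    B = InfluenceMatrix(ids, list(ids), np.zeros((3, 3), dtype=int))
    dag = fit_ordering(X, CausalOrdering(("a", "b", "c")), B)
    assert (dag.coefficients == 0).all()
    Xc = X.values - X.values.mean(axis=0)
    assert dag.pnll == pytest.approx((Xc**2).sum() / (2 * 50))


def test_chain_recovery_with_true_ordering():
    """Chain SEM at n=500, low noise: estimated support equals chain edges."""
    g = WeightedDigraph.from_edges(
        [("g1", "g2", 1.0), ("g2", "g3", 1.0), ("g3", "g4", 1.0)],
        node_ids=["g1", "g2", "g3", "g4"],
    )
    X = sem_sample(g, n=500, noise_sd=0.5, seed=1)
    dag = fit_ordering(
        X, CausalOrdering(("g1", "g2", "g3", "g4")), ancestor_closure(g)
    )
    assert dag.edges() == g.edges()


def test_incomparable_swap_is_exactly_invariant():
    """Swapping two adjacent nodes with no influence edge between them leaves
    coefficients and pnll exactly unchanged."""
    # b and c are not related in the influence graph; both depend on a
    g = WeightedDigraph.from_edges(
        [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")],
        node_ids=["a", "b", "c", "d"],
    )
    B = ancestor_closure(g)
    X = sem_sample(g, n=80, seed=3)
    d1 = fit_ordering(X, CausalOrdering(("a", "b", "c", "d")), B)
    d2 = fit_ordering(X, CausalOrdering(("a", "c", "b", "d")), B)
    np.testing.assert_array_equal(d1.coefficients, d2.coefficients)
    assert d1.pnll == d2.pnll


@pytest.mark.parametrize("seed", range(4))
def test_support_is_acyclic_and_within_influence_edges(seed):
    from ripe.orderings import global_orderings

    rng = np.random.default_rng(seed)
    p = 12
    ids = [f"g{i}" for i in range(p)]
    M = (rng.random((p, p)) < 0.25).astype(np.int8)
    np.fill_diagonal(M, 0)
    B = InfluenceMatrix(ids, list(ids), M)
    X = ExpressionMatrix(rng.normal(size=(60, p)), ids)
    oset = global_orderings(B, budget=10, seed=seed)
    for dag in fit_orderings(X, oset, B):
        assert dag.edges() <= B.edges()
        # acyclicity: support respects the ordering positions
        pos = dag.ordering.position_index
        for i, j in dag.edges():
            assert pos[i] < pos[j]


def test_min_sample_count_enforced():
    ids = ["a", "b"]
    X = ExpressionMatrix(np.zeros((1, 2)), ids)
    B = InfluenceMatrix(ids, list(ids), np.zeros((2, 2), dtype=int))
    with pytest.raises(ValueError, match="2 expression samples"):
        fit_ordering(X, CausalOrdering(("a", "b")), B)


# ---------------------------------------------------------------------------
# pnll score
# ---------------------------------------------------------------------------


def test_pnll_independent_reimplementation_agrees():
    """Score recomputed by explicit loops on a 4-gene fixture matches the
    fitted pnll and pnll_score to 1e-8."""
    g, B, X, order = _ideal_setup(p=4, n=60, seed=9, density=1.0)
    cfg = PenaltyConfig(alpha=0.1)
    dag = fit_ordering(X, order, B, cfg)

    Xc = X.values - X.values.mean(axis=0)
    n = X.n_samples
    total = 0.0
    for j, gene in enumerate(X.gene_ids):
        resid = Xc[:, j] - Xc @ dag.coefficients[:, j]
        total += float(resid @ resid) / (2 * n)
        lam = dag.node_lambdas[gene]
        total += lam * float(np.abs(dag.coefficients[:, j]).sum())
    assert dag.pnll == pytest.approx(total, abs=1e-8)
    assert pnll_score(X, dag, cfg) == pytest.approx(total, abs=1e-8)


def test_adding_a_useful_edge_lowers_pnll():
    g = WeightedDigraph.from_edges([("a", "b", 1.0)], node_ids=["a", "b"])
    X = sem_sample(g, n=200, seed=2)
    B = ancestor_closure(g)
    order = CausalOrdering(("a", "b"))
    fitted = fit_ordering(X, order, B)
    null = fitted.__class__(
        order, np.zeros((2, 2)), ["a", "b"], node_lambdas=fitted.node_lambdas
    )
    assert fitted.pnll < pnll_score(X, null)


# ---------------------------------------------------------------------------
# consistency in n
# ---------------------------------------------------------------------------


def test_support_recovery_improves_with_sample_size():
    """Median F1 of support recovery (ideal influence matrix, true ordering)
    is non-decreasing over n in {50, 200, 1000}."""
    medians = []
    for n in (50, 200, 1000):
        scores = []
        for seed in range(20):
            g, B, X, order = _ideal_setup(p=15, n=n, seed=seed)
            dag = fit_ordering(X, order, B)
            scores.append(prf(dag.edges(), g.edges()).f1)
        medians.append(np.median(scores))
    assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9
    assert medians[-1] >= 95.0


# ---------------------------------------------------------------------------
# two-layer mode
# ---------------------------------------------------------------------------


def test_two_layer_reduces_to_standard_fit_when_all_perturbed():
    g, B, X, order = _ideal_setup(p=6, n=80, seed=4, density=1.0)
    full = fit_ordering(X, order, B)
    two = fit_two_layer(X, X.gene_ids, B, [order])[0]
    np.testing.assert_array_equal(full.coefficients, two.coefficients)
    assert full.pnll == pytest.approx(two.pnll)


def test_two_layer_without_influence_edges_gives_no_target_edges():
    rng = np.random.default_rng(5)
    ids = ["tf1", "tf2", "t1", "t2"]
    X = ExpressionMatrix(rng.normal(size=(40, 4)), ids)
    B = InfluenceMatrix(["tf1", "tf2"], list(ids), np.zeros((2, 4), dtype=int))
    dag = fit_two_layer(X, ["tf1", "tf2"], B, [CausalOrdering(("tf1", "tf2"))])[0]
    assert (dag.coefficients == 0).all()


def test_two_layer_recovers_tf_target_structure():
    """5 TFs regulating 20 targets: recovered support matches the generator
    and never contains an edge leaving an unperturbed target."""
    rng = np.random.default_rng(6)
    tfs = [f"tf{i}" for i in range(5)]
    targets = [f"t{i}" for i in range(20)]
    ids = tfs + targets
    W = np.zeros((25, 25))
    W[1, 0] = 1.0  # one TF regulating another
    for j in range(5, 25):  # each target gets 1-2 TF parents
        for i in rng.choice(5, size=rng.integers(1, 3), replace=False):
            W[i, j] = 1.0
    g = WeightedDigraph(ids, W)
    X = sem_sample(g, n=400, seed=7)
    Bfull = ancestor_closure(g)
    rows = [ids.index(t) for t in tfs]
    B = InfluenceMatrix(tfs, ids, Bfull.B[rows, :])
    order = CausalOrdering(("tf1", "tf0", "tf2", "tf3", "tf4"))
    dag = fit_two_layer(X, tfs, B, [order])[0]
    assert dag.edges() == g.edges()
    for i, j in dag.edges():
        assert i in tfs  # no edges out of unperturbed genes


def test_two_layer_requires_perturbed_subset():
    rng = np.random.default_rng(8)
    ids = ["a", "b"]
    X = ExpressionMatrix(rng.normal(size=(10, 2)), ids)
    B = InfluenceMatrix(["z"], ["z"], np.zeros((1, 1), dtype=int))
    with pytest.raises(ValueError, match="subset"):
        fit_two_layer(X, ["z"], B, [CausalOrdering(("z",))])
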