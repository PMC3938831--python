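"""Scoring of estimated networks against a gold standard.

Precision, recall and F1 over directed (or optionally undirected) edge sets,
plus a permutation-style significance test: how often do Erdos-Renyi random
graphs with the same number of edges achieve at least as many true positives
as the estimate?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "prf", "random_graph_tp_test"]


@dataclass
class EvalReport:
    """Edge-recovery scores, in percent."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    directed: bool = True


def _undirect(edges) -> set:
    return {frozenset(e) for e in edges if e[0] != e[1]}


def prf(estimate, truth, directed: bool = True) -> EvalReport:
    """Precision/recall/F1 of an estimated edge set against the truth.

    Directed comparison by default; ``directed=False`` collapses edge
    direction on both sides (for comparing against undirected estimators).
    Scores are percentages; empty denominators score 0.
    """
    est = set(map(tuple, estimate)) if directed else _undirect(estimate)
    tru = set(map(tuple, truth)) if directed else _undirect(truth)
    tp = len(est & tru)
    fp = len(est - tru)
    fn = len(tru - est)
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return EvalReport(tp, fp, fn, precision, recall, f1, directed=directed)


def random_graph_tp_test(
    estimate, gold, nodes, n_rand: int = 10_000, seed=0
) -> float:
    """Empirical p-value for the observed true-positive count.

    Draws ``n_rand`` Erdos-Renyi random directed graphs with exactly
    ``|estimate|`` edges on the given node universe (edge-uniform, no
    self-loops), counts true positives against ``gold``, and returns

        (1 + #{random graphs with TP >= observed TP}) / (n_rand + 1).

    The plus-one correction keeps the p-value strictly positive under a
    finite Monte-Carlo null.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    nodes = list(nodes)
    p = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    est = set(map(tuple, estimate))
    m = len(est)
    gold_idx = {
        pos[a] * p + pos[b] for a, b in map(tuple, gold) if a in pos and b in pos
    }
    observed = sum(
        1 for a, b in est if a in pos and b in pos and pos[a] * p + pos[b] in gold_idx
    )
    if m == 0:
        return 1.0
    # enumerate ordered non-self pairs as flat codes 0 .. p(p-1)-1
    codes = np.array(
        [i * p + j for i in range(p) for j in range(p) if i != j], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_rand)):
        sample = rng.choice(codes, size=m, replace=False)
        tp = sum(1 for c in sample if int(c) in gold_idx)
        if tp >= observed:
            hits += 1
    return (1 + hits) / (n_rand + 1)
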