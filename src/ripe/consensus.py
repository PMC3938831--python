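"""Consensus network from the best-scoring per-ordering estimates.

The per-ordering DAGs whose penalized negative log-likelihood falls in the
lower q-th quantile are averaged: the edge confidence Lambda_ij is the
fraction of selected DAGs in which the coefficient theta_ij is nonzero, and
the final edge set keeps entries with Lambda_ij > tau.  Because different
orderings orient feedback loops differently, the consensus may contain
cycles even though every individual estimate is acyclic.  Sign and magnitude
matrices summarize the mean coefficient over the same selected set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import ScoredDAG

__all__ = [
    "ConsensusNetwork",
    "consensus",
    "select_dags",
    "sign_magnitude",
    "sweep",
    "write_consensus_edges",
]

#: defaults; accuracy is flat across a broad range of both knobs, and these
#: sit in the middle of that plateau.
DEFAULT_Q = 0.2
DEFAULT_TAU = 0.3


@dataclass
class ConsensusNetwork:
    """Edge-confidence summary of an ensemble of per-ordering DAGs.

    ``confidence[i, j]`` in [0, 1] is the fraction of selected DAGs containing
    edge i -> j; ``sign``/``magnitude`` are the sign and absolute value of the
    mean coefficient over the selected set; ``edges`` holds the pairs with
    confidence strictly above ``tau``.
    """

    gene_ids: list
    confidence: np.ndarray
    sign: np.ndarray
    magnitude: np.ndarray
    tau: float
    q: float
    n_selected: int

    def __post_init__(self) -> None:
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence entries must lie in [0, 1]")

    @property
    def edge_mask(self) -> np.ndarray:
        return self.confidence > self.tau

    @property
    def edges(self) -> set:
        rows, cols = np.nonzero(self.edge_mask)
        return {(self.gene_ids[i], self.gene_ids[j]) for i, j in zip(rows, cols)}

    def to_frame(self) -> pd.DataFrame:
        """Selected edges as a table: source, target, confidence, sign, magnitude."""
        rows, cols = np.nonzero(self.edge_mask)
        return pd.DataFrame(
            {
                "source": [self.gene_ids[i] for i in rows],
                "target": [self.gene_ids[j] for j in cols],
                "confidence": self.confidence[rows, cols],
                "sign": self.sign[rows, cols].astype(int),
                "magnitude": self.magnitude[rows, cols],
            }
        )


def select_dags(dags: list, q: float) -> list:
    """DAGs whose pnll is <= the lower q-th quantile of all pnll values.

    At least one DAG is always selected; pnll ties at the threshold are all
    included.
    """
    if not dags:
        raise ValueError("need at least one ScoredDAG")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    scores = np.array([d.pnll for d in dags])
    cut = np.quantile(scores, q)
    chosen = [d for d, s in zip(dags, scores) if s <= cut]
    if not chosen:  # guard: numerical quantile below the minimum
        chosen = [dags[int(np.argmin(scores))]]
    return chosen


def sign_magnitude(selected_dags: list) -> tuple[np.ndarray, np.ndarray]:
    """Sign and magnitude of the mean coefficient over the selected DAGs.

    For each pair (i, j) the coefficients are averaged over the selected set
    (zeros included where an estimate lacks the edge); S = sign of the mean,
    M = its absolute value.  Opposite-signed coefficients can cancel to zero.
    """
    if not selected_dags:
        raise ValueError("selected_dags must be nonempty")
    mean_theta = np.mean([d.coefficients for d in selected_dags], axis=0)
    return np.sign(mean_theta), np.abs(mean_theta)


def consensus(
    dags: list, q: float = DEFAULT_Q, tau: float = DEFAULT_TAU
) -> ConsensusNetwork:
    """Average the best-scoring per-ordering DAGs into a consensus network."""
    if not (0 <= tau < 1):
        raise ValueError("tau must lie in [0, 1)")
    chosen = select_dags(dags, q)
    gene_ids = chosen[0].gene_ids
    for d in chosen:
        if d.gene_ids != gene_ids:
            raise ValueError("all DAGs must share the same gene ids")
    conf = np.mean([d.support() for d in chosen], axis=0)
    sign, mag = sign_magnitude(chosen)
    return ConsensusNetwork(
        list(gene_ids), conf, sign, mag, tau=tau, q=q, n_selected=len(chosen)
    )


def sweep(dags: list, q_grid, tau_grid) -> pd.DataFrame:
    """Edge counts over a (q, tau) grid, for sensitivity checks."""
    records = []
    for q in q_grid:
        chosen = select_dags(dags, float(q))
        conf = np.mean([d.support() for d in chosen], axis=0)
        for tau in tau_grid:
            records.append(
                {
                    "q": float(q),
                    "tau": float(tau),
                    "n_selected": len(chosen),
                    "n_edges": int((conf > float(tau)).sum()),
                }
            )
    return pd.DataFrame.from_records(records)


def write_consensus_edges(path, net: ConsensusNetwork) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False)
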