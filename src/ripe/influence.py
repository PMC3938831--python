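"""Influence-matrix estimation from replicated perturbation screens.

Each single-gene knockout/knockdown is compared gene-by-gene against the
wild-type baseline with a two-sample test; thresholding the resulting p-value
matrix yields the binary influence matrix B.  A diagnostic table over a grid
of cutoffs (edge count and largest connected component size) supports picking
the cutoff: in a modular network, a sharp drop in the largest component marks
the point where noise edges have been removed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_core import InfluenceMatrix

__all__ = [
    "PerturbationScreen",
    "PvalueMatrix",
    "differential_expression",
    "threshold_influence",
    "cutoff_diagnostics",
    "write_screen",
    "read_screen",
]


@dataclass
class PerturbationScreen:
    """Replicated expression profiles for each perturbation plus wild-type.

    ``expression[g]`` is the (p genes x r replicates) matrix measured under
    the perturbation of gene ``g``; ``wildtype`` is (p x r0).  All matrices
    share ``gene_ids`` row order.  At least two replicates per condition are
    required so that within-group variances are estimable.
    """

    gene_ids: list
    expression: dict  # perturbed gene id -> (p x r) array
    wildtype: np.ndarray  # (p x r0)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        p = len(self.gene_ids)
        self.wildtype = np.asarray(self.wildtype, dtype=float)
        if self.wildtype.shape[0] != p:
            raise ValueError("wildtype rows must match gene_ids")
        if self.wildtype.shape[1] < 2:
            raise ValueError("need >= 2 wild-type replicates")
        self.expression = {
            g: np.asarray(m, dtype=float) for g, m in self.expression.items()
        }
        for g, m in self.expression.items():
            if m.shape[0] != p:
                raise ValueError(f"screen for {g!r}: rows must match gene_ids")
            if m.shape[1] < 2:
                raise ValueError(f"screen for {g!r}: need >= 2 replicates")
            if g not in self.gene_ids:
                raise ValueError(f"perturbed gene {g!r} not in gene_ids")

    @property
    def perturbed_ids(self) -> list:
        return list(self.expression)


@dataclass
class PvalueMatrix:
    """Two-sided p-values of knockout-vs-wildtype differential expression.

    ``P[i, j]`` tests gene ``target_ids[j]`` under the perturbation of
    ``perturbed_ids[i]``.  Self-comparisons are set to 1: a perturbed gene's
    own response carries no edge information.
    """

    perturbed_ids: list
    target_ids: list
    P: np.ndarray
    method: str = "welch"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.perturbed_ids), len(self.target_ids)):
            raise ValueError("P shape mismatch")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def _self_mask(perturbed_ids, target_ids) -> np.ndarray:
    tpos = {v: j for j, v in enumerate(target_ids)}
    mask = np.zeros((len(perturbed_ids), len(target_ids)), dtype=bool)
    for i, g in enumerate(perturbed_ids):
        if g in tpos:
            mask[i, tpos[g]] = True
    return mask


def _pooled_t(ko: np.ndarray, wt: np.ndarray, var_floor: float) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values per gene (rows)."""
    r, r0 = ko.shape[1], wt.shape[1]
    m1, m0 = ko.mean(axis=1), wt.mean(axis=1)
    v1 = ko.var(axis=1, ddof=1)
    v0 = wt.var(axis=1, ddof=1)
    sp2 = ((r - 1) * v1 + (r0 - 1) * v0) / (r + r0 - 2)
    sp2 = np.maximum(sp2, var_floor)
    se = np.sqrt(sp2 * (1.0 / r + 1.0 / r0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / se
    df = r + r0 - 2
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance in both groups: equal means -> no evidence, p = 1;
    # different means -> infinitely strong evidence, p = 0
    dead = ~np.isfinite(t)
    pvals[dead] = np.where(np.isclose(m1[dead], m0[dead]), 1.0, 0.0)
    return pvals


def differential_expression(
    screen: PerturbationScreen, method: str = "welch"
) -> PvalueMatrix:
    """Per-entry two-sample tests of each perturbation against wild-type.

    Parameters
    ----------
    screen
        The replicated perturbation screen.
    method
        ``"welch"`` (default): unequal-variance two-sample t.
        ``"pooled"``: classical pooled-variance t.
        ``"moderated"``: pooled-variance t with the per-gene pooled variance
        floored at the median pooled variance across all genes, a simple
        variance-stabilization in the small-replicate regime.

    Returns
    -------
    PvalueMatrix
        k x p two-sided p-values with self-comparisons forced to 1.
    """
    if method not in {"welch", "pooled", "moderated"}:
        raise ValueError(f"unknown method {method!r}")
    perturbed = screen.perturbed_ids
    wt = screen.wildtype
    rows = []
    if method == "moderated":
        # shared floor computed over every condition's pooled variances
        all_sp2 = []
        for g in perturbed:
            ko = screen.expression[g]
            r, r0 = ko.shape[1], wt.shape[1]
            sp2 = (
                (r - 1) * ko.var(axis=1, ddof=1)
                + (r0 - 1) * wt.var(axis=1, ddof=1)
            ) / (r + r0 - 2)
            all_sp2.append(sp2)
        var_floor = float(np.median(np.concatenate(all_sp2)))
    for g in perturbed:
        ko = screen.expression[g]
        if method == "welch":
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                # constant rows (e.g. the clamped gene itself) trigger a scipy
                # precision warning; those entries are overwritten below
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(ko, wt, axis=1, equal_var=False)
            pv = np.asarray(res.pvalue, dtype=float)
            bad = ~np.isfinite(pv)
            if bad.any():
                eq = np.isclose(ko.mean(axis=1)[bad], wt.mean(axis=1)[bad])
                pv[bad] = np.where(eq, 1.0, 0.0)
        elif method == "pooled":
            pv = _pooled_t(ko, wt, var_floor=0.0)
        else:
            pv = _pooled_t(ko, wt, var_floor=var_floor)
        rows.append(pv)
    P = np.vstack(rows)
    P[_self_mask(perturbed, screen.gene_ids)] = 1.0
    return PvalueMatrix(perturbed, list(screen.gene_ids), P, method=method)


def threshold_influence(
    P: PvalueMatrix, cutoff: float, adjust: str = "none"
) -> InfluenceMatrix:
    """Binary influence matrix from a p-value matrix.

    ``B[i, j] = 1`` iff the (optionally Benjamini-Hochberg adjusted) p-value
    is <= ``cutoff``; self-entries stay 0.  BH adjustment is applied over the
    family of all non-self entries.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    if adjust not in {"none", "bh"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    vals = P.P.copy()
    mask = _self_mask(P.perturbed_ids, P.target_ids)
    if adjust == "bh":
        flat = vals[~mask]
        adj = multipletests(flat, method="fdr_bh")[1]
        vals[~mask] = adj
    B = (vals <= cutoff).astype(np.int8)
    B[mask] = 0
    return InfluenceMatrix(P.perturbed_ids, P.target_ids, B)


def cutoff_diagnostics(
    P: PvalueMatrix, grid, adjust: str = "none"
) -> pd.DataFrame:
    """Edge count and largest-component size over a grid of cutoffs.

    For each cutoff the influence graph is thresholded and the size of the
    largest connected component of its *undirected* skeleton is recorded
    (isolated nodes count as components of size 1).  The table, sorted by
    cutoff, is the diagnostic used to pick the cutoff: a drop in the largest
    component as the cutoff decreases signals the removal of noise edges that
    bridge otherwise separate modules.
    """
    grid = sorted(float(c) for c in grid)
    if not grid or any(not (0 < c <= 1) for c in grid):
        raise ValueError("grid must be nonempty with cutoffs in (0, 1]")
    records = []
    for c in grid:
        B = threshold_influence(P, c, adjust=adjust)
        g = nx.Graph()
        g.add_nodes_from(set(B.perturbed_ids) | set(B.target_ids))
        g.add_edges_from(B.edges())
        largest = max(len(cc) for cc in nx.connected_components(g))
        records.append(
            {"cutoff": c, "n_edges": int(B.B.sum()), "largest_component": largest}
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# I/O: one TSV per condition plus a manifest
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"


def write_screen(directory, screen: PerturbationScreen) -> None:
    """Write a screen as per-condition TSVs plus a manifest.

    The manifest maps each file to its perturbed gene; the wild-type row is
    flagged with ``is_wildtype = 1`` and an empty perturbed gene.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []

    def _dump(name: str, mat: np.ndarray) -> None:
        cols = [f"rep{r + 1}" for r in range(mat.shape[1])]
        pd.DataFrame(mat, index=screen.gene_ids, columns=cols).to_csv(
            os.path.join(directory, name), sep="\t"
        )

    _dump("wildtype.tsv", screen.wildtype)
    rows.append({"file": "wildtype.tsv", "perturbed_gene": "", "is_wildtype": 1})
    for g in screen.perturbed_ids:
        fname = f"ko_{g}.tsv"
        _dump(fname, screen.expression[g])
        rows.append({"file": fname, "perturbed_gene": g, "is_wildtype": 0})
    pd.DataFrame(rows).to_csv(
        os.path.join(directory, MANIFEST_NAME), sep="\t", index=False
    )


def read_screen(directory) -> PerturbationScreen:
    manifest = pd.read_csv(
        os.path.join(directory, MANIFEST_NAME), sep="\t", dtype={"perturbed_gene": str}
    )
    wildtype = None
    expression = {}
    gene_ids = None
    for _, row in manifest.iterrows():
        df = pd.read_csv(os.path.join(directory, row["file"]), sep="\t", index_col=0)
        if gene_ids is None:
            gene_ids = [str(v) for v in df.index]
        if int(row["is_wildtype"]):
            wildtype = df.to_numpy()
        else:
            expression[str(row["perturbed_gene"])] = df.to_numpy()
    if wildtype is None:
        raise ValueError("manifest contains no wild-type entry")
    return PerturbationScreen(gene_ids, expression, wildtype)
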