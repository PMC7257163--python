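"""Linear-Gaussian local models and BIC scoring.

Each node X is modelled as normally distributed around a linear function of
its parents, X | u_1..u_k ~ N(a0 + Σ a_i u_i, σ²). The fit is ordinary least
squares; the node score is BIC = n·ln(RSS/n) + k·ln(n) with k = number of
regression coefficients (intercept included, σ excluded — this bookkeeping
makes Δk = 1 for an arc addition and Δk = 0 for a reversal). Lower is
better. The network score is the sum of node scores (decomposability), so a
candidate move is scored by refitting only the locals it touches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_model import ExpressionMatrix, NetworkError

logger = logging.getLogger("tbnlearn")

#: relative floor applied to an exactly-zero RSS (BIC undefined at RSS = 0)
RSS_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class LocalModel:
    """OLS fit of one node on its parents, with its node-level BIC."""

    node: str
    parents: tuple[str, ...]
    a0: float
    coeffs: tuple[float, ...]
    sigma: float
    rss: float
    tss: float
    k: int
    bic: float


@dataclass
class GaussianBN:
    """A DAG plus one fitted linear-Gaussian local model per node."""

    structure: nx.DiGraph
    locals: dict[str, LocalModel]
    n: int

    def bic_global(self) -> float:
        return bic_global(self)


def _floored_rss(rss: float, tss: float) -> float:
    if rss > 0:
        return rss
    floor = max(RSS_FLOOR_REL * tss, np.finfo(float).tiny)
    logger.warning("RSS is 0 (exact fit); clamped to %.3g", floor)
    return floor


def fit_local(node: str, parents, expr: ExpressionMatrix) -> LocalModel:
    """Least-squares fit of *node*'s profile on its parents' profiles.

    Rank-deficient designs (collinear parents) fall back to the minimum-norm
    solution with a warning. Requires n > |parents| + 1.
    """
    parents = tuple(parents)
    y = expr.row(node)
    n = expr.n_samples
    k = len(parents) + 1
    if n <= k:
        raise NetworkError(
            f"insufficient samples for node {node}: n={n} <= k={k}"
        )
    X = np.empty((n, k))
    X[:, 0] = 1.0
    if parents:
        X[:, 1:] = expr.rows(parents).T
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        logger.warning(
            "rank-deficient design for node %s (rank %d < k %d); "
            "minimum-norm solution used", node, rank, k,
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    sigma = math.sqrt(rss / n)
    bic = n * math.log(_floored_rss(rss, tss) / n) + k * math.log(n)
    return LocalModel(
        node=node,
        parents=parents,
        a0=float(beta[0]),
        coeffs=tuple(float(b) for b in beta[1:]),
        sigma=sigma,
        rss=rss,
        tss=tss,
        k=k,
        bic=bic,
    )


def bic_node(local: LocalModel, n: int) -> float:
    """Node-level BIC: n·ln(RSS/n) + k·ln(n); lower is better."""
    return n * math.log(_floored_rss(local.rss, local.tss) / n) + local.k * math.log(n)


def delta_bic(rss_old: float, rss_new: float, n: int, delta_k: int) -> float:
    """Score improvement BIC_old − BIC_new = n·ln(RSS_old/RSS_new) − Δk·ln(n).

    Positive ⇒ the move improves the model. Δk is 1 for an arc addition and
    0 for a reversal.
    """
    if rss_old <= 0 or rss_new <= 0:
        raise NetworkError("delta_bic requires strictly positive RSS values")
    return n * math.log(rss_old / rss_new) - delta_k * math.log(n)


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scored copy of an expression matrix."""
    sd = expr.values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        flat = [n for n, s in zip(expr.node_ids, sd.ravel()) if s == 0]
        raise NetworkError(f"zero-variance profile(s): {flat[:5]}")
    values = (expr.values - expr.values.mean(axis=1, keepdims=True)) / sd
    return ExpressionMatrix(expr.node_ids, expr.sample_ids, values)


def fit_bn(
    structure: nx.DiGraph, expr: ExpressionMatrix, standardize_expr: bool = False
) -> GaussianBN:
    """Fit every local model of an acyclic structure against the data.

    With ``standardize_expr`` the matrix is z-scored per gene first; the
    default uses expression as-is.
    """
    if not nx.is_directed_acyclic_graph(structure):
        raise NetworkError("structure must be acyclic")
    if standardize_expr:
        expr = standardize(expr)
    locals_ = {
        node: fit_local(node, sorted(structure.predecessors(node)), expr)
        for node in sorted(structure.nodes)
    }
    return GaussianBN(structure=structure, locals=locals_, n=expr.n_samples)


def bic_global(bn: GaussianBN) -> float:
    """Network score: sum of all node BICs (fixed summation order)."""
    missing = [n for n in bn.structure.nodes if n not in bn.locals]
    if missing:
        raise NetworkError(f"unfitted local model(s): {missing[:5]}")
    return float(sum(bn.locals[n].bic for n in sorted(bn.locals)))
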