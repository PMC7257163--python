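"""Hybrid structure learning over the whitelist search space.

One search run iterates: draw a set of `w` whitelist arcs (sampling
probability ∝ |Pearson r| of the TF pair, without replacement), score every
candidate against the *current* model — an arc not yet present and creating
no cycle is an *addition* (Δk = 1, refit the child's local model); an arc
whose reverse is present is a *reversal* (Δk = 0, both endpoint locals
refit) — then greedily accept the single best move if its ΔBIC exceeds the
stop threshold τ = 10 / |BIC_global(initial TBN)|. When no move clears τ the
search tries to escape the local optimum for up to `escape_attempts`
consecutive rounds with the sampling size multiplied by `escape_multiplier`;
a successful escape resumes normal search, otherwise the run stops. Accepted
arcs retire from the whitelist (a reversal also retires the displaced
orientation for good). An ensemble driver repeats the run under seeds
seed, seed+1, … for consensus building downstream.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from joblib import Parallel, delayed

from .bn_init import InitializedModel
from .gaussian_bn import GaussianBN, bic_global, fit_bn, fit_local
from .network_model import ExpressionMatrix, NetworkError, Whitelist, WhitelistArc

logger = logging.getLogger("tbnlearn")


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the hybrid search.

    ``w`` is the number of whitelist arcs sampled per iteration; the stop
    threshold is fixed by rule to 10 / |BIC_global| of the initial TBN
    (override with ``threshold`` for experiments); ``max_iterations``
    defaults to 10·|whitelist| as a termination safety cap.
    """

    w: int = 100
    escape_attempts: int = 10
    escape_multiplier: float = 2.0
    n_runs: int = 100
    seed: int = 0
    max_iterations: int | None = None
    threshold: float | None = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.w < 1:
            raise NetworkError("w must be >= 1")
        if self.escape_attempts < 0:
            raise NetworkError("escape_attempts must be >= 0")
        if self.escape_multiplier < 1:
            raise NetworkError("escape_multiplier must be >= 1")
        if self.n_runs < 1:
            raise NetworkError("n_runs must be >= 1")
        if self.threshold is not None and self.threshold <= 0:
            raise NetworkError("threshold must be positive")


@dataclass(frozen=True)
class Move:
    source: str
    target: str
    move_type: str  # "add" | "reverse"
    delta_bic: float
    iteration: int


@dataclass(frozen=True)
class LearnedModel:
    """One run's final structure with its global score and move trace."""

    arcs: tuple[tuple[str, str], ...]
    tf_ids: frozenset[str]
    bic_global: float
    moves: tuple[Move, ...]
    seed: int

    def structure(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.arcs)
        return g

    def tf_tf_arcs(self) -> set[tuple[str, str]]:
        return {
            (s, t) for s, t in self.arcs if s in self.tf_ids and t in self.tf_ids
        }


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _weighted_draw_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> list[int]:
    """Sequential weighted draws; probabilities renormalize after each pick."""
    p = np.asarray(weights, dtype=float).copy()
    out: list[int] = []
    for _ in range(size):
        total = p.sum()
        if total <= 0:
            break
        cum = np.cumsum(p)
        i = int(np.searchsorted(cum, rng.random() * total, side="right"))
        i = min(i, len(p) - 1)
        out.append(i)
        p[i] = 0.0
    return out


def sample_arcs(
    whitelist: Whitelist, size: int, rng: np.random.Generator
) -> list[WhitelistArc]:
    """Draw min(size, |whitelist|) arcs, probability ∝ sampling_prob."""
    if not whitelist.arcs:
        return []
    probs = np.array([a.sampling_prob for a in whitelist.arcs], dtype=float)
    if np.any(np.isnan(probs)):
        raise NetworkError("whitelist sampling probabilities not set")
    idx = _weighted_draw_without_replacement(probs, min(size, len(probs)), rng)
    return [whitelist.arcs[i] for i in idx]


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateEvaluation:
    move_type: str  # "add" | "reverse"
    delta_bic: float
    new_locals: dict


def evaluate_candidate(
    bn: GaussianBN,
    arc: tuple[str, str],
    expr: ExpressionMatrix,
    tf_graph: nx.DiGraph | None = None,
) -> CandidateEvaluation | None:
    """Score one whitelist arc against the current model; None if rejected.

    Rejection cases: the arc is already present, or the candidate structure
    would contain a directed cycle. Evaluations are independent of one
    another (each is scored against the current model), so a batch may be
    evaluated in any order — or concurrently — with identical results.
    """
    u, v = arc
    g = tf_graph if tf_graph is not None else bn.structure
    for endpoint in (u, v):
        if endpoint not in expr:
            raise NetworkError(f"no expression profile for {endpoint}")
    if bn.structure.has_edge(u, v):
        return None  # already present
    if bn.structure.has_edge(v, u):
        # reversal: v->u becomes u->v; cycle iff a v..u path survives elsewhere
        g.remove_edge(v, u)
        try:
            cyclic = nx.has_path(g, v, u)
        finally:
            g.add_edge(v, u)
        if cyclic:
            return None
        old_u, old_v = bn.locals[u], bn.locals[v]
        new_u = fit_local(u, tuple(p for p in old_u.parents if p != v), expr)
        new_v = fit_local(v, old_v.parents + (u,), expr)
        delta = (old_u.bic + old_v.bic) - (new_u.bic + new_v.bic)
        return CandidateEvaluation("reverse", delta, {u: new_u, v: new_v})
    # addition: cycle iff u is reachable from v
    if nx.has_path(g, v, u):
        return None
    old_v = bn.locals[v]
    new_v = fit_local(v, old_v.parents + (u,), expr)
    delta = old_v.bic - new_v.bic
    return CandidateEvaluation("add", delta, {v: new_v})


# ---------------------------------------------------------------------------
# Search loop
# ---------------------------------------------------------------------------


def learn_structure(
    init: InitializedModel,
    expr: ExpressionMatrix,
    config: SearchConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LearnedModel:
    """One full hybrid-search run; deterministic given (init, expr, config, seed)."""
    run_seed = config.seed if seed is None else seed
    if rng is None:
        rng = np.random.default_rng(run_seed)

    tbn = init.tbn
    structure = tbn.to_digraph()
    tf_ids = frozenset(tbn.tf_ids)
    tf_graph = nx.DiGraph()
    tf_graph.add_nodes_from(tf_ids)
    tf_graph.add_edges_from(
        (s, t) for s, t, _ in tbn.edges if s in tf_ids and t in tf_ids
    )

    bn = fit_bn(structure, expr)
    bic = bic_global(bn)
    tau = config.threshold if config.threshold is not None else 10.0 / abs(bic)
    if not np.isfinite(bic):
        raise NetworkError(f"non-finite initial score {bic!r}")

    active = list(init.whitelist.arcs)
    if any(a.sampling_prob is None for a in active):
        raise NetworkError("whitelist sampling probabilities not set")
    weights = np.array([a.sampling_prob for a in active], dtype=float)

    max_iter = (
        config.max_iterations
        if config.max_iterations is not None
        else 10 * max(len(active), 1)
    )
    moves: list[Move] = []
    escape = 0
    iteration = 0

    while active and iteration < max_iter:
        iteration += 1
        size = config.w if escape == 0 else int(round(config.w * config.escape_multiplier))
        idx = _weighted_draw_without_replacement(weights, min(size, len(active)), rng)
        best: tuple[float, float, tuple[str, str], int, CandidateEvaluation] | None = None
        for i in idx:
            a = active[i]
            ev = evaluate_candidate(bn, (a.source, a.target), expr, tf_graph)
            if ev is None:
                continue
            # order: max ΔBIC, then higher sampling_prob, then lexicographic
            key = (ev.delta_bic, a.sampling_prob, (a.source, a.target))
            if best is None or (
                key[0] > best[0]
                or (key[0] == best[0] and key[1] > best[1])
                or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
            ):
                best = (key[0], key[1], key[2], i, ev)
        if best is not None and best[0] > tau:
            delta, _, (u, v), i, ev = best
            if ev.move_type == "reverse":
                structure.remove_edge(v, u)
                tf_graph.remove_edge(v, u)
            structure.add_edge(u, v)
            tf_graph.add_edge(u, v)
            bn.locals.update(ev.new_locals)
            bic -= delta
            if not np.isfinite(bic):
                raise NetworkError(
                    f"non-finite score after move {u}->{v} at iteration {iteration}: "
                    f"delta={delta!r}"
                )
            assert nx.is_directed_acyclic_graph(tf_graph), (
                f"cycle introduced by {ev.move_type} {u}->{v}"
            )
            moves.append(Move(u, v, ev.move_type, delta, iteration))
            del active[i]
            weights = np.delete(weights, i)
            if escape:
                logger.debug("run %d: escape succeeded at iteration %d", run_seed, iteration)
            escape = 0
        else:
            escape += 1
            if escape > config.escape_attempts:
                break

    return LearnedModel(
        arcs=tuple(sorted(structure.edges())),
        tf_ids=tf_ids,
        bic_global=bic,
        moves=tuple(moves),
        seed=run_seed,
    )


def run_ensemble(
    init: InitializedModel, expr: ExpressionMatrix, config: SearchConfig
) -> list[LearnedModel]:
    """Run `n_runs` independent searches under seeds seed, seed+1, …

    Runs are embarrassingly parallel (each owns its seed); output order is
    seed order regardless of worker scheduling.
    """

    def one(i: int) -> LearnedModel:
        t0 = time.perf_counter()
        model = learn_structure(init, expr, config, seed=config.seed + i)
        logger.info(
            "run seed=%d: %d moves, bic=%.6g, %.2fs",
            config.seed + i, len(model.moves), model.bic_global,
            time.perf_counter() - t0,
        )
        return model

    if config.n_jobs == 1:
        return [one(i) for i in range(config.n_runs)]
    return Parallel(n_jobs=config.n_jobs)(
        delayed(one)(i) for i in range(config.n_runs)
    )
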