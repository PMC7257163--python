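"""Ground-truth networks and linear-Gaussian expression for testing.

Emulates the statistical structure the learner assumes: a loop-rich prior
TRN whose TF-TF part contains an acyclic *generative core* (a weakly
connected random DAG) plus cycle-closing decoy arcs, positive binding
weights that are stochastically higher on core arcs, and expression sampled
from the linear structural-equation model x_v = a0 + Σ a_i·x_parent_i + ε on
the core only — the loop arcs are observational decoys with no generative
effect, mirroring how a real ChIP-Seq prior carries feedback loops while
the fitted model is a DAG. Also builds the yeast-style false-prior
robustness fixture (gold network, corrupted prior, expression, injected-arc
list) as a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_model import ExpressionMatrix, NetworkError, RegulatoryNetwork
from .topology_eval import inject_false_arcs


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic regulatory network + expression fixture."""

    n_tf: int
    n_gene: int
    tf_tf_arcs: int
    tf_gene_arcs: int
    loop_fraction: float = 0.25
    coeff_range: tuple[float, float] = (0.5, 1.5)
    sign_prob: float = 0.5
    noise_sigma: float = 1.0
    n_samples: int = 100
    seed: int = 0
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.n_tf < 2:
            raise NetworkError("need at least 2 TFs")
        if not 0 <= self.loop_fraction <= 1:
            raise NetworkError("loop_fraction must be in [0, 1]")
        n_core = self.tf_tf_arcs - round(self.loop_fraction * self.tf_tf_arcs)
        if n_core < self.n_tf - 1:
            raise NetworkError(
                f"core arc count {n_core} cannot weakly connect {self.n_tf} TFs"
            )
        if n_core > self.n_tf * (self.n_tf - 1) // 2:
            raise NetworkError("more core arcs than ordered pairs allow in a DAG")
        if self.n_samples < 3:
            raise NetworkError("n_samples >= 3 required")
        lo, hi = self.coeff_range
        if not (0 < lo <= hi):
            raise NetworkError("coeff_range must be positive")
        if self.n_gene and self.tf_gene_arcs > self.n_tf * self.n_gene:
            raise NetworkError("too many TF-gene arcs for the node counts")


def _tf_names(n: int) -> list[str]:
    return [f"TF{i+1:03d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i+1:04d}" for i in range(n)]


def simulate_trn(spec: SyntheticSpec) -> tuple[RegulatoryNetwork, nx.DiGraph]:
    """Loop-rich TRN plus its hidden acyclic generative core.

    The core is a random weakly-connected DAG on the TFs (spanning tree +
    random forward arcs in a random topological order) with all TF→gene
    arcs. Cycle-closing decoys are arcs against the topological order whose
    reverse direction is reachable in the core — so each closes a directed
    cycle; when ≥ 2 decoys are requested, at least one 2-cycle (a reversed
    core arc) and one longer cycle are forced in.
    """
    rng = np.random.default_rng(spec.seed)
    tfs = _tf_names(spec.n_tf)
    genes = _gene_names(spec.n_gene)
    n_loop = round(spec.loop_fraction * spec.tf_tf_arcs)
    n_core = spec.tf_tf_arcs - n_loop

    order = [tfs[i] for i in rng.permutation(spec.n_tf)]
    pos = {tf: i for i, tf in enumerate(order)}
    core: set[tuple[str, str]] = set()
    for i in range(1, spec.n_tf):
        j = int(rng.integers(0, i))
        core.add((order[j], order[i]))
    forward = [
        (order[j], order[i])
        for i in range(spec.n_tf)
        for j in range(i)
        if (order[j], order[i]) not in core
    ]
    extra = n_core - (spec.n_tf - 1)
    if extra:
        idx = rng.choice(len(forward), size=extra, replace=False)
        core |= {forward[i] for i in sorted(idx)}

    core_graph = nx.DiGraph()
    core_graph.add_nodes_from(tfs)
    core_graph.add_edges_from(sorted(core))

    loops: list[tuple[str, str]] = []
    if n_loop:
        reach = {v: nx.descendants(core_graph, v) for v in tfs}
        two_cycle = sorted((t, s) for s, t in core)
        longer = sorted(
            (u, v)
            for v in tfs
            for u in reach[v]
            if (u, v) not in core and (v, u) not in core
        )
        chosen: list[tuple[str, str]] = []
        if n_loop >= 2 and two_cycle and longer:
            chosen.append(two_cycle[int(rng.integers(len(two_cycle)))])
            chosen.append(longer[int(rng.integers(len(longer)))])
        pool = [a for a in sorted(set(two_cycle) | set(longer)) if a not in chosen]
        remaining = n_loop - len(chosen)
        if remaining > len(pool):
            raise NetworkError(
                f"cannot place {n_loop} cycle-closing arcs: only "
                f"{len(pool) + len(chosen)} candidates"
            )
        if remaining:
            idx = rng.choice(len(pool), size=remaining, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        loops = chosen

    # TF -> gene arcs: every gene gets one parent first (when budget allows)
    tf_gene: list[tuple[str, str]] = []
    if spec.n_gene and spec.tf_gene_arcs:
        taken: set[tuple[str, str]] = set()
        budget = spec.tf_gene_arcs
        if budget >= spec.n_gene:
            for g in genes:
                parent = tfs[int(rng.integers(spec.n_tf))]
                taken.add((parent, g))
            budget -= spec.n_gene
        pool2 = [
            (tf, g) for tf in tfs for g in genes if (tf, g) not in taken
        ]
        if budget:
            idx = rng.choice(len(pool2), size=budget, replace=False)
            taken |= {pool2[i] for i in sorted(idx)}
        tf_gene = sorted(taken)

    def weight_core() -> float | None:
        return float(rng.uniform(1.0, 2.0)) if spec.weighted else None

    def weight_loop() -> float | None:
        return float(rng.uniform(0.1, 1.1)) if spec.weighted else None

    def weight_gene() -> float | None:
        return float(rng.uniform(0.1, 2.0)) if spec.weighted else None

    edges = (
        [(s, t, weight_core()) for s, t in sorted(core)]
        + [(s, t, weight_loop()) for s, t in loops]
        + [(s, t, weight_gene()) for s, t in tf_gene]
    )
    net = RegulatoryNetwork(frozenset(tfs), frozenset(genes), tuple(edges))

    generative = nx.DiGraph()
    generative.add_nodes_from(tfs)
    generative.add_nodes_from(genes)
    generative.add_edges_from(sorted(core))
    generative.add_edges_from(tf_gene)
    return net, generative


def simulate_expression(
    generative_dag: nx.DiGraph, spec: SyntheticSpec
) -> tuple[ExpressionMatrix, dict]:
    """Sample expression from the linear-Gaussian model along the core DAG.

    Nodes are generated in topological order as x_v = a0 + Σ a_i·x_parent_i
    + ε with ε ~ N(0, noise_sigma²) i.i.d. across samples; coefficient
    magnitudes are uniform in coeff_range with sign positive with
    probability sign_prob, intercepts uniform in (−1, 1). Returns the matrix
    and the true parameters {node: {"a0": …, "coeffs": {parent: a}}}.
    """
    if not nx.is_directed_acyclic_graph(generative_dag):
        raise NetworkError("generative graph must be acyclic")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    lo, hi = spec.coeff_range
    nodes = sorted(generative_dag.nodes)
    values: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}
    for v in nx.lexicographical_topological_sort(generative_dag):
        parents = sorted(generative_dag.predecessors(v))
        a0 = float(rng.uniform(-1.0, 1.0))
        coeffs = {}
        x = np.full(spec.n_samples, a0)
        for p in parents:
            a = float(rng.uniform(lo, hi))
            if rng.random() >= spec.sign_prob:
                a = -a
            coeffs[p] = a
            x = x + a * values[p]
        x = x + rng.normal(0.0, spec.noise_sigma, size=spec.n_samples)
        values[v] = x
        params[v] = {"a0": a0, "coeffs": coeffs}
    mat = np.vstack([values[n] for n in nodes])
    samples = tuple(f"S{i+1:03d}" for i in range(spec.n_samples))
    return ExpressionMatrix(tuple(nodes), samples, mat), params


def make_robustness_fixture(
    spec: SyntheticSpec,
    fp_fraction: float,
    rng: np.random.Generator | None = None,
) -> tuple[RegulatoryNetwork, RegulatoryNetwork, ExpressionMatrix, list]:
    """Gold network, FP-corrupted prior, expression, and the injected arcs.

    Mirrors the yeast-style robustness experiment: the gold prior (loops
    included) is corrupted with `fp_fraction` random false TF-TF arcs;
    expression comes from the hidden generative core only.
    """
    if not 0 <= fp_fraction <= 1:
        raise NetworkError("fp_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    gold, core = simulate_trn(spec)
    expr, _ = simulate_expression(core, spec)
    corrupted, injected = inject_false_arcs(gold, fp_fraction, rng)
    return gold, corrupted, expr, injected
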