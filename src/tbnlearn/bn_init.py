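"""Convert a loopy TRN into a Bayesian starting point.

Pipeline: split the TRN into its TF-TF and TF→gene components; break the
regulatory loops of the TF-TF component by greedily removing low-weight arcs
while weak connectivity holds, until a minimal connected DAG (a spanning-tree
skeleton, n−1 arcs per component) remains; the removed arcs become the
*whitelist*, the search space of the learner. The skeleton is rejoined with
the TF→gene component (the TBN), intersected with the expression compendium
so the model is fully observable, and each whitelist arc is assigned a
sampling probability proportional to |Pearson r| of its TF pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .network_model import (
    ExpressionMatrix,
    NetworkError,
    RegulatoryNetwork,
    Whitelist,
    WhitelistArc,
)

logger = logging.getLogger("tbnlearn")

#: arcs with |r| below this get a probability floor before normalization
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class InitializedModel:
    """Loop-broken starting point: spanning DAG + fixed TF→gene arcs + whitelist."""

    dag: RegulatoryNetwork
    whitelist: Whitelist
    tf_gene: RegulatoryNetwork | None = None
    provenance: dict = None  # removal order, seed, mode

    @property
    def tbn(self) -> RegulatoryNetwork:
        if self.tf_gene is None:
            return self.dag
        return assemble_tbn(self.dag, self.tf_gene)


def decompose(trn: RegulatoryNetwork) -> tuple[RegulatoryNetwork, RegulatoryNetwork]:
    """Split a TRN into its TF-TF component and its TF→gene component."""
    tf_tf = tuple(e for e in trn.edges if e[1] in trn.tf_ids)
    tf_gene = tuple(e for e in trn.edges if e[1] in trn.gene_ids)
    if not tf_tf:
        raise NetworkError("degenerate TF-TF component: no TF-TF arcs")
    tf_part = RegulatoryNetwork(trn.tf_ids, frozenset(), tf_tf)
    gene_part = RegulatoryNetwork(trn.tf_ids, trn.gene_ids, tf_gene)
    return tf_part, gene_part


def break_loops(tf_tf: RegulatoryNetwork, seed: int = 0) -> InitializedModel:
    """Greedy loop-breaking of the TF-TF component into a minimal connected DAG.

    Arcs are visited in increasing binding weight (ties in stable input
    order); in unweighted mode they are shuffled with *seed* and treated as
    equal weight. Each visited arc is removed if the component stays weakly
    connected, otherwise restored and skipped. Per weakly-connected component
    of n nodes the surviving skeleton has exactly n−1 arcs; being an
    orientation of a tree it is acyclic for free. Removed arcs form the
    whitelist, keeping their original weights.
    """
    edges = list(tf_tf.edges)
    if not edges:
        raise NetworkError("empty TF-TF component")
    weighted = tf_tf.weighted
    if any((w is None) == weighted for _, _, w in edges):
        raise NetworkError("mixture of weighted and unweighted arcs")

    rng = np.random.default_rng(seed)
    if weighted:
        order = list(np.argsort([w for _, _, w in edges], kind="stable"))
    else:
        order = list(rng.permutation(len(edges)))

    # undirected multiplicity view for connectivity bookkeeping
    und = nx.Graph()
    und.add_nodes_from(n for e in edges for n in e[:2])
    for s, t, _ in edges:
        key = frozenset((s, t))
        if und.has_edge(s, t):
            und[s][t]["count"] += 1
        else:
            und.add_edge(s, t, count=1)

    for tf in tf_tf.tf_ids:
        if tf not in und:
            logger.warning("isolated TF %s contributes no DAG arcs", tf)
            und.add_node(tf)

    comp_of: dict[str, int] = {}
    comp_size: list[int] = []
    comp_arcs: list[int] = []
    for ci, comp in enumerate(nx.connected_components(und)):
        for node in comp:
            comp_of[node] = ci
        comp_size.append(len(comp))
        comp_arcs.append(0)
    for s, t, _ in edges:
        comp_arcs[comp_of[s]] += 1

    removed: list[int] = []
    for idx in order:
        s, t, _ = edges[idx]
        ci = comp_of[s]
        if comp_arcs[ci] <= comp_size[ci] - 1:
            continue  # component already at tree size
        if und[s][t]["count"] > 1:
            und[s][t]["count"] -= 1
            comp_arcs[ci] -= 1
            removed.append(idx)
            continue
        # last parallel copy: removable iff (s,t) is not an undirected bridge
        und.remove_edge(s, t)
        if nx.has_path(und, s, t):
            comp_arcs[ci] -= 1
            removed.append(idx)
        else:
            und.add_edge(s, t, count=1)

    removed_set = set(removed)
    dag_edges = tuple(edges[i] for i in range(len(edges)) if i not in removed_set)
    wl = Whitelist(
        tuple(WhitelistArc(edges[i][0], edges[i][1], edges[i][2]) for i in removed)
    )
    dag = RegulatoryNetwork(tf_tf.tf_ids, frozenset(), dag_edges)
    prov = {
        "seed": int(seed),
        "mode": "weighted" if weighted else "unweighted",
        "removal_order": [(edges[i][0], edges[i][1]) for i in removed],
    }
    return InitializedModel(dag=dag, whitelist=wl, provenance=prov)


def assemble_tbn(dag: RegulatoryNetwork, tf_gene: RegulatoryNetwork) -> RegulatoryNetwork:
    """Rejoin the loop-broken TF-TF DAG with the fixed TF→gene component."""
    collisions = dag.arc_set() & tf_gene.arc_set()
    if collisions:
        raise NetworkError(
            f"arc collision between DAG and TF-gene component: {sorted(collisions)[:5]}"
        )
    return RegulatoryNetwork(
        dag.tf_ids | tf_gene.tf_ids, tf_gene.gene_ids, dag.edges + tf_gene.edges
    )


def intersect_with_expression(
    tbn: RegulatoryNetwork, whitelist: Whitelist, expr: ExpressionMatrix
) -> tuple[RegulatoryNetwork, Whitelist]:
    """Restrict the TBN and whitelist to nodes with an expression profile.

    Nodes missing from *expr* are dropped with all incident arcs. If the
    surviving graph is weakly disconnected it is restricted to its largest
    weakly-connected component (logged).
    """
    keep = {n for n in tbn.nodes if n in expr}
    edges = tuple(e for e in tbn.edges if e[0] in keep and e[1] in keep)
    tfs = frozenset(t for t in tbn.tf_ids if t in keep)
    genes = frozenset(g for g in tbn.gene_ids if g in keep)
    # drop nodes that lost every arc
    touched = {n for e in edges for n in e[:2]}
    tfs = frozenset(t for t in tfs if t in touched)
    genes = frozenset(g for g in genes if g in touched)
    if len(tfs) < 2:
        raise NetworkError("insufficient observable network: fewer than 2 TFs")
    net = RegulatoryNetwork(tfs, genes, edges)

    g = net.to_digraph()
    if g.number_of_nodes() and not nx.is_weakly_connected(g):
        comps = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
        largest = comps[0]
        logger.info(
            "expression intersection disconnected the TBN; keeping largest "
            "component (%d of %d nodes)", len(largest), g.number_of_nodes(),
        )
        edges = tuple(e for e in edges if e[0] in largest and e[1] in largest)
        tfs = frozenset(t for t in tfs if t in largest)
        genes = frozenset(gn for gn in genes if gn in largest)
        if len(tfs) < 2:
            raise NetworkError("insufficient observable network: fewer than 2 TFs")
        net = RegulatoryNetwork(tfs, genes, edges)

    wl = Whitelist(
        tuple(a for a in whitelist if a.source in net.tf_ids and a.target in net.tf_ids)
    )
    return net, wl


def initialize(
    trn: RegulatoryNetwork, expr: ExpressionMatrix, seed: int = 0
) -> InitializedModel:
    """Full initialization pipeline: decompose → break loops → assemble →
    intersect with expression → correlation-based sampling probabilities."""
    tf_tf, tf_gene = decompose(trn)
    partial = break_loops(tf_tf, seed=seed)
    tbn = assemble_tbn(partial.dag, tf_gene)
    tbn2, wl = intersect_with_expression(tbn, partial.whitelist, expr)
    wl = compute_arc_probabilities(wl, expr)
    tf_edges = tuple(e for e in tbn2.edges if e[1] in tbn2.tf_ids)
    gene_edges = tuple(e for e in tbn2.edges if e[1] in tbn2.gene_ids)
    return InitializedModel(
        dag=RegulatoryNetwork(tbn2.tf_ids, frozenset(), tf_edges),
        whitelist=wl,
        tf_gene=RegulatoryNetwork(tbn2.tf_ids, tbn2.gene_ids, gene_edges),
        provenance=partial.provenance,
    )


def compute_arc_probabilities(
    whitelist: Whitelist, expr: ExpressionMatrix
) -> Whitelist:
    """Attach Pearson correlations and |r|-proportional sampling probabilities.

    The signed r is retained for reporting; the extraction probability is
    |r| / Σ|r| (a floor of 1e-12 keeps exactly-uncorrelated arcs drawable).
    """
    if not whitelist.arcs:
        return whitelist
    corrs = []
    for a in whitelist:
        for tf in (a.source, a.target):
            x = expr.row(tf)
            if np.ptp(x) == 0 or np.std(x) == 0:
                raise NetworkError(f"zero-variance expression profile for TF {tf}")
        x, y = expr.row(a.source), expr.row(a.target)
        r = float(np.corrcoef(x, y)[0, 1])
        corrs.append(r)
    mags = np.maximum(np.abs(corrs), PROB_FLOOR)
    probs = mags / mags.sum()
    # renormalize exactly to absorb float round-off
    probs = probs / probs.sum()
    arcs = tuple(
        replace(a, correlation=corrs[i], sampling_prob=float(probs[i]))
        for i, a in enumerate(whitelist.arcs)
    )
    return Whitelist(arcs)
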