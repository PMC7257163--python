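"""Topological statistics, hierarchy layers, overlap and robustness metrics.

The TF hierarchy uses the hierarchy height h = (out − in)/(out + in)
computed on the TF-TF subgraph: a TF regulating many other TFs while being
regulated by few sits near the top (h → 1, master regulator), the converse
near the bottom (h → −1, workhorse), with middle managers between the
cutoffs. The robustness harness injects random false TF-TF arcs into a gold
prior and reports consensus size, %FP and precision = TP/(TP+FP),
direction-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork
from .network_model import NetworkError, RegulatoryNetwork

logger = logging.getLogger("tbnlearn")

DEFAULT_CUTOFFS = (-1.0 / 3.0, 1.0 / 3.0)


def _tf_tf_arcs(net: RegulatoryNetwork) -> list[tuple[str, str]]:
    return [(s, t) for s, t, _ in net.edges if t in net.tf_ids]


# ---------------------------------------------------------------------------
# Degrees and hierarchy
# ---------------------------------------------------------------------------


def degree_stats(net: RegulatoryNetwork) -> tuple[pd.DataFrame, dict]:
    """Per-TF in/out degrees on the TF-TF subgraph, plus connectivity summaries.

    Two conventions of "average connectivity" are reported: the mean total
    degree (in + out) per node, and arcs per node (E/n).
    """
    if not net.edges:
        raise NetworkError("empty network")
    arcs = _tf_tf_arcs(net)
    tfs = sorted({n for a in arcs for n in a} | set())
    out_deg = {t: 0 for t in tfs}
    in_deg = {t: 0 for t in tfs}
    for s, t in arcs:
        out_deg[s] += 1
        in_deg[t] += 1
    table = pd.DataFrame(
        {
            "node": tfs,
            "out_degree": [out_deg[t] for t in tfs],
            "in_degree": [in_deg[t] for t in tfs],
        }
    )
    n = max(len(tfs), 1)
    summary = {
        "mean_total_degree": float((table["out_degree"] + table["in_degree"]).mean())
        if len(table)
        else 0.0,
        "arcs_per_node": len(arcs) / n,
        "n_tf_tf_arcs": len(arcs),
        "n_tfs": len(tfs),
    }
    return table, summary


def hierarchy_layers(
    net: RegulatoryNetwork, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """Assign each TF a hierarchy height and layer on the TF-TF subgraph.

    h = (out − in)/(out + in); layer = master_regulator if h > high cutoff,
    workhorse if h < low cutoff, middle_manager otherwise. Isolated TFs get
    h = 0, middle_manager, and an `isolated` flag.
    """
    low, high = cutoffs
    arcs = _tf_tf_arcs(net)
    if not arcs:
        raise NetworkError("TF-TF subgraph is empty")
    tfs = sorted(net.tf_ids)
    out_deg = {t: 0 for t in tfs}
    in_deg = {t: 0 for t in tfs}
    for s, t in arcs:
        out_deg[s] += 1
        in_deg[t] += 1
    rows = []
    for tf in tfs:
        o, i = out_deg[tf], in_deg[tf]
        isolated = (o + i) == 0
        h = 0.0 if isolated else (o - i) / (o + i)
        if isolated:
            layer = "middle_manager"
        elif h > high:
            layer = "master_regulator"
        elif h < low:
            layer = "workhorse"
        else:
            layer = "middle_manager"
        rows.append(
            {
                "node": tf,
                "out_degree": o,
                "in_degree": i,
                "h": h,
                "layer": layer,
                "isolated": isolated,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------


def edge_overlap(
    net_a: RegulatoryNetwork,
    net_b: RegulatoryNetwork,
    restrict_to_common_regulators: bool = True,
) -> dict:
    """Shared / exclusive arc counts between two networks.

    With the restriction flag, only arcs whose source is a TF present in
    both networks are compared (the regulator-centred comparison). The
    shared fraction is relative to network A (the reference).
    """
    if not (net_a.nodes & net_b.nodes):
        raise NetworkError("networks have disjoint node universes")
    arcs_a = net_a.arc_set()
    arcs_b = net_b.arc_set()
    if restrict_to_common_regulators:
        common = net_a.tf_ids & net_b.tf_ids
        arcs_a = {a for a in arcs_a if a[0] in common}
        arcs_b = {a for a in arcs_b if a[0] in common}
    shared = arcs_a & arcs_b
    return {
        "shared": len(shared),
        "a_only": len(arcs_a - arcs_b),
        "b_only": len(arcs_b - arcs_a),
        "shared_fraction": len(shared) / len(arcs_a) if arcs_a else 0.0,
    }


# ---------------------------------------------------------------------------
# False-prior robustness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RobustnessReport:
    """One Table-style row of the false-prior robustness evaluation."""

    fp_fraction: float
    consensus_size: int
    fp_count: int
    pct_fp: float
    precision: float
    tp_count: int
    reversed_count: int  # selected arcs whose reverse (not itself) is in gold

    def as_row(self) -> dict:
        return {
            "fp_rate": f"{self.fp_fraction:.0%}",
            "consensus_size": self.consensus_size,
            "pct_fp": f"{self.pct_fp:.0f}%",
            "precision": round(self.precision, 2),
        }


def inject_false_arcs(
    net: RegulatoryNetwork, fraction: float, rng: np.random.Generator
) -> tuple[RegulatoryNetwork, list[tuple[str, str]]]:
    """Add round(fraction·|TF-TF arcs|) random absent TF→TF arcs to a gold prior.

    Injected arcs are drawn uniformly among ordered TF pairs not already in
    the network (no self-loops, no duplicates); the injected list is
    returned for downstream FP accounting. On a weighted network the fakes
    receive weights uniform between the gold min and max (the all-or-none
    weight invariant requires one).
    """
    if fraction < 0:
        raise NetworkError("fraction must be >= 0")
    tf_arcs = _tf_tf_arcs(net)
    n_inject = round(fraction * len(tf_arcs))
    if n_inject == 0:
        return net, []
    tfs = sorted(net.tf_ids)
    present = net.arc_set()
    absent = [
        (u, v)
        for u in tfs
        for v in tfs
        if u != v and (u, v) not in present
    ]
    if len(absent) < n_inject:
        raise NetworkError(
            f"cannot inject {n_inject} arcs: only {len(absent)} absent TF pairs"
        )
    idx = rng.choice(len(absent), size=n_inject, replace=False)
    injected = [absent[i] for i in sorted(idx)]
    if net.weighted:
        ws = [w for _, _, w in net.edges]
        lo, hi = min(ws), max(ws)
        new_edges = tuple((u, v, float(rng.uniform(lo, hi))) for u, v in injected)
    else:
        new_edges = tuple((u, v, None) for u, v in injected)
    corrupted = RegulatoryNetwork(net.tf_ids, net.gene_ids, net.edges + new_edges)
    return corrupted, injected


def precision_report(
    consensus: ConsensusNetwork,
    gold_arcs: set[tuple[str, str]],
    injected_arcs: list[tuple[str, str]] | None = None,
    fp_fraction: float = 0.0,
) -> RobustnessReport:
    """TP/FP/precision of the selected consensus arcs against a gold standard.

    Matching is direction-sensitive: a reversed gold arc counts as FP (it is
    additionally tallied in `reversed_count` for diagnostics).
    """
    cand = consensus.candidates
    if len(cand) == 0 or not bool(np.asarray(cand["selected"], dtype=bool).any()):
        raise NetworkError("empty consensus: no selected arcs")
    selected = consensus.selected_arcs()
    gold = set(gold_arcs)
    tp = selected & gold
    fp = selected - gold
    reversed_ = {(s, t) for s, t in fp if (t, s) in gold}
    return RobustnessReport(
        fp_fraction=fp_fraction,
        consensus_size=len(selected),
        fp_count=len(fp),
        pct_fp=100.0 * len(fp) / len(selected),
        precision=len(tp) / (len(tp) + len(fp)),
        tp_count=len(tp),
        reversed_count=len(reversed_),
    )
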