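"""Consensus transcriptional BN from an ensemble of learned models.

Every *learned* TF-TF arc — an arc accepted as a search move and still
present in a run's final structure — becomes a candidate, weighted by the
accumulated strength of the models containing it: w_ij = Σ_m S(m). Because
raw BIC_global values carry a data-scale-dependent sign, the default
per-model strength is the shifted positive score
S(m) = worst_bic − bic(m) + δ (δ = |worst_bic|·1e-6 + 1), so presence in
more models and in better-scoring models both strictly increase the weight;
a literal raw-sum mode (`mode="raw"`) is also provided. The confidence
threshold keeps the strong tail of the weight distribution: `percentile=5`
keeps the candidates at or above the 95th weight percentile (the strict
~5% core; pass `tail="bottom"` to instead drop the weakest p% and keep the
rest). Selection is then repaired: one direction per TF pair, cycles broken
at their weakest arc, and weak connectivity of the selected-plus-fixed
graph verified. An inclusive candidate mode (`include="structure"`, every
TF-TF arc of every final structure, initial-DAG skeleton included) is
available for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import NetworkError
from .structure_search import LearnedModel

logger = logging.getLogger("tbnlearn")


@dataclass
class ConsensusNetwork:
    """TF-TF consensus: candidate table with selection flags + fixed arcs."""

    candidates: pd.DataFrame  # columns: source, target, frequency, weight, selected
    fixed_tf_gene_arcs: tuple[tuple[str, str], ...]
    percentile: float
    n_models: int

    @property
    def selected(self) -> pd.DataFrame:
        return self.candidates[self.candidates["selected"]]

    def selected_arcs(self) -> set[tuple[str, str]]:
        return set(
            zip(self.selected["source"], self.selected["target"], strict=True)
        )

    @property
    def edges(self):
        """Selected TF-TF arcs as (source, target, weight) for the writers."""
        return [
            (r.source, r.target, float(r.weight))
            for r in self.selected.itertuples()
        ]


def _model_strengths(models: Sequence[LearnedModel], mode: str) -> list[float]:
    scores = [m.bic_global for m in models]
    if mode == "raw":
        return scores
    if mode != "shifted":
        raise NetworkError(f"unknown strength mode {mode!r}")
    worst = max(scores)  # lower BIC is better
    delta = abs(worst) * 1e-6 + 1.0
    return [worst - s + delta for s in scores]


def edge_strengths(
    models: Sequence[LearnedModel],
    mode: str = "shifted",
    include: str = "learned",
) -> pd.DataFrame:
    """Candidate table of TF-TF arcs across the ensemble.

    ``include="learned"`` (default) counts an arc in a model only when the
    model *learned* it — accepted it as an add/reverse move that survived to
    the final structure. ``include="structure"`` counts every TF-TF arc of
    every final structure, initial-DAG skeleton included.
    """
    if not models:
        raise NetworkError("empty ensemble")
    if include not in ("learned", "structure"):
        raise NetworkError(f"unknown candidate mode {include!r}")
    strengths = _model_strengths(models, mode)
    freq: dict[tuple[str, str], int] = {}
    weight: dict[tuple[str, str], float] = {}
    for m, s in zip(models, strengths, strict=True):
        if include == "learned":
            final = set(m.arcs)
            arcs = {
                (mv.source, mv.target) for mv in m.moves
            } & final
        else:
            arcs = m.tf_tf_arcs()
        for arc in sorted(arcs):
            freq[arc] = freq.get(arc, 0) + 1
            weight[arc] = weight.get(arc, 0.0) + s
    order = sorted(freq)
    return pd.DataFrame(
        {
            "source": [a[0] for a in order],
            "target": [a[1] for a in order],
            "frequency": [freq[a] for a in order],
            "weight": [weight[a] for a in order],
        }
    )


def select_by_percentile(
    candidates: pd.DataFrame, percentile: float, tail: str = "top"
) -> pd.DataFrame:
    """Flag candidates passing the weight-percentile confidence threshold.

    ``tail="top"``: keep the strong tail — candidates with weight ≥ the
    (100 − percentile)-th percentile of the weight distribution (so
    percentile ≈ the fraction of candidates retained).
    ``tail="bottom"``: drop the weak tail — keep weight ≥ the percentile-th
    percentile. Linear-interpolation percentiles throughout.
    """
    if not 0 <= percentile <= 100:
        raise NetworkError(f"percentile {percentile} outside [0, 100]")
    if tail not in ("top", "bottom"):
        raise NetworkError(f"unknown tail {tail!r}")
    out = candidates.copy()
    w = out["weight"].to_numpy()
    q = 100.0 - percentile if tail == "top" else percentile
    threshold = float(np.percentile(w, q))
    out["selected"] = out["weight"] >= threshold
    return out


def _repair(candidates: pd.DataFrame) -> pd.DataFrame:
    """Enforce one direction per pair and acyclicity of the selected arcs."""
    out = candidates.copy()
    sel = out[out["selected"]]
    # (i) reciprocal pairs: keep higher weight, tie -> higher frequency, then lexicographic
    by_arc = {
        (r.source, r.target): (r.weight, r.frequency, r.Index)
        for r in sel.itertuples()
    }
    for (s, t), (w, f, i) in list(by_arc.items()):
        rev = (t, s)
        if rev in by_arc:
            w2, f2, i2 = by_arc[rev]
            keep_fwd = (w, f, rev) > (w2, f2, (s, t))  # smaller id wins full tie
            drop = i2 if keep_fwd else i
            if out.at[drop, "selected"]:
                out.at[drop, "selected"] = False
                logger.info(
                    "consensus: dropped reciprocal arc %s->%s",
                    *(rev if keep_fwd else (s, t)),
                )
    # (ii) cycle repair: drop the lowest-weight arc of each remaining cycle
    while True:
        sel = out[out["selected"]]
        g = nx.DiGraph()
        g.add_edges_from(zip(sel["source"], sel["target"], strict=True))
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        arcs = {(u, v) for u, v, *_ in cycle}
        in_cycle = sel[
            [(s, t) in arcs for s, t in zip(sel["source"], sel["target"], strict=True)]
        ]
        drop = in_cycle.sort_values(
            ["weight", "frequency", "source", "target"]
        ).index[0]
        out.at[drop, "selected"] = False
        logger.info(
            "consensus: broke cycle by dropping %s->%s",
            out.at[drop, "source"], out.at[drop, "target"],
        )
    return out


def build_consensus(
    models: Sequence[LearnedModel],
    percentile: float,
    mode: str = "shifted",
    include: str = "learned",
    tail: str = "top",
) -> ConsensusNetwork:
    """Percentile-thresholded, repaired consensus network of an ensemble."""
    candidates = select_by_percentile(
        edge_strengths(models, mode, include), percentile, tail
    )
    candidates = _repair(candidates)

    tf_ids = models[0].tf_ids
    fixed = sorted(
        {(s, t) for m in models for s, t in m.arcs if t not in tf_ids}
    )
    sel = candidates[candidates["selected"]]
    g = nx.Graph()
    g.add_edges_from(zip(sel["source"], sel["target"], strict=True))
    g.add_edges_from(fixed)
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        logger.warning(
            "consensus network is weakly disconnected: %d components of sizes %s",
            len(comps), sorted((len(c) for c in comps), reverse=True)[:10],
        )
    return ConsensusNetwork(
        candidates=candidates,
        fixed_tf_gene_arcs=tuple(fixed),
        percentile=percentile,
        n_models=len(models),
    )


def write_consensus(net: ConsensusNetwork, path) -> None:
    """Full candidate table as TSV: source, target, frequency, weight, selected."""
    out = net.candidates.copy()
    out["selected"] = out["selected"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
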