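"""Core domain types, structural predicates and file I/O for regulatory networks.

A transcriptional regulatory network (TRN) is a directed graph whose nodes
split into transcription factors (TFs, the only nodes allowed outgoing arcs)
and target genes. Arcs optionally carry a nonnegative binding score derived
from ChIP-Seq evidence. This module holds the validated in-memory containers
(:class:`RegulatoryNetwork`, :class:`ExpressionMatrix`, :class:`Whitelist`),
the acyclicity/connectivity predicates the Bayesian machinery relies on, and
every reader/writer (TSV edge lists, expression matrices, SIF/GraphML exports,
JSON ensemble serialization).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("tbnlearn")

ENSEMBLE_SCHEMA_VERSION = 1

#: (source, target, weight-or-None)
Arc = tuple[str, str, float | None]


class NetworkError(ValueError):
    """Raised on invalid network structure or malformed input."""


class ParseError(NetworkError):
    """Raised on malformed input files; message carries the line number."""


def _fmt(x: float) -> str:
    """Serialize a float with 17 significant digits (lossless round trip)."""
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed TF→TF / TF→gene graph with optional binding-score weights.

    Invariants (enforced at construction): every arc source is a declared TF;
    TF and gene id sets are disjoint and cover all arc endpoints; no
    self-loops or duplicate (source, target) pairs; weights are either
    present on all arcs (all ≥ 0) or absent on all.
    """

    tf_ids: frozenset[str]
    gene_ids: frozenset[str]
    edges: tuple[Arc, ...]

    def __post_init__(self) -> None:
        if self.tf_ids & self.gene_ids:
            raise NetworkError(
                f"tf_ids and gene_ids overlap: {sorted(self.tf_ids & self.gene_ids)[:5]}"
            )
        nodes = self.tf_ids | self.gene_ids
        seen: set[tuple[str, str]] = set()
        n_weighted = 0
        for s, t, w in self.edges:
            if s == t:
                raise NetworkError(f"self-loop {s}->{t} not allowed")
            if s not in self.tf_ids:
                raise NetworkError(f"arc source {s!r} is not a declared TF")
            if t not in nodes:
                raise NetworkError(f"arc target {t!r} is not a declared node")
            if (s, t) in seen:
                raise NetworkError(f"duplicate arc {s}->{t}")
            seen.add((s, t))
            if w is not None:
                if not math.isfinite(w) or w < 0:
                    raise NetworkError(f"arc {s}->{t} has invalid weight {w}")
                n_weighted += 1
        if n_weighted not in (0, len(self.edges)):
            raise NetworkError("weights must be present on all arcs or none")

    # -- convenience -------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return self.tf_ids | self.gene_ids

    @property
    def n_arcs(self) -> int:
        return len(self.edges)

    @property
    def weighted(self) -> bool:
        return bool(self.edges) and self.edges[0][2] is not None

    def arc_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.edges}

    def to_digraph(self) -> nx.DiGraph:
        # sorted node insertion keeps downstream iteration order independent
        # of the per-process hash seed
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for s, t, w in self.edges:
            if w is None:
                g.add_edge(s, t)
            else:
                g.add_edge(s, t, weight=w)
        return g

    @staticmethod
    def from_arcs(
        arcs: Iterable[Arc],
        tf_ids: Iterable[str],
        extra_genes: Iterable[str] = (),
    ) -> "RegulatoryNetwork":
        """Build a network, inferring gene_ids as non-TF arc endpoints."""
        arcs = tuple(arcs)
        tfs = frozenset(tf_ids)
        genes = {t for _, t, _ in arcs if t not in tfs} | set(extra_genes)
        return RegulatoryNetwork(tfs, frozenset(genes), arcs)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples matrix of continuous, normalized expression values."""

    node_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.node_ids), len(self.sample_ids)):
            raise NetworkError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.node_ids)} nodes x {len(self.sample_ids)} samples"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise NetworkError("duplicate node IDs in expression matrix")
        if len(self.sample_ids) < 3:
            raise NetworkError("n_samples >= 3 required")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise NetworkError(
                f"missing value at ({self.node_ids[i]}, {self.sample_ids[j]})"
            )
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, node: str) -> bool:
        return node in self._index  # type: ignore[attr-defined]

    def row(self, node: str) -> np.ndarray:
        return self.values[self._index[node]]  # type: ignore[attr-defined]

    def rows(self, nodes: Sequence[str]) -> np.ndarray:
        idx = [self._index[n] for n in nodes]  # type: ignore[attr-defined]
        return self.values[idx]


@dataclass(frozen=True)
class WhitelistArc:
    """A candidate TF→TF arc excluded from the initial DAG.

    Carries the ChIP-Seq binding weight it entered with, the Pearson
    correlation of the two TF expression profiles once computed, and its
    normalized sampling probability in the search.
    """

    source: str
    target: str
    weight: float | None = None
    correlation: float | None = None
    sampling_prob: float | None = None


@dataclass(frozen=True)
class Whitelist:
    """The search space of the learner: TF-TF arcs removed at loop-breaking."""

    arcs: tuple[WhitelistArc, ...]

    def __post_init__(self) -> None:
        pairs = [(a.source, a.target) for a in self.arcs]
        if len(set(pairs)) != len(pairs):
            raise NetworkError("duplicate arcs in whitelist")
        for a in self.arcs:
            if a.source == a.target:
                raise NetworkError(f"self-loop {a.source} in whitelist")
        probs = [a.sampling_prob for a in self.arcs if a.sampling_prob is not None]
        if probs:
            if len(probs) != len(self.arcs):
                raise NetworkError("sampling_prob set on some arcs but not all")
            if any(p < 0 for p in probs):
                raise NetworkError("negative sampling probability")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise NetworkError(
                    f"sampling probabilities sum to {sum(probs)!r}, expected 1"
                )

    def __len__(self) -> int:
        return len(self.arcs)

    def __iter__(self):
        return iter(self.arcs)

    def pairs(self) -> set[tuple[str, str]]:
        return {(a.source, a.target) for a in self.arcs}


# ---------------------------------------------------------------------------
# Structural predicates
# ---------------------------------------------------------------------------


def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, RegulatoryNetwork):
        return net.to_digraph()
    if isinstance(net, nx.DiGraph):
        return net
    raise TypeError(f"expected RegulatoryNetwork or DiGraph, got {type(net)}")


def is_acyclic(net) -> bool:
    """True iff the directed graph contains no directed cycle."""
    g = _as_digraph(net)
    if g.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    return nx.is_directed_acyclic_graph(g)


def is_weakly_connected(net) -> bool:
    """True iff the graph is connected when arc direction is ignored."""
    g = _as_digraph(net)
    if g.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    return nx.is_weakly_connected(g)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_tf_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text regulator list, one ID per line."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return frozenset(i for i in ids if i)


def read_edge_list(
    path: str | Path, tf_list: str | Path | None = None
) -> RegulatoryNetwork:
    """Read a delimiter-separated edge list into a validated network.

    Columns are ``source, target[, weight]`` (tab or comma separated, no
    header). When *tf_list* is given it names the regulators; otherwise every
    node appearing as a source is treated as a TF. Duplicate rows collapse to
    the maximum weight; first-appearance row order is preserved.
    """
    path = Path(path)
    arcs: dict[tuple[str, str], float | None] = {}
    order: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty edge list")
        delim = _detect_delimiter(first)
        fh.seek(0)
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            if len(row) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(row)}"
                )
            s, t = row[0], row[1]
            w: float | None = None
            if len(row) == 3:
                try:
                    w = float(row[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {row[2]!r}"
                    ) from exc
                if w < 0:
                    raise NetworkError(f"{path}:{lineno}: negative weight {w}")
            key = (s, t)
            if key in arcs:
                old = arcs[key]
                if (w is None) != (old is None):
                    raise ParseError(
                        f"{path}:{lineno}: arc {s}->{t} mixes weighted and "
                        "unweighted rows"
                    )
                if w is not None and old is not None:
                    arcs[key] = max(old, w)
            else:
                arcs[key] = w
                order.append(key)
    tfs = (
        read_tf_list(tf_list)
        if tf_list is not None
        else frozenset(s for s, _ in order)
    )
    edges = tuple((s, t, arcs[(s, t)]) for s, t in order)
    return RegulatoryNetwork.from_arcs(edges, tfs)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV/CSV expression table: header ``id, sample1..sampleM``."""
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: empty expression file")
        delim = _detect_delimiter(header_line)
        header = [c.strip() for c in header_line.rstrip("\n").split(delim)]
        sample_ids = tuple(header[1:])
        node_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}"
                )
            node = row[0].strip()
            vals = []
            for j, cell in enumerate(row[1:]):
                cell = cell.strip()
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    raise NetworkError(
                        f"missing value at ({node}, {sample_ids[j]})"
                    )
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r}"
                    ) from exc
            node_ids.append(node)
            rows.append(vals)
    if len(set(node_ids)) != len(node_ids):
        dup = sorted({n for n in node_ids if node_ids.count(n) > 1})
        raise NetworkError(f"duplicate node ID(s) in expression: {dup[:5]}")
    return ExpressionMatrix(tuple(node_ids), sample_ids, np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_network(net, path: str | Path, fmt: str = "tsv") -> None:
    """Write a network as TSV edge list, SIF, or GraphML.

    *net* may be a :class:`RegulatoryNetwork` or any object exposing an
    ``edges`` iterable of (source, target, weight) triples (e.g. a selected
    consensus view).
    """
    path = Path(path)
    edges = list(net.edges)
    if fmt == "tsv":
        with path.open("w") as fh:
            for s, t, w in edges:
                if w is None:
                    fh.write(f"{s}\t{t}\n")
                else:
                    fh.write(f"{s}\t{t}\t{_fmt(w)}\n")
    elif fmt == "sif":
        with path.open("w") as fh:
            for s, t, _ in edges:
                fh.write(f"{s}\tregulates\t{t}\n")
    elif fmt == "graphml":
        g = _as_digraph(net) if isinstance(net, (RegulatoryNetwork, nx.DiGraph)) else None
        if g is None:
            g = nx.DiGraph()
            for s, t, w in edges:
                g.add_edge(s, t, **({} if w is None else {"weight": w}))
        nx.write_graphml(g, path)
    else:
        raise NetworkError(f"unknown format {fmt!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(expr.sample_ids) + "\n")
        for i, node in enumerate(expr.node_ids):
            fh.write(node + "\t" + "\t".join(_fmt(v) for v in expr.values[i]) + "\n")


def write_whitelist(wl: Whitelist, path: str | Path) -> None:
    """Whitelist TSV: source, target, weight, correlation, sampling_prob."""

    def cell(v):
        return "" if v is None else _fmt(v)

    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tweight\tcorrelation\tsampling_prob\n")
        for a in wl.arcs:
            fh.write(
                f"{a.source}\t{a.target}\t{cell(a.weight)}\t"
                f"{cell(a.correlation)}\t{cell(a.sampling_prob)}\n"
            )


def read_whitelist(path: str | Path) -> Whitelist:
    arcs = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def opt(key: str) -> float | None:
                v = row.get(key, "")
                return None if v in ("", None) else float(v)

            arcs.append(
                WhitelistArc(
                    row["source"], row["target"], opt("weight"),
                    opt("correlation"), opt("sampling_prob"),
                )
            )
    return Whitelist(tuple(arcs))


# ---------------------------------------------------------------------------
# Ensemble serialization (JSON, schema-versioned)
# ---------------------------------------------------------------------------


def write_ensemble(models: Sequence, path: str | Path) -> None:
    """Serialize learned models (structures, scores, move traces) to JSON."""
    if not models:
        raise NetworkError("ensemble is empty")
    payload = {
        "schema_version": ENSEMBLE_SCHEMA_VERSION,
        "models": [
            {
                "seed": m.seed,
                "bic_global": m.bic_global,
                "tf_ids": sorted(m.tf_ids),
                "arcs": [[s, t] for s, t in m.arcs],
                "moves": [
                    {
                        "source": mv.source,
                        "target": mv.target,
                        "move_type": mv.move_type,
                        "delta_bic": mv.delta_bic,
                        "iteration": mv.iteration,
                    }
                    for mv in m.moves
                ],
            }
            for m in models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ensemble(path: str | Path):
    from .structure_search import LearnedModel, Move  # local: avoid cycle

    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != ENSEMBLE_SCHEMA_VERSION:
        raise NetworkError(f"unsupported ensemble schema version {version!r}")
    models = []
    for m in payload["models"]:
        models.append(
            LearnedModel(
                arcs=tuple((s, t) for s, t in m["arcs"]),
                tf_ids=frozenset(m["tf_ids"]),
                bic_global=m["bic_global"],
                moves=tuple(
                    Move(
                        mv["source"], mv["target"], mv["move_type"],
                        mv["delta_bic"], mv["iteration"],
                    )
                    for mv in m["moves"]
                ),
                seed=m["seed"],
            )
        )
    return models
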