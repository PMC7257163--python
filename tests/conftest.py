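"""Shared fixtures: tiny hand-built networks/expression and scenario builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import tbnlearn as tl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_expression(rows: dict[str, np.ndarray]) -> tl.ExpressionMatrix:
    names = list(rows)
    n = len(next(iter(rows.values())))
    return tl.ExpressionMatrix(
        tuple(names),
        tuple(f"S{i+1}" for i in range(n)),
        np.vstack([rows[k] for k in names]),
    )


@pytest.fixture
def tiny_trn() -> tl.RegulatoryNetwork:
    """2 TFs, 1 gene: A->B (w=2), A->G1 (w=1), B->G1 (w=3)."""
    return tl.RegulatoryNetwork(
        frozenset({"A", "B"}),
        frozenset({"G1"}),
        (("A", "B", 2.0), ("A", "G1", 1.0), ("B", "G1", 3.0)),
    )


@pytest.fixture
def small_expr() -> tl.ExpressionMatrix:
    rng = np.random.default_rng(42)
    a = rng.normal(size=10)
    return make_expression(
        {"A": a, "B": 2.0 * a + rng.normal(scale=0.1, size=10), "G1": rng.normal(size=10)}
    )


# ---------------------------------------------------------------------------
# Planted-arc scenario: one strong held-out TF-TF arc + zero-effect decoys
# ---------------------------------------------------------------------------

PLANTED = ("T1", "T2")
DECOYS = [
    ("T1", "T4"), ("T1", "T5"), ("T1", "T6"), ("T4", "T2"), ("T5", "T2"),
    ("T6", "T2"), ("T5", "T1"), ("T6", "T1"), ("T4", "T3"), ("T6", "T3"),
]
PLANTED_DAG = [("T3", "T4"), ("T4", "T5"), ("T5", "T6"), ("T3", "T1"), ("T3", "T2")]


def planted_scenario(seed: int, n: int = 200):
    """6 TFs / 10 genes; T2 = 1.5·T1 + small noise is the held-out signal.

    Returns (init, expr): an InitializedModel whose whitelist holds the
    planted arc plus 10 decoy arcs with no generative effect.
    """
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}
    rows["T1"] = rng.normal(size=n)
    rows["T2"] = 1.5 * rows["T1"] + rng.normal(scale=0.3, size=n)
    for t in ("T3", "T4", "T5", "T6"):
        rows[t] = rng.normal(size=n)
    tf_names = ["T1", "T2", "T3", "T4", "T5", "T6"]
    gene_arcs = []
    for i in range(10):
        g = f"G{i+1}"
        parent = tf_names[i % 6]
        rows[g] = 1.0 * rows[parent] + rng.normal(scale=0.5, size=n)
        gene_arcs.append((parent, g, None))
    expr = make_expression(rows)

    tfs = frozenset(tf_names)
    dag = tl.RegulatoryNetwork(tfs, frozenset(), tuple((s, t, None) for s, t in PLANTED_DAG))
    genes = frozenset(f"G{i+1}" for i in range(10))
    tf_gene = tl.RegulatoryNetwork(tfs, genes, tuple(gene_arcs))
    wl = tl.Whitelist(
        tuple(tl.WhitelistArc(s, t) for s, t in [PLANTED] + DECOYS)
    )
    wl = tl.compute_arc_probabilities(wl, expr)
    init = tl.InitializedModel(dag=dag, whitelist=wl, tf_gene=tf_gene, provenance={})
    return init, expr


# ---------------------------------------------------------------------------
# Robustness experiment (yeast-style false-prior design, scaled down)
# ---------------------------------------------------------------------------

ROBUSTNESS_SPEC = dict(
    n_tf=20, n_gene=100, tf_tf_arcs=90, tf_gene_arcs=700,
    loop_fraction=0.25, n_samples=150, weighted=False,
)


def robustness_precision(seed: int, fp_fraction: float, n_runs: int = 100):
    """Full pipeline precision at one injected-FP level; see methods note."""
    spec = tl.SyntheticSpec(seed=seed, **ROBUSTNESS_SPEC)
    gold, corrupted, expr, injected = tl.make_robustness_fixture(spec, fp_fraction)
    init = tl.initialize(corrupted, expr, seed=seed)
    config = tl.SearchConfig(w=10, n_runs=n_runs, seed=seed * 100)
    models = tl.run_ensemble(init, expr, config)
    cons = tl.build_consensus(models, percentile=25.0)
    gold_tf = {(s, t) for s, t, _ in gold.edges if t in gold.tf_ids}
    return tl.precision_report(cons, gold_tf, injected, fp_fraction)
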