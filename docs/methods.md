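# Methods

## Model

The transcriptional BN assumes a jointly multivariate-Gaussian expression
distribution over TFs and genes: each node X with parents pa(X) = {u₁…u_k}
is modelled as X ~ N(a₀ + Σ aᵢuᵢ, σ²), with σ² independent of the parent
values. Local models are fitted by ordinary least squares; rank-deficient
designs (collinear parents) fall back to the minimum-norm solution with a
warning. σ² is reported in the maximum-likelihood convention RSS/n, which
is cosmetic — scoring uses RSS directly.

Scores use the natural logarithm (the base rescales every score
consistently, so move decisions are unaffected). The parameter count k of a
node's local model counts the regression coefficients including the
intercept and excluding σ: this bookkeeping makes an arc addition cost
Δk = 1 and a reversal Δk = 0, which is what the move deltas require. Were σ
counted as well, every absolute node score would shift by ln(n) but all
move deltas would be unchanged. An exactly-zero RSS (possible only on
noiseless synthetic data) is clamped to 1e-12 × TSS (with an absolute tiny
floor for constant profiles) before taking the log, with a warning.

## Initialization

Loop-breaking visits TF-TF arcs in increasing binding weight — equal
weights keep stable input order; unweighted inputs are shuffled once with
the run seed and treated as equal weight — and removes each visited arc if
the component remains weakly connected, otherwise restores and skips it.
"Connected" is read as weak (direction-blind) connectivity: strong
connectivity is impossible for a DAG, and the n−1-arc skeleton this
produces matches the published component sizes. A single pass is
sufficient: a skipped arc is an undirected bridge at visit time and only
becomes "more of a bridge" as later arcs are removed, while any component
still above tree size contains a removable non-bridge arc; so the sweep
always terminates at exactly n−1 arcs per component. Disconnected TF-TF
inputs are processed per component (a forest results) with a warning;
isolated TFs contribute zero skeleton arcs. Reciprocal pairs get no special
treatment: the lower-weight direction is simply visited (and removed)
first.

Whitelist arcs carry the signed Pearson correlation of their TF pair for
reporting; the sampling probability uses |r| normalized to sum 1, because a
strong negative correlation (repression) is as informative a prior as a
strong positive one and probabilities must be nonnegative. Correlations
with |r| below 1e-12 are floored at 1e-12 before normalization so every
whitelist arc stays drawable.

## Search

Candidate sampling is weighted-without-replacement with renormalization
after each draw. Every sampled candidate is evaluated against the *current*
model — evaluations never compound within an iteration, so their results
are order-independent and could run concurrently; the implementation
evaluates them sequentially, which is exactly equivalent. Ties on ΔBIC
break by higher sampling probability, then lexicographic arc id. Exactly
one move is applied per iteration. Cycle-creating candidates beyond the
2-cycle (which is handled as a reversal) are rejected rather than repaired,
since the move set contains only additions and reversals. An accepted arc
retires from the whitelist; the arc displaced by a reversal is considered
resolved and does not re-enter the whitelist (this prevents oscillation).

The stop threshold is τ = 10/|BIC_global(initial TBN)|; the absolute value
matters because the score's sign depends on the data scale and a negative
threshold would never stop the search. Escape attempts (default 10) use a
fixed doubled sampling size (not cumulative doubling) and must also clear
τ — since every accepted move then improves the global score by more than
τ, the post-escape score is automatically better than the pre-escape score,
which is the stated stopping comparison. A safety cap of
10 × |whitelist| iterations guarantees termination on adversarial inputs.
Ensemble runs use seeds seed, seed+1, …; each run owns its generator, so
optional joblib parallelism (`n_jobs`) cannot change results or ordering.

## Consensus

Candidates are the *learned* TF-TF arcs: arcs accepted as moves that
survive to a run's final structure. Unreversed initial-DAG skeleton arcs
are not candidates — they were never chosen by the learner — while a
reversal is a learned arc, so a flipped skeleton arc can enter the
consensus. An inclusive mode (`include="structure"`) counting every TF-TF
arc of every final structure is available for diagnostics.

Per-model strength: summing raw global BIC values is ill-behaved — their
sign depends on the data scale, and with negative scores an arc present in
more models would accumulate a *worse* weight. The default strength is the
shifted positive score S(m) = worst_bic − bic(m) + δ with
δ = |worst_bic|·1e-6 + 1, which preserves both intended orderings
(presence in more models ⇒ larger weight; better models contribute more)
and degenerates to frequency counting when all model scores are equal. The
literal raw sum is available as `mode="raw"`.

The confidence threshold keeps the strong tail of the candidate weight
distribution: `percentile=p` selects candidates at or above the (100−p)th
weight percentile, i.e. roughly the strongest p% — a small p is a strict
filter. The complementary convention (drop the weakest p%, keep the rest)
is available as `tail="bottom"`. Linear-interpolation percentiles are used.
Repair order: (i) if both directions of a TF pair survive, keep the
higher-weight one (ties: higher frequency, then lexicographically smaller
arc); (ii) while a directed cycle remains, drop its lowest-weight arc;
(iii) weak connectivity of selected-plus-fixed arcs is verified and
components are reported as a warning if it fails.

## Topology metrics

Hierarchy height h = (out − in)/(out + in) on the TF-TF subgraph with layer
cutoffs ±1/3 (configurable): master regulator above, workhorse below,
middle manager between; isolated TFs get h = 0, middle manager, and an
`isolated` flag. "Average connectivity" is reported in two conventions —
mean total degree per node, and arcs per node (E/n) — because the intended
definition is ambiguous; neither is asserted against published summary
values. TP/FP matching is direction-sensitive: a consensus arc whose
reverse (but not itself) is in the gold standard counts as a false
positive, and is additionally tallied in a `reversed` diagnostic column.
False-arc injection draws round(fraction × |TF-TF arcs|) ordered TF pairs
(banker's rounding) uniformly from pairs absent in the gold network; on a
weighted gold network injected arcs receive weights uniform between the
gold minimum and maximum, since the container requires weights on all arcs
or none.

## Synthetic data

The generator emulates the statistical structure the learner assumes. A
random weakly-connected DAG on the TFs (spanning tree plus forward arcs in
a random topological order) is the *generative core*; cycle-closing decoy
arcs (a configurable fraction of the TF-TF arcs, both 2-cycles and longer
cycles) are added on top but have **no generative effect** — a joint
Gaussian with true feedback is undefined in this model family, and this
mirrors how real binding priors contain loops while the fitted model is a
DAG. Expression is sampled along the core in topological order with
coefficients uniform in (0.5, 1.5) in magnitude, random sign, intercepts
uniform in (−1, 1), and noise σ = 1 by default. Binding weights are
positive with core arcs stochastically higher (U(1, 2) vs U(0.1, 1.1)).
Fixtures are pure functions of (spec, seed).

What passing tests on these fixtures do **not** show: real expression data
is not linear-Gaussian, has batch and probe effects, and real binding
priors have structured (not uniform) false positives; results here
demonstrate correctness of the machinery and the qualitative robustness
properties, not field performance.

## Problem sizes used in the test suite

Published-size structural checks run at full scale (65 TFs/1827 arcs;
33 TFs/249 arcs; 470-node TBN) since loop-breaking is cheap. Statistical
checks run at reduced scale chosen to mirror the benchmark experiment's
proportions: the robustness experiment uses 20 TFs / 100 genes / 150
samples with 90 TF-TF arcs (matching the benchmark network's ~0.24
ordered-pair density) and 700 TF→gene arcs (~7 per gene), unweighted mode,
100 search runs per condition, consensus percentile 25, and a per-iteration
sampling size of w = 10 — chosen to keep the sampled fraction of the
whitelist (~10–15%) comparable to the full-scale setting, where w = 100
draws from a whitelist of ~1600; a sampling size that covers the whole
whitelist would make every run identical and defeat the frequency-based
consensus filter. The planted-arc recovery scenario uses 6 TFs / 10 genes /
200 samples with one strong held-out arc and 10 zero-effect decoys.

## Known limitations

- No arc deletions: a falsely added arc can only be displaced by a
  reversal, so early spurious additions persist within a run; the consensus
  stage is the mechanism that filters them across runs.
- The search never explores TF→gene arcs; they are fixed throughout.
- Eq-style raw-sum consensus weights are retained only as an option; the
  default shifted strength is an interpretive choice (documented above).
- Expression is used as-is by default — no standardization step is assumed
  after upstream normalization; an optional per-gene z-score switch
  (`fit_bn(..., standardize_expr=True)`) is provided for experiments on data
  whose scale varies wildly across genes.
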