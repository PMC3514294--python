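# Methods

## Random-walk models

The engine works on a weighted digraph with strictly positive collapsed edge
weights `W_ij`. The evolution operator folds damping into the move:
`P_ij = μ W_ij / Σ_j' W_ij'`, so every node with outgoing weight leaks
exactly `1 − μ` of its probability per step. Nodes with no outgoing weight
(dangling nodes, and excluded nodes after their rows are zeroed) have an
all-zero row: full one-step dissipation.

Three models share one piece of linear algebra. With `T` the transient index
set and `A = I − P_TT`:

* absorbing: solve `A X = P_TK` column-block for `F` (never forming
  `G = A^{-1}` densely);
* emitting: solve the transposed system `Aᵀ Y = P_STᵀ` for `H = Yᵀ`;
* channel: both solves against the *same* sparse LU factorisation of `A`
  (SuperLU via `scipy.sparse.linalg.splu`), with the transient set
  excluding both sources and sinks, then
  `Φ̂_si = H_si · Σ_k F_ik / Σ_k' F_sk'`.

The channel denominator needs absorption probabilities *for a source*, which
the transient system does not define; we use the one-step extension
`F_sk = Σ_j P_sj F_jk + P_sk`, i.e. the termination probability of a walker
emitted from `s`. Sources are strictly boundary in the channel transient
set; a query listing the same node as source and sink is rejected.

### Summary statistics

* Mean path length `t̄ = 1 + mean_s Σ_j H_sj` (channel: `Φ̂` in place of
  `H`). The leading 1 counts the emission step.
* Mean absorption `r̄ = mean_i Σ_k F_ik`, averaged over exactly those
  transient nodes with a directed positive-weight path to at least one sink
  (reverse breadth-first search from the sinks); unreachable components
  would otherwise drag the average toward zero without being informative.
* Interference: the per-node minimum of visits over sources — large only
  where every source sends substantial flow.
* Shortest source→sink path length is the minimum *hop count* over
  positive-weight directed edges (breadth-first search), because `t̄` counts
  discrete steps.

### Endpoint handling

`μ = 1` is allowed only for the absorbing model and only when every
transient node can reach a sink (otherwise `A` is singular and the
unreachable nodes are named in the error). `μ = 0` returns the degenerate
all-zero result with a warning rather than failing — the query is
well-formed, the flow just dies immediately. Tests assert the direct-solve
residual `‖A x − b‖_∞ < 1e-9`.

## Graph construction

Typed edges are collapsed per direction: directed edges contribute their
weight forward only, undirected edges contribute equally both ways, ignored
types contribute nothing, and parallel contributions sum. Unlisted edge
types default to undirected. Weight resolution has two explicit modes
rather than being inferred from the data: *default* mode assigns 2 to
self-loops and 1 to every other edge; *attribute* mode takes weights from a
column and treats nulls as zero (the edge then drops out). Node order is
fixed lexicographically at construction so matrices and output files are
byte-reproducible.

Excluded nodes model biologically irrelevant shortcuts: any flow reaching
them is fully dissipated. They are kept in the graph with their outgoing
rows zeroed and incoming entries retained — deleting them would silently
renormalise their neighbours' rows and redistribute the flow instead of
dissipating it. Self-loops are kept and enter both the numerator and
denominator of their row (a walker may revisit its own node).

## Damping calibration

`t̄(μ)` and `r̄(μ)` are monotone increasing, so a target value is a root of
a monotone scalar function on `(0, 1)`. The solver brackets with
`[1e-6, 1 − 1e-6]`, verifies `f(lo) ≤ target ≤ f(hi)` (otherwise it reports
the achievable range), and runs Newton iterations with a central
finite-difference derivative (`h = 1e-6`, clipped to the bracket); a step
leaving the bracket is replaced by bisection and the bracket is updated
from the monotonicity. Convergence is declared on the *statistic*,
`|f(μ) − target| < 1e-8 · max(1, target)`, because the statistic is what the
user specified; the finite difference costs two extra sparse solves per
iteration, which is cheap next to implementing the derivative system.
If the statistic is constant in μ (a single-path channel, where `t̄ = L_sp`
for every μ) the bracket midpoint is returned with a warning. Path-deviation
targets are `t̄* = L_sp + d` (absolute) or `L_sp (1 + d)` (relative); for
the emitting model, which has no sinks, the deviation is interpreted
against the minimal one-step walk, `L_sp := 1` — both deviation forms are
accepted for emitting even though only `t̄` itself is strictly needed
there.

## Ranking, selection, colours

Ranking attributes are the per-boundary columns of `H`/`Φ̂`/`F`, their
total, the interference (emitting/channel), or any imported custom column.
Selection is top-k, strict cutoff (`value > x`), or the participation ratio
`PR = (Σ v)² / Σ v²` rounded to the nearest integer — the standard
scale-invariant effective count of significant entries (uniform values over
n nodes give n; one spike gives 1). Rounding to nearest rather than flooring
gives the closest count. Ties in the ranking break by node id ascending, so
selections are deterministic.

Colours use subtractive CMY mixing: each of up to three attribute columns
is scaled to `[0, 1]` by `s(v)/s(v_max)` with `s` linear, square-root or
`log1p` (default square-root, which suits the dynamic range typical of flow
values), assigned cyan, magenta, yellow in order, and combined as
`RGB = (1 − c, 1 − m, 1 − y)`. No flow means white; a node dominated by one
source visibly takes that source's hue. A single column runs through the
same machinery as a cyan ramp; an eight-bin sequential palette constant
(`SEQUENTIAL_PALETTE_8`) is provided for discretised single-attribute
styling and can be replaced by any user hex list.

## File formats

SIF input (`source etype target...`, tab- or space-delimited) implies
default-weight mode; a TSV edge table may name a weight column. Results
export is a self-contained tab-delimited dialect: `#key<TAB>value` headers
record model, μ, criterion, boundaries and summary statistics; columns are
named with the `ITM<model-code><run-id>[<boundary-tag>]` scheme; rows cover
every node with a nonzero value at full `repr` precision, ordered by
descending total with id tie-break. On import, rows whose ids are absent
from the target graph are skipped (count logged) and unknown columns come
back as custom ranking attributes, supporting derived-attribute workflows
(e.g. averaging two source columns into a new one). The layout is declared
self-contained, not byte-compatible with any other tool's export. Run ids
increase monotonically per output directory via a sidecar counter file and
are purely cosmetic.

## Monte Carlo oracle

`itmflow.simulate` estimates the same quantities by stepping walker
ensembles directly: per step (1) a dissipation trial with probability
`1 − μ`, (2) a weight-proportional move, (3) a termination check at the
arrival node — matching `P = μ · rownorm(W)`, where dissipation precedes
the move. Stepping onto an excluded or dangling node kills the walk. A
visit is counted on every arrival at a transient node, the starting node is
never counted, and arrival at a boundary node terminates (any arrival at a
source terminates, including via a source self-loop). `Φ̂` is estimated as
the mean visit count among sink-absorbed walks — the conditional-mean form
of the analytic definition. The ensemble is vectorised over walkers
(padded neighbour tables, cumulative row distributions), so 2×10⁵ walkers
on 30-node graphs take well under a second; a fixed seed is
bit-reproducible, and a guard raises if ≥ 0.1% of walks hit the step cap.

Fixture generators (`path`, `parallel_paths`, `lattice_with_holes` with 10%
of nodes and edges removed, connected `random_er` regenerated with an
incremented seed if a draw is disconnected) are deterministic in their
seed. They emulate the topologies the flow models are designed for — sparse,
roughly homogeneous interaction maps — but not the heavy-tailed degree
distributions, weight heterogeneity or annotation noise of real
interactomes, so passing tests demonstrate correctness of the computation,
not biological performance on real networks.

## Problem sizes and limitations

The test and acceptance suites run on graphs of 3–36 nodes with ensembles
up to 2×10⁵ walkers — sizes where closed forms and tight Monte Carlo errors
make the checks sharp; the sparse-LU path itself scales to much larger
networks. Known limitations: damping is uniform (no per-node dissipation),
no stationary/eigenvector analyses, the emitting model rejects `μ = 1`
outright rather than handling the marginally convergent cases, and the raw
(unnormalised) channel visits `Φ^s_{ik}` are exposed as a convenience
(`FlowResult.raw_phi`) without a reference to compare against.
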