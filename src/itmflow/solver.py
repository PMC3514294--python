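"""Damped random-walk flow models on weighted digraphs.

A walker at node *i* survives each step with probability mu (the damping
factor) and then moves to neighbour *j* with probability proportional to the
edge weight W_ij.  Folding damping into the move gives the row-substochastic
evolution operator

    P_ij = mu * W_ij / sum_j' W_ij'

Boundary nodes terminate walks: *sinks* absorb, and *sources* absorb walkers
that return to them after emission.  With P_TT the restriction of P to
transient (non-boundary, non-excluded) nodes and G = (I - P_TT)^-1 the
fundamental matrix of the absorbing chain, the three models are:

* absorbing:  F_ik = (G P_.K)_ik — the probability that a walk from transient
  node i terminates at sink k;
* emitting:   H_si = (P_S. G)_si — the expected number of visits to transient
  node i per walker emitted from source s;
* normalized channel:  Phi-hat_si = sum_k H_si F_ik / sum_k' F_sk' — visits
  per walker conditioned on termination at a sink, with the dissipation
  denominator divided out, tracing likely source-to-sink routes.

G is never materialised: each model needs only a handful of solves against a
single sparse LU factorisation of (I - P_TT).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .errors import NumericalError, ValidationError
from .graph import ModelQuery, WeightedDigraph, mark_excluded

logger = logging.getLogger(__name__)

MODEL_CODES = {"emitting": "E", "absorbing": "A", "channel": "C"}


@dataclass(frozen=True)
class EvolutionOperator:
    """The damped one-step operator P plus node-index bookkeeping."""

    graph: WeightedDigraph
    P: sparse.csr_matrix
    mu: float
    query: ModelQuery
    transient_idx: np.ndarray
    source_idx: np.ndarray
    sink_idx: np.ndarray
    excluded_idx: np.ndarray

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.graph.nodes

    @property
    def transient_nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes[i] for i in self.transient_idx)

    def transient_system(self) -> sparse.csc_matrix:
        """The matrix I - P_TT whose solves drive every model."""
        T = self.transient_idx
        P_TT = self.P[np.ix_(T, T)]
        return (sparse.identity(len(T), format="csc") - P_TT).tocsc()


@dataclass
class FlowResult:
    """Per-node output of one flow model run.

    Only the blocks a model defines are populated: H for emitting; F and
    r_bar for absorbing; H, F, F_source and Phi_hat for channel.  t_bar is
    the mean path length (emitting and channel models).
    """

    model: str
    mu: float
    sources: tuple[str, ...]
    sinks: tuple[str, ...]
    transient_nodes: tuple[str, ...]
    H: Optional[np.ndarray] = None  # (n_sources, n_transient) expected visits
    F: Optional[np.ndarray] = None  # (n_transient, n_sinks) absorption probs
    F_source: Optional[np.ndarray] = None  # (n_sources, n_sinks), channel only
    Phi_hat: Optional[np.ndarray] = None  # (n_sources, n_transient)
    t_bar: Optional[float] = None
    r_bar: Optional[float] = None
    custom: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def visit_matrix(self) -> np.ndarray:
        """H for emitting, Phi-hat for channel (source x transient)."""
        if self.model == "emitting":
            assert self.H is not None
            return self.H
        if self.model == "channel":
            assert self.Phi_hat is not None
            return self.Phi_hat
        raise ValidationError(f"{self.model} model has no per-source visit matrix")

    def raw_phi(self, source: str) -> np.ndarray:
        """Unnormalised channel visits Phi^s_{ik} = H_si F_ik (transient x sink)."""
        if self.model != "channel":
            raise ValidationError("raw_phi is defined only for the channel model")
        s = self.sources.index(source)
        assert self.H is not None and self.F is not None
        return self.H[s][:, None] * self.F


def build_evolution_operator(
    graph: WeightedDigraph, mu: float, query: ModelQuery
) -> EvolutionOperator:
    """Row-normalise W and fold in damping: P = mu * diag(1/rowsum) W.

    Rows of excluded nodes (and of dangling nodes with no outgoing weight)
    are identically zero — full one-step dissipation there.
    """
    if not (0.0 <= mu <= 1.0):
        raise ValidationError(f"damping factor mu={mu!r} outside [0, 1]")
    query.validate_against(graph)
    if query.excluded - graph.excluded:
        graph = mark_excluded(graph, query.excluded)

    out = np.asarray(graph.W.sum(axis=1)).ravel()
    inv = np.zeros_like(out)
    np.divide(1.0, out, out=inv, where=out > 0)
    P = (sparse.diags(mu * inv) @ graph.W).tocsr()

    index = graph.index
    source_idx = np.array([index[s] for s in query.sources], dtype=int)
    sink_idx = np.array([index[k] for k in query.sinks], dtype=int)
    excluded_idx = np.array(sorted(index[x] for x in graph.excluded), dtype=int)
    boundary = set(source_idx) | set(sink_idx) | set(excluded_idx)
    transient_idx = np.array(
        [i for i in range(graph.n_nodes) if i not in boundary], dtype=int
    )
    return EvolutionOperator(
        graph=graph,
        P=P,
        mu=mu,
        query=query,
        transient_idx=transient_idx,
        source_idx=source_idx,
        sink_idx=sink_idx,
        excluded_idx=excluded_idx,
    )


def _sink_reachable(op: EvolutionOperator) -> np.ndarray:
    """Boolean mask over all nodes: has a directed positive-weight path to a sink.

    Computed by breadth-first search from the sinks on the reversed graph;
    a sink itself counts as reachable.
    """
    n = op.graph.n_nodes
    if len(op.sink_idx) == 0:
        return np.zeros(n, dtype=bool)
    adj = (op.graph.W > 0).astype(np.int8)
    dist = csgraph.shortest_path(
        adj.T.tocsr(), method="D", unweighted=True, indices=op.sink_idx
    )
    return np.isfinite(dist).any(axis=0)


def shortest_boundary_path(op: EvolutionOperator) -> float:
    """Minimum hop count from any source to any sink on positive-weight edges."""
    if len(op.source_idx) == 0 or len(op.sink_idx) == 0:
        raise ValidationError("shortest source-to-sink path needs both boundaries")
    adj = (op.graph.W > 0).astype(np.int8).tocsr()
    dist = csgraph.shortest_path(
        adj, method="D", unweighted=True, indices=op.source_idx
    )
    best = dist[:, op.sink_idx].min()
    if not np.isfinite(best):
        raise ValidationError("no directed path from any source to any sink")
    return float(best)


def _factorize(op: EvolutionOperator):
    A = op.transient_system()
    try:
        return splu(A)
    except RuntimeError as exc:  # singular factorisation
        raise NumericalError(f"transient system is singular: {exc}") from exc


def _zero_result(op: EvolutionOperator) -> FlowResult:
    q = op.query
    nT, nS, nK = len(op.transient_idx), len(q.sources), len(q.sinks)
    res = FlowResult(
        model=q.model,
        mu=op.mu,
        sources=q.sources,
        sinks=q.sinks,
        transient_nodes=op.transient_nodes,
    )
    if q.model in ("emitting", "channel"):
        res.H = np.zeros((nS, nT))
        res.t_bar = 1.0
    if q.model in ("absorbing", "channel"):
        res.F = np.zeros((nT, nK))
    if q.model == "absorbing":
        res.r_bar = 0.0
    if q.model == "channel":
        res.F_source = np.zeros((nS, nK))
        res.Phi_hat = np.zeros((nS, nT))
    return res


def solve_absorbing(op: EvolutionOperator) -> FlowResult:
    """Absorption probabilities F_ik by solving (I - P_TT) X = P_TK.

    mu = 1 is allowed only when every transient node has a directed path to
    some sink; otherwise the transient system is singular and the offending
    nodes are named in the error.
    """
    if len(op.sink_idx) == 0:
        raise ValidationError("absorbing model requires at least one sink")
    if op.mu == 0.0:
        warnings.warn("mu = 0: all flow dissipates in one step; result is all zero")
        return _zero_result(op)
    reachable = _sink_reachable(op)
    if op.mu == 1.0:
        bad = [op.graph.nodes[i] for i in op.transient_idx if not reachable[i]]
        if bad:
            raise NumericalError(
                "mu = 1 requires every transient node to reach a sink; "
                f"unreachable: {bad}"
            )
    lu = _factorize(op)
    T, K = op.transient_idx, op.sink_idx
    B = np.asarray(op.P[np.ix_(T, K)].todense())
    F = lu.solve(B) if B.size else np.zeros((len(T), len(K)))
    res = FlowResult(
        model="absorbing",
        mu=op.mu,
        sources=op.query.sources,
        sinks=op.query.sinks,
        transient_nodes=op.transient_nodes,
        F=F,
    )
    res.r_bar = mean_absorption(res, op)
    return res


def solve_emitting(op: EvolutionOperator) -> FlowResult:
    """Expected visit counts H_si via the transposed system (I - P_TT)^T.

    Walks terminate by dissipation or by returning to any source (the sources
    form an emitting boundary), so mu < 1 is required for convergence unless
    return-absorption alone suffices; we require mu < 1 outright.
    """
    if len(op.source_idx) == 0:
        raise ValidationError("emitting model requires at least one source")
    if op.mu >= 1.0:
        raise ValidationError("the emitting model requires mu < 1")
    if op.mu == 0.0:
        warnings.warn("mu = 0: all flow dissipates in one step; result is all zero")
        return _zero_result(op)
    lu = _factorize(op)
    S, T = op.source_idx, op.transient_idx
    P_ST = np.asarray(op.P[np.ix_(S, T)].todense())
    # H = P_ST G  <=>  H^T solves (I - P_TT)^T H^T = P_ST^T
    H = lu.solve(P_ST.T, trans="T").T if P_ST.size else np.zeros((len(S), len(T)))
    res = FlowResult(
        model="emitting",
        mu=op.mu,
        sources=op.query.sources,
        sinks=op.query.sinks,
        transient_nodes=op.transient_nodes,
        H=H,
    )
    res.t_bar = mean_path_length(res)
    return res


def solve_channel(op: EvolutionOperator) -> FlowResult:
    """Normalized channel model: emitting visits re-weighted by sink absorption.

    The transient set excludes both boundaries.  One LU factorisation serves
    both blocks: F = G P_TK (forward solves) and H = P_ST G (transposed
    solves).  The per-source denominator is the one-step extension
    F_sk = sum_j P_sj F_jk + P_sk — the total probability that a walker
    emitted from s terminates at some sink.
    """
    if len(op.source_idx) == 0 or len(op.sink_idx) == 0:
        raise ValidationError("channel model requires at least one source and one sink")
    if op.mu == 0.0:
        warnings.warn("mu = 0: all flow dissipates in one step; result is all zero")
        return _zero_result(op)
    if op.mu == 1.0:
        raise ValidationError("the channel model requires mu < 1")
    lu = _factorize(op)
    S, T, K = op.source_idx, op.transient_idx, op.sink_idx
    P_TK = np.asarray(op.P[np.ix_(T, K)].todense())
    P_ST = np.asarray(op.P[np.ix_(S, T)].todense())
    P_SK = np.asarray(op.P[np.ix_(S, K)].todense())
    if len(T):
        F = lu.solve(P_TK)
        H = lu.solve(P_ST.T, trans="T").T
    else:
        F = np.zeros((0, len(K)))
        H = np.zeros((len(S), 0))
    F_source = P_ST @ F + P_SK
    denom = F_source.sum(axis=1)
    dead = np.where(denom <= 0.0)[0]
    if dead.size:
        names = [op.query.sources[int(s)] for s in dead]
        raise ValidationError(
            f"sources with no directed path to any sink: {names}"
        )
    Phi_hat = H * F.sum(axis=1)[None, :] / denom[:, None]
    res = FlowResult(
        model="channel",
        mu=op.mu,
        sources=op.query.sources,
        sinks=op.query.sinks,
        transient_nodes=op.transient_nodes,
        H=H,
        F=F,
        F_source=F_source,
        Phi_hat=Phi_hat,
    )
    res.t_bar = mean_path_length(res)
    return res


def solve(op: EvolutionOperator) -> FlowResult:
    """Dispatch to the solver matching the query's model."""
    return {
        "emitting": solve_emitting,
        "absorbing": solve_absorbing,
        "channel": solve_channel,
    }[op.query.model](op)


def mean_path_length(result: FlowResult) -> float:
    """Average number of steps before termination.

    t-bar = 1 + mean over sources of the row sums of H (emitting) or of
    Phi-hat (channel, where it is bounded below by the shortest
    source-to-sink hop count).
    """
    M = result.visit_matrix
    if M.shape[0] == 0:
        raise ValidationError("mean path length needs at least one source")
    return 1.0 + float(M.sum(axis=1).mean())


def mean_absorption(result: FlowResult, op: EvolutionOperator) -> float:
    """Mean total absorption probability r-bar.

    Averages sum_k F_ik over exactly those transient nodes with a directed
    path to at least one sink; nodes in components that cannot reach a sink
    are excluded from the average.
    """
    if result.F is None:
        raise ValidationError("mean absorption requires an absorbing result")
    reachable = _sink_reachable(op)
    mask = reachable[op.transient_idx]
    n_T = int(mask.sum())
    if n_T == 0:
        raise ValidationError("no transient node has a directed path to any sink")
    return float(result.F[mask].sum() / n_T)


def interference(result: FlowResult) -> dict[str, float]:
    """Per-node minimum of visit counts over all sources.

    Large only where *every* source sends substantial flow, so it highlights
    nodes jointly influenced by the whole context.
    """
    M = result.visit_matrix
    if M.shape[0] == 0:
        raise ValidationError("interference needs at least one source")
    mins = M.min(axis=0)
    return dict(zip(result.transient_nodes, mins.tolist()))
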