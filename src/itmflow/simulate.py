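"""Monte Carlo random-walk ensembles: the independent check on the algebra.

The linear solves give expectations in closed form; this module estimates the
same quantities by simulating walkers directly, step by step.  Each step a
walker (1) survives a dissipation trial with probability mu, (2) moves to a
neighbour chosen with probability proportional to edge weight, then (3) is
checked for termination — stepping onto an excluded node kills the walk, a
boundary node absorbs it.  A visit is counted on every arrival at a transient
node (repeat visits included); the starting node itself is never counted.

The ensemble is vectorised over walkers, so 10^5-walker runs on small graphs
take seconds.  A fixed seed gives bit-identical statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import NumericalError, ValidationError
from .graph import ModelQuery, WeightedDigraph, mark_excluded

logger = logging.getLogger(__name__)


@dataclass
class WalkEnsembleStats:
    """Empirical flow estimates from one simulated walker ensemble.

    ``visits`` aggregates mean visits per walker over all starts;
    ``H_hat``/``F_hat``/``phi_hat`` hold the per-start estimates matching the
    analytic H, F and Phi-hat, each with a standard-error companion.
    """

    visits: dict[str, float]
    terminations: dict[str, int]
    dissipated: int
    truncated: int
    n_walkers: int
    seed: int
    max_steps: int
    H_hat: dict[str, dict[str, float]] = field(default_factory=dict)
    H_se: dict[str, dict[str, float]] = field(default_factory=dict)
    F_hat: dict[str, dict[str, float]] = field(default_factory=dict)
    F_se: dict[str, dict[str, float]] = field(default_factory=dict)
    phi_hat: dict[str, dict[str, float]] = field(default_factory=dict)
    phi_se: dict[str, dict[str, float]] = field(default_factory=dict)


class _WalkEngine:
    """Vectorised stepping over a fixed graph/boundary configuration."""

    def __init__(self, graph: WeightedDigraph, boundary: set[str], mu: float):
        self.nodes = graph.nodes
        self.index = graph.index
        self.mu = mu
        n = graph.n_nodes
        W = graph.W.tocsr()
        deg = np.diff(W.indptr)
        self.maxdeg = int(deg.max()) if n else 0
        # padded neighbour table + row-wise cumulative move distribution
        self.nbr = np.zeros((n, max(self.maxdeg, 1)), dtype=np.int64)
        self.cum = np.ones((n, max(self.maxdeg, 1)))
        self.dangling = np.zeros(n, dtype=bool)
        for i in range(n):
            row = W.indices[W.indptr[i] : W.indptr[i + 1]]
            w = W.data[W.indptr[i] : W.indptr[i + 1]]
            if len(row) == 0:
                self.dangling[i] = True
                continue
            c = np.cumsum(w) / w.sum()
            self.nbr[i, : len(row)] = row
            self.cum[i, : len(row)] = c
            self.cum[i, len(row) :] = 1.0
        self.boundary = np.zeros(n, dtype=bool)
        for b in boundary:
            self.boundary[self.index[b]] = True
        self.excluded = np.zeros(n, dtype=bool)
        for x in graph.excluded:
            self.excluded[self.index[x]] = True

    def run(self, start: str, n: int, rng: np.random.Generator, max_steps: int):
        """Returns (visit counts per walker x node, termination node per walker).

        Termination code: node index if absorbed at a boundary node, -1 if
        dissipated (or killed at an excluded/dangling node), -2 if truncated.
        """
        n_nodes = len(self.nodes)
        visits = np.zeros((n, n_nodes), dtype=np.int32)
        term = np.full(n, -2, dtype=np.int64)
        cur = np.full(n, self.index[start], dtype=np.int64)
        alive = np.arange(n)
        for _ in range(max_steps):
            if alive.size == 0:
                break
            # (1) dissipation trial
            survive = rng.random(alive.size) < self.mu
            term[alive[~survive]] = -1
            alive = alive[survive]
            cur_a = cur[alive]
            if alive.size == 0:
                break
            # dangling nodes: nowhere to move, walk dies
            dang = self.dangling[cur_a]
            term[alive[dang]] = -1
            alive = alive[~dang]
            cur_a = cur_a[~dang]
            if alive.size == 0:
                break
            # (2) weight-proportional move
            u = rng.random(alive.size)
            choice = (u[:, None] > self.cum[cur_a]).sum(axis=1)
            nxt = self.nbr[cur_a, choice]
            cur[alive] = nxt
            # (3) termination checks at the arrival node
            killed = self.excluded[nxt]
            term[alive[killed]] = -1
            absorbed = self.boundary[nxt] & ~killed
            term[alive[absorbed]] = nxt[absorbed]
            transient = ~killed & ~absorbed
            visits[alive[transient], nxt[transient]] += 1
            alive = alive[transient]
        return visits, term


def _check_truncation(term: np.ndarray, max_steps: int) -> int:
    truncated = int((term == -2).sum())
    if truncated >= 0.001 * term.size and truncated > 0:
        raise NumericalError(
            f"{truncated}/{term.size} walks truncated at {max_steps} steps; "
            "increase max_steps"
        )
    return truncated


def simulate(
    graph: WeightedDigraph,
    query: ModelQuery,
    mu: float,
    n_walkers: int,
    seed: int = 0,
    max_steps: int = 10_000,
    starts: Optional[Sequence[str]] = None,
) -> WalkEnsembleStats:
    """Simulate a walker ensemble for the query and collect flow estimates.

    Emitting/channel: walkers are split equally over the sources (each start
    gets ``n_walkers // n_starts``).  Absorbing: walkers start at every
    transient node in turn (override with ``starts`` to probe specific
    origins).  Estimates: ``H_hat`` is the mean visit count per walker,
    ``F_hat`` the fraction of walks absorbed per sink, and ``phi_hat`` the
    mean visit count among sink-absorbed walks only — the conditional mean
    that the normalized channel model computes analytically.
    """
    if n_walkers < 1:
        raise ValidationError("n_walkers must be >= 1")
    if not (0.0 <= mu <= 1.0):
        raise ValidationError(f"mu={mu!r} outside [0, 1]")
    query.validate_against(graph)
    if query.excluded - graph.excluded:
        graph = mark_excluded(graph, query.excluded)

    if query.model == "absorbing":
        boundary = set(query.sinks)
    else:
        boundary = set(query.sources) | set(query.sinks)
    transient = [
        n for n in graph.nodes if n not in boundary and n not in graph.excluded
    ]
    if starts is None:
        starts = list(query.sources) if query.sources else transient
    if not starts:
        raise ValidationError("no start nodes for the simulation")
    per_start = max(1, n_walkers // len(starts))

    engine = _WalkEngine(graph, boundary, mu)
    rng = np.random.default_rng(seed)
    sink_idx = [graph.index[k] for k in query.sinks]

    agg_visits = np.zeros(graph.n_nodes)
    terminations: dict[str, int] = {}
    dissipated = truncated = total = 0
    stats = WalkEnsembleStats(
        visits={},
        terminations=terminations,
        dissipated=0,
        truncated=0,
        n_walkers=0,
        seed=seed,
        max_steps=max_steps,
    )
    for start in starts:
        visits, term = engine.run(start, per_start, rng, max_steps)
        truncated += _check_truncation(term, max_steps)
        total += per_start
        dissipated += int((term == -1).sum())
        for node_i in np.unique(term[term >= 0]):
            name = graph.nodes[node_i]
            terminations[name] = terminations.get(name, 0) + int(
                (term == node_i).sum()
            )
        agg_visits += visits.sum(axis=0)

        mean = visits.mean(axis=0)
        se = visits.std(axis=0, ddof=1) / np.sqrt(per_start)
        stats.H_hat[start] = {n: float(mean[graph.index[n]]) for n in transient}
        stats.H_se[start] = {n: float(se[graph.index[n]]) for n in transient}
        if sink_idx:
            absorbed = np.isin(term, sink_idx)
            frac = {}
            fse = {}
            for k_i, k in zip(sink_idx, query.sinks):
                p = float((term == k_i).mean())
                frac[k] = p
                fse[k] = float(np.sqrt(p * (1 - p) / per_start))
            stats.F_hat[start] = frac
            stats.F_se[start] = fse
            n_abs = int(absorbed.sum())
            if query.model == "channel" and n_abs > 1:
                v_abs = visits[absorbed]
                pm = v_abs.mean(axis=0)
                ps = v_abs.std(axis=0, ddof=1) / np.sqrt(n_abs)
                stats.phi_hat[start] = {
                    n: float(pm[graph.index[n]]) for n in transient
                }
                stats.phi_se[start] = {
                    n: float(ps[graph.index[n]]) for n in transient
                }

    stats.visits = {
        n: float(agg_visits[graph.index[n]] / total) for n in graph.nodes
    }
    stats.dissipated = dissipated
    stats.truncated = truncated
    stats.n_walkers = total
    return stats
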