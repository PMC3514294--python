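"""Weighted directed graphs built from typed edge lists.

Interaction networks usually arrive as a list of typed edges (protein A binds
protein B, kinase X phosphorylates substrate Y, ...).  The random-walk engine
needs a single nonnegatively weighted digraph, so this module handles the
translation: assigning a direction category to each interaction type,
resolving missing weights, collapsing parallel edges by summing weights per
direction, and marking *excluded* nodes whose outgoing flow is fully
dissipated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .errors import ValidationError

logger = logging.getLogger(__name__)

DIRECTED = "directed"
UNDIRECTED = "undirected"
IGNORED = "ignored"
_CATEGORIES = (DIRECTED, UNDIRECTED, IGNORED)


@dataclass(frozen=True)
class RawEdge:
    """A single typed edge as read from a SIF file or an edge table.

    ``weight`` may be ``None``, meaning "not specified"; how a missing weight
    is resolved depends on the weighting mode (see
    :func:`apply_default_weights`).
    """

    source: str
    target: str
    etype: str = ""
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError(
                f"edge endpoints must be nonempty strings, got "
                f"{self.source!r} -> {self.target!r}"
            )
        if self.weight is not None and self.weight < 0:
            raise ValidationError(
                f"negative weight {self.weight!r} on edge "
                f"{self.source!r} -[{self.etype}]-> {self.target!r}"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class EdgeTypePolicy:
    """Maps each interaction type to a direction category.

    Unlisted types default to *undirected* (bidirectional with equal weight),
    matching the common convention for physical-interaction edge types.
    """

    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for etype, cat in self.categories.items():
            if cat not in _CATEGORIES:
                raise ValidationError(
                    f"unknown category {cat!r} for edge type {etype!r}; "
                    f"expected one of {_CATEGORIES}"
                )

    @classmethod
    def from_lists(
        cls,
        directed: Sequence[str] = (),
        undirected: Sequence[str] = (),
        ignored: Sequence[str] = (),
    ) -> "EdgeTypePolicy":
        cats: dict[str, str] = {}
        for group, cat in ((directed, DIRECTED), (undirected, UNDIRECTED), (ignored, IGNORED)):
            for etype in group:
                if etype in cats and cats[etype] != cat:
                    raise ValidationError(
                        f"edge type {etype!r} assigned to both {cats[etype]!r} and {cat!r}"
                    )
                cats[etype] = cat
        return cls(cats)

    def category_of(self, etype: str) -> str:
        return self.categories.get(etype, UNDIRECTED)


@dataclass(frozen=True)
class WeightedDigraph:
    """The random-walk substrate: ordered nodes plus positive edge weights.

    Nodes are kept in lexicographic order so that matrices and output files
    are byte-reproducible.  ``excluded`` nodes have no outgoing weights, but
    incoming weights are retained: a walker may still step onto an excluded
    node (and die there), so neighbours' normalisation denominators keep
    counting the flow lost that way.
    """

    nodes: tuple[str, ...]
    W: sparse.csr_matrix
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.W.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("weight matrix shape does not match node count")
        if self.W.nnz and self.W.data.min() <= 0:
            raise ValidationError("all stored weights must be strictly positive")
        unknown = self.excluded - set(self.nodes)
        if unknown:
            raise ValidationError(f"excluded nodes not in graph: {sorted(unknown)}")

    @classmethod
    def from_weight_map(
        cls,
        weights: Mapping[tuple[str, str], float],
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedDigraph":
        """Build a graph from an ``(i, j) -> weight`` map; zero entries dropped."""
        nodes = sorted(set(extra_nodes) | {n for pair in weights for n in pair})
        index = {n: i for i, n in enumerate(nodes)}
        rows, cols, data = [], [], []
        for (u, v), w in weights.items():
            if w < 0:
                raise ValidationError(f"negative weight {w!r} on edge {u!r} -> {v!r}")
            if w > 0:
                rows.append(index[u])
                cols.append(index[v])
                data.append(float(w))
        W = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(nodes), len(nodes)), dtype=float
        )
        W.sum_duplicates()
        return cls(tuple(nodes), W)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        undirected: bool = False,
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedDigraph":
        weights: dict[tuple[str, str], float] = {}
        for u, v, w in edges:
            weights[(u, v)] = weights.get((u, v), 0.0) + w
            if undirected and u != v:
                weights[(v, u)] = weights.get((v, u), 0.0) + w
        return cls.from_weight_map(weights, extra_nodes=extra_nodes)

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, u: str, v: str) -> float:
        idx = self.index
        return float(self.W[idx[u], idx[v]])

    def out_weight(self, u: str) -> float:
        return float(self.W[self.index[u]].sum())

    def weight_map(self) -> dict[tuple[str, str], float]:
        coo = self.W.tocoo()
        return {
            (self.nodes[i], self.nodes[j]): w
            for i, j, w in zip(coo.row, coo.col, coo.data)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedDigraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.excluded == other.excluded
            and (self.W != other.W).nnz == 0
        )


@dataclass(frozen=True)
class ModelQuery:
    """A flow query: model kind plus boundary and excluded node sets."""

    model: str  # emitting | absorbing | channel
    sources: tuple[str, ...] = ()
    sinks: tuple[str, ...] = ()
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.model not in ("emitting", "absorbing", "channel"):
            raise ValidationError(
                f"unknown model {self.model!r}; expected emitting, absorbing or channel"
            )
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "sinks", tuple(self.sinks))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if set(self.sources) & set(self.sinks):
            raise ValidationError(
                f"sources and sinks overlap: {sorted(set(self.sources) & set(self.sinks))}"
            )
        overlap = self.excluded & (set(self.sources) | set(self.sinks))
        if overlap:
            raise ValidationError(
                f"excluded nodes overlap boundary nodes: {sorted(overlap)}"
            )
        if self.model in ("emitting", "channel") and not self.sources:
            raise ValidationError(f"the {self.model} model requires at least one source")
        if self.model in ("absorbing", "channel") and not self.sinks:
            raise ValidationError(f"the {self.model} model requires at least one sink")

    def validate_against(self, graph: WeightedDigraph) -> None:
        nodes = set(graph.nodes)
        for name, group in (
            ("source", self.sources),
            ("sink", self.sinks),
            ("excluded", self.excluded),
        ):
            missing = set(group) - nodes
            if missing:
                raise ValidationError(f"{name} nodes not in graph: {sorted(missing)}")


def apply_default_weights(
    raw_edges: Sequence[RawEdge], mode: str = "default"
) -> list[RawEdge]:
    """Resolve missing edge weights.

    ``mode='default'`` (no weight attribute in the input): every edge gets the
    default weight — 2 for a self-loop, 1 otherwise.  ``mode='attribute'``
    (weights come from an attribute column): a missing (null) value is treated
    as weight 0, so the edge drops out of the collapsed graph.
    """
    if mode not in ("default", "attribute"):
        raise ValidationError(f"unknown weighting mode {mode!r}")
    out = []
    for e in raw_edges:
        if mode == "default":
            out.append(replace(e, weight=2.0 if e.is_self_loop else 1.0))
        else:
            out.append(e if e.weight is not None else replace(e, weight=0.0))
    return out


def collapse_edges(
    raw_edges: Sequence[RawEdge], policy: Optional[EdgeTypePolicy] = None
) -> WeightedDigraph:
    """Collapse typed multi-edges into a single weighted digraph.

    Per ordered pair (i, j), the collapsed weight is the sum of all directed
    raw-edge weights i->j plus the weights of all undirected raw edges
    incident to {i, j} (an undirected edge contributes equally to both
    directions).  Ignored types contribute nothing; pairs summing to zero get
    no entry.  Nodes touched by any raw edge stay in the node set even if all
    of their edges collapse away.
    """
    policy = policy or EdgeTypePolicy()
    weights: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for e in raw_edges:
        nodes.add(e.source)
        nodes.add(e.target)
        if e.weight is None:
            raise ValidationError(
                f"unresolved weight on edge {e.source!r} -[{e.etype}]-> {e.target!r}; "
                "call apply_default_weights first"
            )
        if e.weight < 0:
            raise ValidationError(
                f"negative weight {e.weight!r} on edge "
                f"{e.source!r} -[{e.etype}]-> {e.target!r}"
            )
        cat = policy.category_of(e.etype)
        if cat == IGNORED:
            continue
        weights[(e.source, e.target)] = weights.get((e.source, e.target), 0.0) + e.weight
        if cat == UNDIRECTED and not e.is_self_loop:
            weights[(e.target, e.source)] = (
                weights.get((e.target, e.source), 0.0) + e.weight
            )
    return WeightedDigraph.from_weight_map(weights, extra_nodes=nodes)


def mark_excluded(graph: WeightedDigraph, excluded: Iterable[str]) -> WeightedDigraph:
    """Zero the outgoing weights of ``excluded`` nodes, keeping incoming ones.

    Any flow reaching an excluded node is fully dissipated: the node keeps its
    incoming entries (so neighbours still route probability into it) but loses
    all outgoing ones (a walker arriving there dies).  Excluded nodes are not
    deleted — deletion would silently redistribute their inflow to surviving
    neighbours instead of dissipating it.
    """
    excluded = frozenset(excluded)
    if not excluded:
        return graph
    unknown = excluded - set(graph.nodes)
    if unknown:
        raise ValidationError(f"excluded nodes not in graph: {sorted(unknown)}")
    mask_rows = np.array([n in excluded for n in graph.nodes])
    W = graph.W.tolil(copy=True)
    W[np.where(mask_rows)[0], :] = 0.0
    W = W.tocsr()
    W.eliminate_zeros()
    return WeightedDigraph(graph.nodes, W, excluded=graph.excluded | excluded)
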