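"""Reading query graphs and round-tripping results as tab-delimited text.

Two graph dialects are accepted: SIF lines (``source  etype  target...``,
tab- or space-delimited, no weights, hence default-weight mode) and a
TSV edge table with a header row (columns ``source``, ``target``, optional
``etype`` and a weight column).

Results are exported to a self-contained tab-delimited file: ``#``-prefixed
``key<TAB>value`` header lines record the full query (model, mu, criterion,
boundaries, summary statistics), followed by one row per node with a
per-boundary attribute column, totals, interference (emitting/channel) and a
hex colour.  The file plus the query graph suffice to restore a run; on
import, rows whose node id is absent from the target graph are skipped, and
unknown extra columns are preserved as custom ranking attributes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calibrate import DissipationCriterion
from .errors import ValidationError
from .graph import RawEdge, WeightedDigraph
from .rank import (
    RankedSelection,
    SelectionCriterion,
    hex_to_rgb,
    rgb_to_hex,
)
from .solver import MODEL_CODES, FlowResult, interference

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_LABEL_RE = re.compile(r"^ITM([EAC])(\d+)\[(.+)\]$")
_RUNID_FILE = ".itmflow_runid"


@dataclass(frozen=True)
class ItmLabel:
    """Column label for one boundary attribute, e.g. ``ITME243[S1]``."""

    model_code: str  # E | A | C
    run_id: int
    boundary_tag: str

    def __post_init__(self) -> None:
        if self.model_code not in ("E", "A", "C"):
            raise ValidationError(f"unknown model code {self.model_code!r}")
        if self.run_id < 1:
            raise ValidationError("run id must be a positive integer")

    def render(self) -> str:
        return f"ITM{self.model_code}{self.run_id}[{self.boundary_tag}]"

    @classmethod
    def parse(cls, text: str) -> "ItmLabel":
        m = _LABEL_RE.match(text)
        if not m:
            raise ValidationError(f"not an ITM attribute label: {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))


def next_run_id(directory: PathLike) -> int:
    """Monotonically increasing run id, persisted in a sidecar counter file."""
    path = Path(directory) / _RUNID_FILE
    current = 0
    if path.exists():
        try:
            current = int(path.read_text().strip())
        except ValueError:
            current = 0
    path.write_text(f"{current + 1}\n")
    return current + 1


# ---------------------------------------------------------------- graph input


def read_sif(path: PathLike) -> list[RawEdge]:
    """Parse a SIF file into raw edges (weights unset: default-weight mode).

    Lines are ``source etype target [target2 ...]``; a line containing a tab
    is split on tabs, otherwise on whitespace.  Lines with a bare node id
    declare an isolated node and yield no edge.
    """
    edges: list[RawEdge] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) == 1:
            continue  # isolated node declaration
        if len(fields) == 2:
            raise ValidationError(
                f"{path}:{lineno}: SIF line needs source, type and target"
            )
        src, etype, targets = fields[0], fields[1], fields[2:]
        edges.extend(RawEdge(src, tgt, etype) for tgt in targets)
    return edges


def read_edge_table(
    path: PathLike, weight_column: Optional[str] = None
) -> list[RawEdge]:
    """Parse a TSV edge table (header row; ``#`` comment lines skipped).

    Requires ``source`` and ``target`` columns; ``etype`` is optional.  If
    ``weight_column`` is given, that column supplies weights and empty cells
    become unset (null) weights; otherwise all weights stay unset
    (default-weight mode).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValidationError(f"edge table {path} lacks required column {col!r}")
    if weight_column is not None and weight_column not in df.columns:
        raise ValidationError(f"edge table {path} lacks weight column {weight_column!r}")
    edges = []
    for row in df.itertuples(index=False):
        etype = getattr(row, "etype", "") if "etype" in df.columns else ""
        weight: Optional[float] = None
        if weight_column is not None:
            cell = getattr(row, weight_column)
            if cell is not None and not (isinstance(cell, float) and np.isnan(cell)):
                cell = str(cell).strip()
                if cell:
                    weight = float(cell)
        edges.append(
            RawEdge(str(row.source), str(row.target), str(etype or ""), weight)
        )
    return edges


def read_graph_file(
    path: PathLike, weight_column: Optional[str] = None
) -> tuple[list[RawEdge], str]:
    """Dispatch on extension; returns (edges, weighting mode)."""
    p = Path(path)
    if p.suffix.lower() == ".sif":
        if weight_column is not None:
            raise ValidationError("SIF files carry no weights; omit the weight column")
        return read_sif(p), "default"
    edges = read_edge_table(p, weight_column)
    return edges, ("attribute" if weight_column is not None else "default")


# ------------------------------------------------------------- results output


def _fmt(x: float) -> str:
    return repr(float(x))


def _boundary_columns(result: FlowResult) -> tuple[tuple[str, ...], np.ndarray]:
    """(tags, matrix) with one column per boundary node, rows = transient nodes."""
    if result.model == "absorbing":
        assert result.F is not None
        return result.sinks, result.F
    return result.sources, result.visit_matrix.T


def write_results_tsv(
    result: FlowResult,
    selection: RankedSelection,
    path: PathLike,
    criterion: Optional[DissipationCriterion] = None,
    run_id: Optional[int] = None,
    excluded: tuple[str, ...] = (),
) -> None:
    """Export a completed run; the file alone (plus the graph) restores it.

    Rows cover every node with any nonzero value, at full precision, ordered
    by descending total with ties broken by node id.
    """
    path = Path(path)
    if run_id is None:
        run_id = next_run_id(path.parent if str(path.parent) else ".")
    tags, M = _boundary_columns(result)
    code = MODEL_CODES[result.model]
    labels = [ItmLabel(code, run_id, t).render() for t in tags]
    nodes = result.transient_nodes
    total = M.sum(axis=1)
    inter = None
    if result.model in ("emitting", "channel"):
        inter_map = interference(result)
        inter = np.array([inter_map[n] for n in nodes])

    lines = []
    lines.append(f"#model\t{result.model}")
    lines.append(f"#mu\t{_fmt(result.mu)}")
    if criterion is not None:
        lines.append(f"#criterion_kind\t{criterion.kind}")
        lines.append(f"#criterion_value\t{_fmt(criterion.value)}")
    lines.append(f"#sources\t{','.join(result.sources)}")
    lines.append(f"#sinks\t{','.join(result.sinks)}")
    lines.append(f"#excluded\t{','.join(sorted(excluded))}")
    if result.t_bar is not None:
        lines.append(f"#t_bar\t{_fmt(result.t_bar)}")
    if result.r_bar is not None:
        lines.append(f"#r_bar\t{_fmt(result.r_bar)}")

    header = ["node_id"] + labels + ["total"]
    if inter is not None:
        header.append("interference")
    custom_names = sorted(result.custom)
    header += custom_names
    header.append("color")
    lines.append("\t".join(header))

    keep = [i for i in range(len(nodes)) if np.any(M[i] != 0.0)]
    order = sorted(keep, key=lambda i: (-total[i], nodes[i]))
    for i in order:
        row = [nodes[i]] + [_fmt(x) for x in M[i]] + [_fmt(total[i])]
        if inter is not None:
            row.append(_fmt(inter[i]))
        for name in custom_names:
            row.append(_fmt(result.custom[name].get(nodes[i], 0.0)))
        rgb = selection.colors.get(nodes[i], (1.0, 1.0, 1.0))
        row.append(rgb_to_hex(rgb))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_results_tsv(
    path: PathLike, graph: Optional[WeightedDigraph] = None
) -> tuple[FlowResult, RankedSelection]:
    """Restore a run from its exported file.

    Rows whose node id is absent from ``graph`` (when given) are skipped and
    the skip count is logged.  Unknown extra columns come back as custom
    ranking attributes on the result.
    """
    text = Path(path).read_text(encoding="utf-8").splitlines()
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    for lineno, line in enumerate(text, 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if header is not None:
                continue  # trailing comments
            parts = line[1:].split("\t", 1)
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: malformed header line {line!r}"
                )
            meta[parts[0].strip()] = parts[1].strip()
            continue
        fields = line.split("\t")
        if header is None:
            if fields[0] != "node_id":
                raise ValidationError(
                    f"{path}:{lineno}: expected column header starting with node_id"
                )
            header = fields
            continue
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{lineno}: row has {len(fields)} fields, expected {len(header)}"
            )
        rows.append(fields)
    if header is None:
        raise ValidationError(f"{path}: no column header found")
    for key in ("model", "mu"):
        if key not in meta:
            raise ValidationError(f"{path}: missing required header #{key}")
    model = meta["model"]
    if model not in MODEL_CODES:
        raise ValidationError(f"{path}: unknown model {model!r} in header")

    boundary_cols: list[tuple[int, str]] = []
    custom_cols: list[tuple[int, str]] = []
    total_col = inter_col = color_col = None
    for ci, name in enumerate(header[1:], 1):
        m = _LABEL_RE.match(name)
        if m:
            boundary_cols.append((ci, m.group(3)))
        elif name == "total":
            total_col = ci
        elif name == "interference":
            inter_col = ci
        elif name == "color":
            color_col = ci
        else:
            custom_cols.append((ci, name))

    known = set(graph.nodes) if graph is not None else None
    kept, skipped = [], 0
    for fields in rows:
        if known is not None and fields[0] not in known:
            skipped += 1
            continue
        kept.append(fields)
    if skipped:
        logger.info("skipped %d rows with node ids absent from the graph", skipped)

    node_order = [f[0] for f in kept]
    transient = tuple(sorted(node_order))
    pos = {n: i for i, n in enumerate(transient)}
    tags = tuple(t for _, t in boundary_cols)
    M = np.zeros((len(transient), len(tags)))
    for fields in kept:
        i = pos[fields[0]]
        for c, (ci, _) in enumerate(boundary_cols):
            M[i, c] = float(fields[ci])

    sources = tuple(s for s in meta.get("sources", "").split(",") if s)
    sinks = tuple(s for s in meta.get("sinks", "").split(",") if s)
    result = FlowResult(
        model=model,
        mu=float(meta["mu"]),
        sources=sources or (tags if model != "absorbing" else ()),
        sinks=sinks or (tags if model == "absorbing" else ()),
        transient_nodes=transient,
        t_bar=float(meta["t_bar"]) if "t_bar" in meta else None,
        r_bar=float(meta["r_bar"]) if "r_bar" in meta else None,
    )
    if model == "absorbing":
        result.F = M
    elif model == "emitting":
        result.H = M.T
    else:
        result.Phi_hat = M.T
        result.H = M.T  # best available restoration; raw H is not exported
    for ci, name in custom_cols:
        result.custom[name] = {f[0]: float(f[ci]) for f in kept}

    totals = {
        f[0]: (float(f[total_col]) if total_col is not None else M[pos[f[0]]].sum())
        for f in kept
    }
    colors = {}
    if color_col is not None:
        colors = {f[0]: hex_to_rgb(f[color_col]) for f in kept}
    selection = RankedSelection(
        ranking_attribute="total",
        values=totals,
        criterion=SelectionCriterion("cutoff", float("-inf")),
        selected=[f[0] for f in kept],
        colors=colors,
    )
    return result, selection
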