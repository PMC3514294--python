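"""Ranking, selection and colouring of significant nodes.

A completed flow run assigns every transient node one value per boundary
node.  To turn that into an information transduction module (ITM) the user
picks a *ranking attribute* (a per-source/per-sink column, the total, the
interference, or an imported custom column), a *selection criterion* (top-k,
strict cutoff, or the participation ratio) and a colour scheme (subtractive
CMY mixing of up to three attribute columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .solver import FlowResult, interference

#: sequential single-hue 8-bin map for single-attribute displays
#: (a cyan ramp, light to dark); users may substitute any hex list.
SEQUENTIAL_PALETTE_8 = (
    "#f7fcff", "#d8eef7", "#b9e0ef", "#93cfe4",
    "#68b8d7", "#3f9fc6", "#2180ac", "#0b608c",
)

_SCALINGS = {
    "linear": lambda v: v,
    "sqrt": np.sqrt,
    "log": np.log1p,
}


@dataclass
class SelectionCriterion:
    """top_k (k >= 1), cutoff (strict >), or participation_ratio."""

    kind: str
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("top_k", "cutoff", "participation_ratio"):
            raise ValidationError(f"unknown selection criterion {self.kind!r}")
        if self.kind == "top_k":
            if self.value is None or int(self.value) < 1:
                raise ValidationError("top_k requires an integer k >= 1")
            self.value = int(self.value)
        if self.kind == "cutoff" and self.value is None:
            raise ValidationError("cutoff requires a threshold value")


@dataclass
class RankedSelection:
    """A ranked node list with its criterion and display metadata."""

    ranking_attribute: str
    values: dict[str, float]
    criterion: SelectionCriterion
    selected: list[str]
    colors: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def ranking_values(result: FlowResult, choice: str) -> dict[str, float]:
    """One value per transient node for the requested ranking attribute.

    For emitting/channel results the valid choices are a source id, 'total'
    (sum over sources) or 'interference' (min over sources); for absorbing
    results a sink id or 'total' (sum over sinks).  Keys of
    ``result.custom`` (imported columns) are accepted for any model and pass
    through unchanged.
    """
    if choice in result.custom:
        return dict(result.custom[choice])
    nodes = result.transient_nodes
    if result.model in ("emitting", "channel"):
        M = result.visit_matrix
        if choice == "total":
            return dict(zip(nodes, M.sum(axis=0).tolist()))
        if choice == "interference":
            return interference(result)
        if choice in result.sources:
            return dict(zip(nodes, M[result.sources.index(choice)].tolist()))
        valid = list(result.sources) + ["total", "interference"]
    else:
        assert result.F is not None
        if choice == "total":
            return dict(zip(nodes, result.F.sum(axis=1).tolist()))
        if choice in result.sinks:
            return dict(zip(nodes, result.F[:, result.sinks.index(choice)].tolist()))
        valid = list(result.sinks) + ["total"]
    valid += sorted(result.custom)
    raise ValidationError(f"unknown ranking attribute {choice!r}; valid: {valid}")


def participation_ratio(values: Mapping[str, float]) -> int:
    """Scale-invariant effective count of significant values.

    PR = (sum v)^2 / (sum v^2), rounded to the nearest integer.  Uniform
    values over n nodes give n; a single spike gives 1.  Multiplying all
    values by a positive constant leaves PR unchanged, which is what makes
    the resulting node count scale-independent.
    """
    v = np.asarray(list(values.values()), dtype=float)
    if v.size == 0 or (v < 0).any():
        raise ValidationError("participation ratio needs nonnegative values")
    ss = float((v * v).sum())
    if ss == 0.0:
        raise ValidationError("participation ratio undefined for all-zero values")
    pr = float(v.sum()) ** 2 / ss
    return int(math.floor(pr + 0.5))


def _ranked(values: Mapping[str, float]) -> list[tuple[str, float]]:
    # descending value, ties broken by node id ascending
    return sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))


def select_nodes(
    values: Mapping[str, float],
    criterion: SelectionCriterion,
    ranking_attribute: str = "values",
) -> RankedSelection:
    """Apply the selection criterion and return the ordered significant set."""
    ranked = _ranked(values)
    if criterion.kind == "cutoff":
        selected = [n for n, v in ranked if v > criterion.value]
    else:
        if criterion.kind == "top_k":
            k = int(criterion.value)  # type: ignore[arg-type]
        else:
            k = participation_ratio(values)
        positive = [n for n, v in ranked if v > 0]
        selected = positive[: min(k, len(positive))]
    return RankedSelection(
        ranking_attribute=ranking_attribute,
        values=dict(values),
        criterion=criterion,
        selected=selected,
    )


def mix_colors(
    attr_columns: Sequence[Mapping[str, float]],
    scaling: str = "sqrt",
) -> dict[str, tuple[float, float, float]]:
    """Subtractive CMY mixing of up to three attribute columns.

    Each column is scaled to [0, 1] by s(v)/s(v_max) — s linear, sqrt or
    log1p — and assigned cyan, magenta, yellow in order; the node colour is
    RGB = (1 - c, 1 - m, 1 - y).  A node with no flow stays white; a node
    dominated by one column takes that column's hue.  With a single column
    the same machinery yields a sequential single-hue (cyan) ramp.
    """
    if not 1 <= len(attr_columns) <= 3:
        raise ValidationError("colour mixing accepts between one and three attributes")
    if scaling not in _SCALINGS:
        raise ValidationError(f"unknown scaling {scaling!r}; valid: {sorted(_SCALINGS)}")
    s = _SCALINGS[scaling]
    nodes = sorted({n for col in attr_columns for n in col})
    cmy = np.zeros((len(nodes), 3))
    for c, col in enumerate(attr_columns):
        vals = np.array([max(0.0, col.get(n, 0.0)) for n in nodes])
        if (vals < 0).any():
            raise ValidationError("colour attributes must be nonnegative")
        vmax = vals.max() if vals.size else 0.0
        if vmax > 0:
            cmy[:, c] = np.asarray(s(vals)) / float(s(np.array(vmax)))
    rgb = 1.0 - cmy
    return {n: tuple(rgb[i].tolist()) for i, n in enumerate(nodes)}


def rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    r, g, b = (int(round(255 * max(0.0, min(1.0, x)))) for x in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def hex_to_rgb(code: str) -> tuple[float, float, float]:
    code = code.lstrip("#")
    if len(code) != 6:
        raise ValidationError(f"malformed hex colour {code!r}")
    return tuple(int(code[i : i + 2], 16) / 255.0 for i in (0, 2, 4))  # type: ignore[return-value]
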