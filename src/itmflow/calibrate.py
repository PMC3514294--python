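"""Calibrating the damping factor from a target summary statistic.

Users often find it easier to say "let walks take about five steps" or "let
40% of walks reach a sink" than to pick mu directly.  Both the mean path
length t-bar(mu) (emitting/channel) and the mean absorption probability
r-bar(mu) (absorbing) are monotone increasing in mu, so the target is a root
of a monotone scalar function on (0, 1).  We find it with a safeguarded
Newton iteration: the derivative comes from a central finite difference
(each statistic evaluation is one sparse solve), and any Newton step that
would leave the maintained bracket is replaced by bisection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .errors import NumericalError, ValidationError
from .graph import ModelQuery, WeightedDigraph
from .solver import (
    build_evolution_operator,
    shortest_boundary_path,
    solve_absorbing,
    solve_channel,
    solve_emitting,
)

logger = logging.getLogger(__name__)

#: kinds of dissipation criterion and the models they apply to
_KINDS = {
    "direct_mu": ("emitting", "absorbing", "channel"),
    "path_deviation_abs": ("emitting", "channel"),
    "path_deviation_rel": ("emitting", "channel"),
    "absorption_prob": ("absorbing",),
}

_LO, _HI = 1e-6, 1.0 - 1e-6
_MAX_ITER = 100


@dataclass(frozen=True)
class DissipationCriterion:
    """How the damping factor is determined.

    kind:
      * ``direct_mu`` — value is mu itself, in [0, 1];
      * ``path_deviation_abs`` — target t-bar = L_sp + value (steps >= 0);
      * ``path_deviation_rel`` — target t-bar = L_sp * (1 + value);
      * ``absorption_prob`` — target r-bar = value, in (0, 1].

    L_sp is the shortest source-to-sink hop count for the channel model; for
    the emitting model, which has no sinks, the deviation is interpreted
    against the minimal one-step walk (L_sp = 1).
    """

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(
                f"unknown criterion kind {self.kind!r}; expected one of {sorted(_KINDS)}"
            )
        v = self.value
        if self.kind == "direct_mu" and not (0.0 <= v <= 1.0):
            raise ValidationError(f"mu={v!r} outside [0, 1]")
        if self.kind in ("path_deviation_abs", "path_deviation_rel") and v < 0:
            raise ValidationError(f"path deviation must be >= 0, got {v!r}")
        if self.kind == "absorption_prob" and not (0.0 < v <= 1.0):
            raise ValidationError(f"absorption probability must be in (0, 1], got {v!r}")

    def check_model(self, model: str) -> None:
        if model not in _KINDS[self.kind]:
            raise ValidationError(
                f"criterion {self.kind!r} is not valid for the {model} model "
                f"(valid for: {_KINDS[self.kind]})"
            )


def _statistic(graph: WeightedDigraph, query: ModelQuery, mu: float) -> float:
    op = build_evolution_operator(graph, mu, query)
    if query.model == "emitting":
        return solve_emitting(op).t_bar  # type: ignore[return-value]
    if query.model == "channel":
        return solve_channel(op).t_bar  # type: ignore[return-value]
    return solve_absorbing(op).r_bar  # type: ignore[return-value]


def _target_value(
    graph: WeightedDigraph, query: ModelQuery, criterion: DissipationCriterion
) -> float:
    if criterion.kind == "absorption_prob":
        return criterion.value
    if query.model == "channel":
        L_sp = shortest_boundary_path(build_evolution_operator(graph, 0.5, query))
    else:
        L_sp = 1.0  # deviation measured against the minimal one-step walk
    if criterion.kind == "path_deviation_abs":
        return L_sp + criterion.value
    return L_sp * (1.0 + criterion.value)


def resolve_mu(
    graph: WeightedDigraph,
    query: ModelQuery,
    criterion: DissipationCriterion,
    tol: float = 1e-8,
) -> float:
    """Return the damping factor matching the criterion.

    For ``direct_mu`` this is the value itself; otherwise a safeguarded
    Newton search on (0, 1) for mu with |statistic(mu) - target| <
    tol * max(1, target).  The statistic is assumed monotone increasing in
    mu, which is verified through the initial bracket f(lo) <= target <=
    f(hi); a target outside that range raises an error reporting the
    achievable interval.  If the statistic is constant in mu (e.g. the
    channel model on a single-path graph) the bracket midpoint is returned
    with a warning.
    """
    criterion.check_model(query.model)
    if criterion.kind == "direct_mu":
        return criterion.value

    target = _target_value(graph, query, criterion)
    f = lambda mu: _statistic(graph, query, mu)

    lo, hi = _LO, _HI
    f_lo, f_hi = f(lo), f(hi)
    atol = tol * max(1.0, abs(target))
    if abs(f_hi - f_lo) < 1e-9 * max(1.0, abs(f_hi)):
        # degenerate: statistic does not depend on mu
        if abs(f_lo - target) <= max(atol, 1e-6 * max(1.0, abs(target))):
            warnings.warn(
                "statistic is constant in mu and already matches the target; "
                "returning the bracket midpoint"
            )
            return 0.5 * (lo + hi)
        raise ValidationError(
            f"target {target:g} unreachable: statistic is constant at {f_lo:g}"
        )
    if not (f_lo - atol <= target <= f_hi + atol):
        raise ValidationError(
            f"target {target:g} outside the achievable range "
            f"[{f_lo:g}, {f_hi:g}] for mu in ({_LO:g}, {_HI:g})"
        )

    mu = 0.5 * (lo + hi)
    f_mu = f(mu)
    for _ in range(_MAX_ITER):
        if abs(f_mu - target) < atol:
            return mu
        # maintain the bracket using monotonicity
        if f_mu < target:
            lo = mu
        else:
            hi = mu
        h = min(1e-6, 0.5 * (hi - lo))
        d = (f(min(mu + h, _HI)) - f(max(mu - h, _LO))) / (
            min(mu + h, _HI) - max(mu - h, _LO)
        )
        if d > 0:
            step = (target - f_mu) / d
            candidate = mu + step
        else:
            candidate = None
        if candidate is None or not (lo < candidate < hi):
            candidate = 0.5 * (lo + hi)  # bisection fallback
        mu = candidate
        f_mu = f(mu)
    raise NumericalError(
        f"damping-factor search did not converge in {_MAX_ITER} iterations "
        f"(last mu={mu:g}, statistic={f_mu:g}, target={target:g})"
    )
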