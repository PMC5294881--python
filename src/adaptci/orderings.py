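"""Sample-space orderings and their confidence sets.

Six ways to order the terminal outcomes of an adaptive two-stage trial,
each inducing a confidence set ``Omega_phi(point)`` ("at least as extreme
as observed") that is fed to the Clopper-Pearson inversion:

* ``RR`` — the response-rate partial order: ``Omega_RR`` is the tail area
  ``Theta``.  Two continuation points are comparable only when one lies in
  the other's tail, so this ordering is partial and its limits are not
  exact.
* ``PV`` — total order by the exact p-value of each point at ``pi0``
  (sum of null probabilities over its tail area).
* ``RR-A`` — two-step ordering: order the space by the (non-exact) RR
  lower limits themselves.
* ``RR-B`` — order by the overall average response rate
  ``(X1+X2)/(n1+n2(X1))`` (the MLE ordering for binary outcomes).
* ``RR-LR`` — likelihood-ratio style: average rate times ``sqrt(n2(X1))``.
* ``RR-Score`` — score style: average rate times ``n2(X1)``.

Stage-1 stops are ordered the same way under every approach: futility
stops come first (by response count), then all continuation points, then
efficacy stops; their confidence sets are marginal stage-1 tails.  Ties
are always kept inside ``Omega`` — dropping a tied point would break the
coverage guarantee of the inversion.

Rate-based comparisons use exact rational arithmetic (for ``RR-LR`` the
squared statistic ``rate^2 * n2`` is compared, which preserves the order
of the non-negative statistic) so tied metrics are recognised exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import limits as _limits
from .sample_space import G1, G2, G3, SamplePoint, SampleSpace, tail_set

__all__ = [
    "p_value",
    "omega_rr",
    "omega_pv",
    "metric",
    "omega_metric",
    "omega_rra",
    "OrderedSpace",
    "ordered_space",
    "METRIC_ORDERINGS",
]

METRIC_ORDERINGS = ("RR-B", "RR-LR", "RR-Score")

_PV_TIE_TOL = 1e-12
_RRA_TIE_TOL = 1e-10


def p_value(space: SampleSpace, point: SamplePoint, pi0: float | None = None) -> float:
    """Exact p-value of a terminal outcome: null probability of its tail area.

    For continuation points this is the sum of
    ``b(x1'; n1, pi0) * b(x2'; n2(x1'), pi0)`` over the tail area
    ``Theta``; for stage-1 stops it reduces to the marginal binomial tail
    ``P(X1' >= x1 | n1, pi0)`` (futility) or its efficacy-set restriction.
    """
    if pi0 is None:
        pi0 = space.design.pi0
    if not (0.0 < pi0 < 1.0):
        raise ValueError(f"pi0 must be in (0, 1), got {pi0}")
    return _limits.omega_probability(space, tail_set(space, point), pi0)


def omega_rr(space: SampleSpace, point: SamplePoint) -> frozenset[SamplePoint]:
    """RR confidence set: exactly the tail area of the point."""
    return tail_set(space, point)


def omega_pv(
    space: SampleSpace, point: SamplePoint, pi0: float | None = None
) -> frozenset[SamplePoint]:
    """PV confidence set: every point with p-value <= the observed one (ties in)."""
    ref = p_value(space, point, pi0)
    return frozenset(
        q for q in space.points if p_value(space, q, pi0) <= ref + _PV_TIE_TOL
    )


def _metric_key(space: SampleSpace, point: SamplePoint, which: str) -> Fraction:
    """Exact comparison key for a continuation point (monotone in the metric)."""
    n1 = space.design.n1
    n2 = space.design.n2[point.x1]
    k = point.x1 + point.x2
    m = n1 + n2
    if which == "RR-B":
        return Fraction(k, m)
    if which == "RR-LR":
        return Fraction(k * k * n2, m * m)  # (rate * sqrt(n2))^2, order-preserving
    if which == "RR-Score":
        return Fraction(k * n2, m)
    raise ValueError(f"unknown metric ordering {which!r}")


def metric(space: SampleSpace, point: SamplePoint, which: str) -> float:
    """Ordering statistic of a continuation point, as a float.

    RR-B: overall average response rate; RR-LR: rate * sqrt(n2(X1));
    RR-Score: rate * n2(X1).
    """
    if point.group != G2:
        raise ValueError(f"metric is defined for continuation points only, got {point}")
    n2 = space.design.n2[point.x1]
    rate = (point.x1 + point.x2) / (space.design.n1 + n2)
    if which == "RR-B":
        return rate
    if which == "RR-LR":
        return rate * math.sqrt(n2)
    if which == "RR-Score":
        return rate * n2
    raise ValueError(f"unknown metric ordering {which!r}")


def omega_metric(
    space: SampleSpace, point: SamplePoint, which: str
) -> frozenset[SamplePoint]:
    """Confidence set under a metric total order.

    Futility stops rank below every continuation point, which ranks below
    every efficacy stop; within the stage-1 groups points are ordered by
    response count, within the continuation group by the metric (ties in).
    """
    if point.group == G1:
        return frozenset(
            [q for q in space.g1 if q.x1 >= point.x1] + space.g2 + space.g3
        )
    if point.group == G3:
        return frozenset(q for q in space.g3 if q.x1 >= point.x1)
    ref = _metric_key(space, point, which)
    members = [q for q in space.g2 if _metric_key(space, q, which) >= ref]
    return frozenset(members + space.g3)


def _rr_limits(space: SampleSpace, alpha: float) -> dict[SamplePoint, float]:
    return {
        p: _limits.lower_limit(space, tail_set(space, p), alpha) for p in space.points
    }


def omega_rra(
    space: SampleSpace, point: SamplePoint, alpha: float
) -> frozenset[SamplePoint]:
    """Two-step RR-A confidence set.

    First compute the (non-exact) RR lower limit of every point, then use
    those limits as a total ordering: the confidence set of a point is
    every point whose RR limit is at least as large (ties, compared at a
    small float tolerance, included).
    """
    lims = _rr_limits(space, alpha)
    ref = lims[point]
    return frozenset(q for q in space.points if lims[q] >= ref - _RRA_TIE_TOL)


@dataclass(frozen=True)
class OrderedSpace:
    """Per-point ordering metric and confidence sets for one approach."""

    name: str
    space: SampleSpace
    metrics: Mapping[SamplePoint, Optional[float]]
    omegas: Mapping[SamplePoint, frozenset[SamplePoint]]

    def omega(self, point: SamplePoint) -> frozenset[SamplePoint]:
        return self.omegas[point]

    def to_frame(self) -> pd.DataFrame:
        pts = self.space.points
        sizes = {p: len(self.omegas[p]) for p in pts}
        # rank 1 = most extreme (smallest confidence set)
        order = sorted(pts, key=lambda p: sizes[p])
        ranks: dict[SamplePoint, int] = {}
        rank = 0
        prev = None
        for p in order:
            if sizes[p] != prev:
                rank += 1
                prev = sizes[p]
            ranks[p] = rank
        return pd.DataFrame(
            {
                "x1": [p.x1 for p in pts],
                "x2": [p.x2 for p in pts],
                "group": [p.group for p in pts],
                "ordering": self.name,
                "metric": [self.metrics[p] for p in pts],
                "rank": [ranks[p] for p in pts],
                "omega_size": [sizes[p] for p in pts],
            }
        ).astype({"x2": "Int64"})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ordered_space(
    space: SampleSpace,
    name: str,
    alpha: float | None = None,
    pi0: float | None = None,
) -> OrderedSpace:
    """Build the per-point confidence sets for one ordering approach.

    ``alpha`` is needed for RR-A (defaults to the design's alpha); ``pi0``
    for PV (defaults to the design's pi0).
    """
    if name not in _limits.ORDERING_NAMES:
        raise ValueError(
            f"unknown ordering {name!r}; expected one of {_limits.ORDERING_NAMES}"
        )
    pts = space.points
    metrics: dict[SamplePoint, Optional[float]] = {p: None for p in pts}
    omegas: dict[SamplePoint, frozenset[SamplePoint]] = {}
    if name == "RR":
        for p in pts:
            omegas[p] = tail_set(space, p)
    elif name == "PV":
        pv = {p: p_value(space, p, pi0) for p in pts}
        metrics.update(pv)
        for p in pts:
            omegas[p] = frozenset(
                q for q in pts if pv[q] <= pv[p] + _PV_TIE_TOL
            )
    elif name == "RR-A":
        a = space.design.alpha if alpha is None else alpha
        lims = _rr_limits(space, a)
        metrics.update(lims)
        for p in pts:
            omegas[p] = frozenset(
                q for q in pts if lims[q] >= lims[p] - _RRA_TIE_TOL
            )
    else:
        for p in pts:
            omegas[p] = omega_metric(space, p, name)
            if p.group == G2:
                metrics[p] = metric(space, p, name)
    return OrderedSpace(name=name, space=space, metrics=metrics, omegas=omegas)
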