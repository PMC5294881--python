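"""Terminal sample space of an adaptive two-stage trial.

The terminal outcomes partition into three complementary groups:

* ``G1`` — stage-1 futility stops, ``X1 <= r1(f)``, no ``X2``;
* ``G2`` — trials that continue, points ``(X1, X2)`` with
  ``r1(f) < X1 < r1(e)`` and ``0 <= X2 <= n2(X1)``;
* ``G3`` — stage-1 efficacy stops, ``X1 >= r1(e)``, no ``X2``.

A stage-1 stop carries no second-stage count: ``x2`` is ``None``, which is
distinct from a continuation point with ``X2 = 0``.

The response-rate tail area ``Theta(X1, X2)`` of a continuation point is
all of ``G3`` together with the continuation points whose stage-1 rate and
combined rate are both at least the observed ones.  It induces the partial
order behind both the RR ordering and the p-value computation.  All rate
comparisons are done by exact integer cross-multiplication so that tied
rates are decided exactly (ties belong to the tail).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.special import comb

from .design_core import AdaptiveDesign, validate_design

__all__ = [
    "SamplePoint",
    "SampleSpace",
    "enumerate_space",
    "point_probability",
    "tail_set",
    "G1",
    "G2",
    "G3",
]

G1 = "G1"
G2 = "G2"
G3 = "G3"


@dataclass(frozen=True)
class SamplePoint:
    """One terminal outcome: ``x2`` is ``None`` for stage-1 stops."""

    x1: int
    x2: Optional[int]
    group: str

    def __repr__(self) -> str:  # compact: (x1,-) or (x1,x2)
        tail = "-" if self.x2 is None else self.x2
        return f"({self.x1},{tail}){self.group[-1]}"


class SampleSpace:
    """Enumerated sample space with cached probability machinery.

    Points are stored in canonical order: ``G1`` by ``x1``, then ``G2``
    lexicographically by ``(x1, x2)``, then ``G3`` by ``x1``.  Each point's
    probability at rate ``pi`` is ``coef * pi**k * (1-pi)**(m-k)`` with
    ``k`` total responses and ``m`` total trials on that stopping path,
    which vectorises across the whole space.
    """

    def __init__(self, design: AdaptiveDesign, points: list[SamplePoint]):
        self.design = design
        self.points = points
        self.index = {p: i for i, p in enumerate(points)}
        n1 = design.n1
        coefs, ks, ms = [], [], []
        for p in points:
            if p.x2 is None:
                coefs.append(comb(n1, p.x1, exact=True))
                ks.append(p.x1)
                ms.append(n1)
            else:
                n2 = design.n2[p.x1]
                coefs.append(comb(n1, p.x1, exact=True) * comb(n2, p.x2, exact=True))
                ks.append(p.x1 + p.x2)
                ms.append(n1 + n2)
        self._coef = np.asarray(coefs, dtype=float)
        self._k = np.asarray(ks, dtype=float)
        self._m = np.asarray(ms, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @cached_property
    def g1(self) -> list[SamplePoint]:
        return [p for p in self.points if p.group == G1]

    @cached_property
    def g2(self) -> list[SamplePoint]:
        return [p for p in self.points if p.group == G2]

    @cached_property
    def g3(self) -> list[SamplePoint]:
        return [p for p in self.points if p.group == G3]

    @property
    def m2(self) -> int:
        """Size M of the continuation set G2."""
        return len(self.g2)

    def indices(self, points: Iterable[SamplePoint]) -> np.ndarray:
        return np.fromiter((self.index[p] for p in points), dtype=int)

    def probabilities(self, pi) -> np.ndarray:
        """Probability of every point at rate(s) ``pi``.

        Returns shape ``(n_points,)`` for scalar ``pi`` and
        ``(n_points, len(pi))`` for a grid.
        """
        pi = np.asarray(pi, dtype=float)
        if np.any((pi < 0) | (pi > 1)):
            raise ValueError("pi must be in [0, 1]")
        if pi.ndim == 0:
            with np.errstate(invalid="ignore"):
                out = self._coef * pi**self._k * (1.0 - pi) ** (self._m - self._k)
            return out
        return (
            self._coef[:, None]
            * pi[None, :] ** self._k[:, None]
            * (1.0 - pi[None, :]) ** (self._m - self._k)[:, None]
        )

    def subset_probability(self, idx: np.ndarray, pi: float) -> float:
        """Probability of a subset (by indices) at a scalar rate."""
        pi = float(pi)
        if not (0.0 <= pi <= 1.0):
            raise ValueError("pi must be in [0, 1]")
        c, k, m = self._coef[idx], self._k[idx], self._m[idx]
        return float(np.sum(c * pi**k * (1.0 - pi) ** (m - k)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": [p.x1 for p in self.points],
                "x2": [p.x2 for p in self.points],
                "group": [p.group for p in self.points],
            }
        ).astype({"x2": "Int64"})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_space(design: AdaptiveDesign) -> SampleSpace:
    """Enumerate every terminal outcome exactly once, in canonical order."""
    violations = validate_design(design)
    if violations:
        raise ValueError("invalid design: " + "; ".join(violations))
    points: list[SamplePoint] = []
    for x1 in range(0, design.r1_futility + 1):
        points.append(SamplePoint(x1, None, G1))
    for x1 in design.continuation_values:
        for x2 in range(0, design.n2[x1] + 1):
            points.append(SamplePoint(x1, x2, G2))
    for x1 in range(design.r1_efficacy, design.n1 + 1):
        points.append(SamplePoint(x1, None, G3))
    return SampleSpace(design, points)


def point_probability(space: SampleSpace, point: SamplePoint, pi: float) -> float:
    """Exact probability of one terminal outcome at response rate ``pi``."""
    return space.subset_probability(space.indices([point]), pi)


def _combined_rate_le(
    space: SampleSpace, p: SamplePoint, q: SamplePoint
) -> bool:
    """(p.x1+p.x2)/(n1+n2(p.x1)) <= (q.x1+q.x2)/(n1+n2(q.x1)), exactly."""
    n1 = space.design.n1
    num_p = p.x1 + p.x2
    den_p = n1 + space.design.n2[p.x1]
    num_q = q.x1 + q.x2
    den_q = n1 + space.design.n2[q.x1]
    return num_p * den_q <= num_q * den_p


def tail_set(space: SampleSpace, point: SamplePoint) -> frozenset[SamplePoint]:
    """Tail area Theta of a sample point.

    For a continuation point this is all of ``G3`` plus the continuation
    points whose stage-1 and combined response rates are both at least the
    observed ones (ties included).  Stage-1 stops are ordered marginally by
    their response count: a futility stop's tail is every outcome with
    ``x1' >= x1`` (so its tail probability is the stage-1 binomial tail),
    and an efficacy stop's tail is the efficacy stops with ``x1' >= x1``.
    """
    if point.group == G1:
        return frozenset(q for q in space.points if q.x1 >= point.x1)
    if point.group == G3:
        return frozenset(q for q in space.g3 if q.x1 >= point.x1)
    members = set(space.g3)
    for q in space.g2:
        if q.x1 >= point.x1 and _combined_rate_le(space, point, q):
            members.add(q)
    return frozenset(members)
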