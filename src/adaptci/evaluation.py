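"""Coverage and interval-length evaluation of lower-limit procedures.

Coverage probability at a true rate ``pi`` is the total probability of
the outcomes whose lower limit falls strictly below ``pi``:
``P(L(X1, X2) < pi | pi)``.  A procedure is *exact* when this is at least
``1 - alpha`` for every ``pi``.  Coverage is piecewise smooth with jumps
exactly at the finitely many distinct limit values, so the evaluation
grid is augmented with every limit value +/- a small offset to catch the
jump lows.

Two length criteria weigh the continuation outcomes: the simple average
length ``AL = mean over G2 of (1 - L)`` (each point weighted equally) and
the expected length ``EL(pi) = sum over G2 of (1 - L) * P(point | pi)``
(stage-1 stops excluded from both, as their limits coincide across
procedures).  ``G2(CI)`` is the practically plausible subset of G2 whose
second-stage response rate lies inside the exact two-sided confidence
interval of the first-stage rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .limits import LimitTable, cp_binomial_two_sided
from .sample_space import G2, SamplePoint, SampleSpace

__all__ = [
    "CoverageCurve",
    "LengthSummary",
    "default_pi_grid",
    "coverage_curve",
    "average_length",
    "expected_length",
    "el_ratio",
    "g2_ci_subset",
]

_JUMP_EPS = 1e-9
_CI_TOL = 1e-12


@dataclass(frozen=True)
class CoverageCurve:
    """Coverage probability over a pi grid, with its minimum."""

    pi: np.ndarray
    coverage: np.ndarray
    min_coverage: float
    argmin: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pi": self.pi, "coverage": self.coverage})


@dataclass(frozen=True)
class LengthSummary:
    """Average and (optionally) expected interval length for one ordering."""

    ordering: str
    subset: str
    al: float
    pi: np.ndarray | None = None
    el: np.ndarray | None = None


def default_pi_grid(step: float = 0.001) -> np.ndarray:
    """Default evaluation grid: step..1-step inside the open unit interval."""
    n = int(round(1.0 / step)) - 1
    return np.linspace(step, 1.0 - step, n)


def coverage_curve(
    space: SampleSpace,
    table: LimitTable,
    pi_grid: np.ndarray | None = None,
) -> CoverageCurve:
    """Exact coverage ``P(L < pi | pi)`` on a grid augmented at limit jumps."""
    if pi_grid is None:
        pi_grid = default_pi_grid()
    pi_grid = np.asarray(pi_grid, dtype=float)
    if np.any((pi_grid <= 0.0) | (pi_grid >= 1.0)):
        raise ValueError("pi grid must lie strictly inside (0, 1)")
    lims = np.array([table.limits[p] for p in space.points])
    jumps = np.unique(lims)
    aug = np.concatenate([pi_grid, jumps - _JUMP_EPS, jumps + _JUMP_EPS])
    aug = np.unique(aug[(aug > 0.0) & (aug < 1.0)])
    probs = space.probabilities(aug)  # (n_points, n_grid)
    covered = lims[:, None] < aug[None, :]
    coverage = np.sum(probs * covered, axis=0)
    i = int(np.argmin(coverage))
    return CoverageCurve(
        pi=aug,
        coverage=coverage,
        min_coverage=float(coverage[i]),
        argmin=float(aug[i]),
    )


def average_length(table: LimitTable, subset: Iterable[SamplePoint]) -> float:
    """Simple average length ``mean(1 - L)`` over a subset of G2."""
    pts = list(subset)
    if not pts:
        raise ValueError("subset must be nonempty")
    if any(p.group != G2 for p in pts):
        raise ValueError("average length is defined over continuation points only")
    return float(np.mean([1.0 - table.limits[p] for p in pts]))


def expected_length(
    space: SampleSpace,
    table: LimitTable,
    pi,
    subset: Iterable[SamplePoint] | None = None,
) -> float | np.ndarray:
    """Expected length ``sum over G2 of (1 - L) * P(point | pi)``.

    Accepts a scalar or a grid of ``pi``; an optional subset restricts the
    sum (used for the G2(CI) variant).
    """
    pts = space.g2 if subset is None else [p for p in subset]
    if any(p.group != G2 for p in pts):
        raise ValueError("expected length is defined over continuation points only")
    idx = space.indices(pts)
    w = np.array([1.0 - table.limits[p] for p in pts])
    pi_arr = np.asarray(pi, dtype=float)
    probs = space.probabilities(pi_arr if pi_arr.ndim else float(pi_arr))
    if pi_arr.ndim == 0:
        return float(np.sum(w * probs[idx]))
    return np.sum(w[:, None] * probs[idx, :], axis=0)


def el_ratio(
    space: SampleSpace,
    table_a: LimitTable,
    table_b: LimitTable,
    pi_grid: np.ndarray,
    subset: Iterable[SamplePoint] | None = None,
) -> np.ma.MaskedArray:
    """Pointwise ``EL_a(pi) / EL_b(pi)``, masked where the denominator is 0."""
    pts = list(space.g2 if subset is None else subset)
    ela = expected_length(space, table_a, pi_grid, pts)
    elb = expected_length(space, table_b, pi_grid, pts)
    return np.ma.masked_invalid(np.where(elb > 0.0, ela / np.where(elb > 0, elb, 1.0), np.nan))


def g2_ci_subset(space: SampleSpace, level: float = 0.95) -> list[SamplePoint]:
    """Continuation points whose stage-2 rate lies in the stage-1 rate's CI.

    The interval is the exact two-sided Clopper-Pearson CI for
    ``X1 / n1`` at the given level; membership of ``x2 / n2(x1)`` is
    closed-endpoint with a small float tolerance.  ``level = 1`` returns
    all of G2.  The subset depends only on the design, not on any
    ordering.
    """
    design = space.design
    out = []
    for p in space.g2:
        lo, hi = cp_binomial_two_sided(p.x1, design.n1, level)
        rate2 = p.x2 / design.n2[p.x1]
        if lo - _CI_TOL <= rate2 <= hi + _CI_TOL:
            out.append(p)
    return out
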