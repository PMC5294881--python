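"""Exact one-sided lower limits by Clopper-Pearson inversion of a confidence set.

Given an ordering ``phi`` of the sample space, the exact one-sided
``1 - alpha`` lower limit of a point is the infimum of
``{pi : P(Omega_phi(X1, X2) | pi) > alpha}`` — equivalently
``sup {pi : P(Omega_phi | pi) <= alpha}`` — where ``Omega_phi(X1, X2)``
is the set of outcomes at least as extreme as the observed one.  For the
binomial one-sample problem with ``Omega = {X >= x}`` this reduces to the
classical Clopper-Pearson lower limit, i.e. the ``alpha`` quantile of
``Beta(x, n - x + 1)``.

The tail probability ``P(Omega | pi)`` of every confidence set arising
here is non-decreasing in ``pi`` (the sets are upper sets of the outcome
order), so the inversion is a bracketed root find; the implementation
verifies monotonicity on a grid first and falls back to a grid-supremum
scan with local refinement if it ever fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sample_space import G1, G2, G3, SamplePoint, SampleSpace

__all__ = [
    "cp_binomial_lower",
    "cp_binomial_two_sided",
    "omega_probability",
    "lower_limit",
    "LimitTable",
    "limit_table",
    "ORDERING_NAMES",
]

ORDERING_NAMES = ("RR", "PV", "RR-A", "RR-B", "RR-LR", "RR-Score")

_ROOT_XTOL = 1e-10
_MONO_GRID = 513


def cp_binomial_lower(x: int, n: int, alpha: float) -> float:
    """Clopper-Pearson exact one-sided lower limit for a binomial proportion.

    The unique ``L`` with ``P(X >= x | n, L) = alpha`` for ``x >= 1``
    (the ``alpha`` quantile of ``Beta(x, n - x + 1)``); 0 when ``x = 0``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if x == 0:
        return 0.0
    return float(stats.beta.ppf(alpha, x, n - x + 1))


def cp_binomial_two_sided(x: int, n: int, level: float) -> tuple[float, float]:
    """Equal-tailed Clopper-Pearson interval at confidence ``level``.

    Each tail gets ``(1 - level) / 2``; endpoints are 0 at ``x = 0`` and 1
    at ``x = n``.  ``level = 1`` returns the whole unit interval.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError(f"level must be in (0, 1], got {level}")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if level == 1.0:
        return (0.0, 1.0)
    tail = (1.0 - level) / 2.0
    lower = 0.0 if x == 0 else float(stats.beta.ppf(tail, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - tail, x + 1, n - x))
    return (lower, upper)


def omega_probability(
    space: SampleSpace, omega: Iterable[SamplePoint], pi: float
) -> float:
    """Probability of a confidence set at rate ``pi`` (sum of point probabilities)."""
    return space.subset_probability(space.indices(omega), pi)


def lower_limit(space: SampleSpace, omega: Iterable[SamplePoint], alpha: float) -> float:
    """Invert ``P(omega | pi) = alpha`` for the exact one-sided lower limit.

    Returns the lower endpoint of the confidence set
    ``{pi : P(omega | pi) > alpha}``, i.e. ``inf {pi : P(omega | pi) > alpha}``;
    returns 0 when the tail probability already exceeds ``alpha`` at
    ``pi = 0``.  When the tail probability is monotone non-decreasing (the
    case for every upper-set ``omega``) this is the unique root of
    ``P = alpha`` and coincides with ``sup {pi : P <= alpha}``.  For a
    pathological non-monotone ``omega`` (possible under orderings whose
    statistic is not monotone in the outcome order) the first crossing is
    used: it is the infimum definition that preserves the coverage
    guarantee of a nested confidence-set family.
    """
    idx = space.indices(omega)
    if idx.size == 0:
        raise ValueError("omega must be nonempty")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    def prob(pi: float) -> float:
        return space.subset_probability(idx, pi)

    grid = np.linspace(0.0, 1.0, _MONO_GRID)
    vals = space.probabilities(grid)[idx].sum(axis=0)
    if vals[0] > alpha:
        return 0.0
    monotone = bool(np.all(np.diff(vals) >= -1e-12))
    above = np.nonzero(vals > alpha)[0]
    if above.size == 0:
        # tail probability never exceeds alpha on the grid: the confidence
        # set {pi: P > alpha} is (numerically) empty and the interval
        # degenerates toward the top of the unit interval
        warnings.warn(
            "tail probability never exceeds alpha; degenerate confidence set",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 - float(np.finfo(float).eps)
    lo, hi = grid[above[0] - 1], grid[above[0]]
    if monotone:
        return float(optimize.brentq(lambda p: prob(p) - alpha, lo, hi, xtol=_ROOT_XTOL))
    # non-monotone tail probability: refine the first upward crossing by
    # predicate bisection (inf{pi: P > alpha})
    warnings.warn(
        "tail probability not monotone on grid; using first-crossing fallback",
        RuntimeWarning,
        stacklevel=2,
    )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prob(mid) > alpha:
            hi = mid
        else:
            lo = mid
    return float(hi)


@dataclass(frozen=True)
class LimitTable:
    """Per-point exact one-sided lower limits under one ordering."""

    ordering: str
    alpha: float
    limits: Mapping[SamplePoint, float]
    exact: bool

    def __getitem__(self, point: SamplePoint) -> float:
        return self.limits[point]

    def to_frame(self) -> pd.DataFrame:
        pts = list(self.limits)
        return pd.DataFrame(
            {
                "x1": [p.x1 for p in pts],
                "x2": [p.x2 for p in pts],
                "group": [p.group for p in pts],
                "ordering": self.ordering,
                "lower_limit": [self.limits[p] for p in pts],
                "exact_flag": self.exact,
            }
        ).astype({"x2": "Int64"})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def limit_table(space: SampleSpace, ordering_name: str, alpha: float) -> LimitTable:
    """Exact one-sided lower limit for every sample point under one ordering.

    Stage-1 stops get the Clopper-Pearson binomial lower limit at ``n1``
    (their confidence sets are marginal stage-1 tails under every
    ordering).  The RR ordering is only partial, so its limits do not
    guarantee nominal coverage; the table is flagged non-exact.
    """
    from . import orderings  # deferred: orderings builds on this module

    ordered = orderings.ordered_space(space, ordering_name, alpha=alpha)
    limits: dict[SamplePoint, float] = {}
    for p in space.points:
        limits[p] = lower_limit(space, ordered.omega(p), alpha)
    return LimitTable(
        ordering=ordering_name,
        alpha=alpha,
        limits=limits,
        exact=ordering_name != "RR",
    )
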