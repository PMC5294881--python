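"""Adaptive one-arm two-stage design specification and basic operating characteristics.

An adaptive two-stage design enrols ``n1`` participants in stage 1, stops
early for futility when ``X1 <= r1_futility`` or for efficacy when
``X1 >= r1_efficacy``, and otherwise continues with a second-stage sample
size ``n2(X1)`` that is a non-increasing function of the stage-1 response
count.  The treatment is declared promising when ``X1 + X2 >= r(X1)``.

Designs are *inputs* here: this package performs inference and evaluation
for a given design; it does not search for optimal designs.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "AdaptiveDesign",
    "validate_design",
    "reject_null",
    "operating_characteristics",
    "generate_design",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class AdaptiveDesign:
    """Full specification of an adaptive one-arm two-stage trial.

    Parameters
    ----------
    n1
        Stage-1 sample size.
    r1_futility
        Futility bound ``r1(f)``: stop after stage 1 when ``X1 <= r1(f)``.
        ``-1`` means no futility stop.
    r1_efficacy
        Efficacy bound ``r1(e)``: stop after stage 1 when ``X1 >= r1(e)``.
        The sentinel ``n1 + 1`` encodes a design with no efficacy stop
        (empty efficacy set G3).
    n2
        Map ``X1 -> n2(X1)``, the second-stage size for every continuation
        value ``r1(f) < X1 < r1(e)``; must be non-increasing in ``X1``.
    r
        Map ``X1 -> r(X1)``, the critical total-response count on the same
        domain: reject the null when ``X1 + X2 >= r(X1)``.
    pi0, pi1
        Historical (null) and alternative response rates, ``0 < pi0 < pi1 < 1``.
    alpha, beta
        One-sided significance level and type II error target used when the
        design was constructed.  They are carried as metadata; confidence
        limits take their own ``alpha``.
    """

    n1: int
    r1_futility: int
    r1_efficacy: int
    n2: Mapping[int, int]
    r: Mapping[int, int]
    pi0: float
    pi1: float
    alpha: float = 0.05
    beta: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "n2", dict(sorted(self.n2.items())))
        object.__setattr__(self, "r", dict(sorted(self.r.items())))

    @property
    def continuation_values(self) -> range:
        """Stage-1 response counts for which the trial continues to stage 2."""
        return range(self.r1_futility + 1, self.r1_efficacy)

    @property
    def has_efficacy_stop(self) -> bool:
        return self.r1_efficacy <= self.n1

    def content_hash(self) -> str:
        """Short content hash identifying the design in output headers."""
        payload = json.dumps(_to_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_design(design: AdaptiveDesign) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    Returns an empty list iff the design is valid.  Never raises.
    """
    v: list[str] = []
    n1 = design.n1
    if n1 < 1:
        v.append(f"n1: must be >= 1, got {n1}")
        return v
    if not (-1 <= design.r1_futility):
        v.append(f"r1_futility: must be >= -1, got {design.r1_futility}")
    if not (design.r1_futility < design.r1_efficacy):
        v.append(
            "r1_futility/r1_efficacy: need r1_futility < r1_efficacy, got "
            f"{design.r1_futility} >= {design.r1_efficacy}"
        )
    if not (design.r1_efficacy <= n1 + 1):
        v.append(f"r1_efficacy: must be <= n1 + 1 = {n1 + 1}, got {design.r1_efficacy}")

    expected = set(range(design.r1_futility + 1, design.r1_efficacy))
    for name, table in (("n2", design.n2), ("r", design.r)):
        if set(table) != expected:
            v.append(
                f"{name}: domain must be exactly {{r1_futility+1, ..., r1_efficacy-1}} "
                f"= {sorted(expected)}, got {sorted(table)}"
            )
    if set(design.n2) == expected:
        xs = sorted(expected)
        for x1 in xs:
            if design.n2[x1] < 1:
                v.append(f"n2: n2({x1}) must be >= 1, got {design.n2[x1]}")
        for a, b in zip(xs, xs[1:]):
            if design.n2[a] < design.n2[b]:
                v.append(
                    f"n2: must be non-increasing in X1, but n2({a})={design.n2[a]} "
                    f"< n2({b})={design.n2[b]}"
                )
        if set(design.r) == expected:
            for x1 in xs:
                lo, hi = x1, x1 + design.n2[x1] + 1
                if not (lo <= design.r[x1] <= hi):
                    v.append(f"r: need {lo} <= r({x1}) <= {hi}, got {design.r[x1]}")
    for name, val, lo, hi in (
        ("pi0", design.pi0, 0.0, 1.0),
        ("pi1", design.pi1, 0.0, 1.0),
        ("alpha", design.alpha, 0.0, 1.0),
        ("beta", design.beta, 0.0, 1.0),
    ):
        if not (lo < val < hi):
            v.append(f"{name}: must lie in ({lo}, {hi}), got {val}")
    if 0.0 < design.pi0 < 1.0 and 0.0 < design.pi1 < 1.0 and design.pi1 <= design.pi0:
        v.append(f"pi1: must exceed pi0, got pi1={design.pi1} <= pi0={design.pi0}")
    return v


def _require_valid(design: AdaptiveDesign) -> None:
    violations = validate_design(design)
    if violations:
        raise ValueError("invalid design: " + "; ".join(violations))


def reject_null(design: AdaptiveDesign, x1: int, x2: int | None = None) -> bool:
    """Final decision for a terminal outcome ``(x1, x2)``.

    ``x2`` is absent (``None``) for stage-1 stops.  True means the null
    ``pi <= pi0`` is rejected (efficacy stop, or total responses reach the
    critical value ``r(x1)``).
    """
    _require_valid(design)
    if x2 is None:
        if x1 >= design.r1_efficacy and x1 <= design.n1 and x1 >= 0:
            return True
        if 0 <= x1 <= design.r1_futility:
            return False
        raise ValueError(
            f"({x1}, absent) is not a stage-1 stopping outcome of this design"
        )
    if x1 not in design.n2 or not (0 <= x2 <= design.n2[x1]):
        raise ValueError(f"({x1}, {x2}) is not in the sample space of this design")
    return x1 + x2 >= design.r[x1]


def operating_characteristics(design: AdaptiveDesign, pi: float) -> dict[str, float]:
    """Exact rejection probability, expected sample size and PET at rate ``pi``.

    ``reject_prob`` is the exact probability of declaring efficacy;
    ``pet`` the probability of early termination after stage 1;
    ``expected_sample_size`` is ``n1 + sum_x1 b(x1; n1, pi) n2(x1)`` over
    continuation values.  For arbitrary input designs the type I/II error
    targets need not hold; the values are reported, not enforced.
    """
    _require_valid(design)
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    n1 = design.n1
    p1 = stats.binom.pmf(np.arange(n1 + 1), n1, pi)
    reject = float(p1[design.r1_efficacy:].sum()) if design.has_efficacy_stop else 0.0
    pet = float(p1[: design.r1_futility + 1].sum()) + (
        float(p1[design.r1_efficacy:].sum()) if design.has_efficacy_stop else 0.0
    )
    en = float(n1)
    for x1 in design.continuation_values:
        w = float(p1[x1])
        n2 = design.n2[x1]
        en += w * n2
        need = design.r[x1] - x1
        reject += w * float(stats.binom.sf(need - 1, n2, pi))
    return {"reject_prob": reject, "expected_sample_size": en, "pet": pet}


def generate_design(
    seed: int,
    n1_range: tuple[int, int] = (4, 15),
    n2_max: int = 8,
    pi0: float = 0.3,
    alpha: float = 0.05,
) -> AdaptiveDesign:
    """Draw a random valid adaptive two-stage design.

    Deterministic for a fixed seed.  The shape mixture deliberately covers
    the edge geometries that occur in optimal designs: with probability
    ~0.2 the efficacy set G3 is empty (sentinel ``r1_efficacy = n1 + 1``),
    with probability ~0.2 the continuation region is a single point, and
    with probability ~0.25 ``n2`` is constant (a Simon-like design).
    """
    lo, hi = n1_range
    if not (1 <= lo <= hi) or n2_max < 1:
        raise ValueError(f"infeasible ranges: n1_range={n1_range}, n2_max={n2_max}")
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(lo, hi + 1))
    r1f = int(rng.integers(-1, n1 // 3 + 1))
    if rng.random() < 0.2:
        r1e = n1 + 1  # no efficacy stop: G3 empty
    elif rng.random() < 0.25:
        r1e = min(r1f + 2, n1 + 1)  # single continuation value
    else:
        r1e = int(rng.integers(r1f + 2, n1 + 2))
    width = r1e - r1f - 1
    if width < 1:  # pragma: no cover - construction keeps width >= 1
        r1e = r1f + 2
        width = 1
    if rng.random() < 0.25:
        sizes = [int(rng.integers(1, n2_max + 1))] * width
    else:
        sizes = sorted(
            (int(s) for s in rng.integers(1, n2_max + 1, size=width)), reverse=True
        )
    xs = list(range(r1f + 1, r1e))
    n2 = dict(zip(xs, sizes))
    # critical values near the null expectation, jittered within the legal band
    r_map = {}
    for x1 in xs:
        base = int(np.ceil(pi0 * (n1 + n2[x1])))
        jitter = int(rng.integers(-1, 2))
        r_map[x1] = int(np.clip(base + jitter, x1, x1 + n2[x1] + 1))
    design = AdaptiveDesign(
        n1=n1,
        r1_futility=r1f,
        r1_efficacy=r1e,
        n2=n2,
        r=r_map,
        pi0=pi0,
        pi1=min(pi0 + 0.2, 0.95),
        alpha=alpha,
        beta=0.2,
    )
    _require_valid(design)
    return design


# ---------------------------------------------------------------------------
# I/O: JSON (canonical) and CSV (header block + per-stage table)

def _to_jsonable(design: AdaptiveDesign) -> dict:
    return {
        "pi0": design.pi0,
        "pi1": design.pi1,
        "alpha": design.alpha,
        "beta": design.beta,
        "n1": design.n1,
        "r1_futility": design.r1_futility,
        "r1_efficacy": design.r1_efficacy,
        "stages": [
            {"x1": x1, "n2": design.n2[x1], "r": design.r[x1]}
            for x1 in sorted(design.n2)
        ],
    }


def _from_jsonable(obj: dict) -> AdaptiveDesign:
    return AdaptiveDesign(
        n1=int(obj["n1"]),
        r1_futility=int(obj["r1_futility"]),
        r1_efficacy=int(obj["r1_efficacy"]),
        n2={int(s["x1"]): int(s["n2"]) for s in obj["stages"]},
        r={int(s["x1"]): int(s["r"]) for s in obj["stages"]},
        pi0=float(obj["pi0"]),
        pi1=float(obj["pi1"]),
        alpha=float(obj["alpha"]),
        beta=float(obj["beta"]),
    )


_SCALARS = ("pi0", "pi1", "alpha", "beta", "n1", "r1_futility", "r1_efficacy")


def write_design(design: AdaptiveDesign, path: str | Path) -> None:
    """Write a design to ``.json`` or ``.csv`` (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(_to_jsonable(design), indent=2) + "\n")
        return
    buf = io.StringIO()
    obj = _to_jsonable(design)
    for key in _SCALARS:
        buf.write(f"# {key}={obj[key]}\n")
    buf.write("x1,n2,r\n")
    for s in obj["stages"]:
        buf.write(f"{s['x1']},{s['n2']},{s['r']}\n")
    path.write_text(buf.getvalue())


def read_design(path: str | Path) -> AdaptiveDesign:
    """Read a design from ``.json`` or ``.csv``; round-trips losslessly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _from_jsonable(json.loads(path.read_text()))
    header: dict[str, str] = {}
    stages = []
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            header[key.strip()] = val.strip()
        elif ln.lower().startswith("x1"):
            continue
        else:
            x1, n2, r = (int(tok) for tok in ln.split(","))
            stages.append({"x1": x1, "n2": n2, "r": r})
    obj: dict = {k: float(header[k]) for k in ("pi0", "pi1", "alpha", "beta")}
    obj.update({k: int(header[k]) for k in ("n1", "r1_futility", "r1_efficacy")})
    obj["stages"] = stages
    return _from_jsonable(obj)
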