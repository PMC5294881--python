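# Methods

## Model and sample space

A one-arm two-stage binomial trial tests `H0: π ≤ π0` against `Ha: π ≥ π1`,
rejecting for high response counts.  The design is the triple
`(n1, n2(X1), r(X1))` together with stage-1 stopping bounds `r1(f) < r1(e)`:
stop for futility when `X1 ≤ r1(f)`, for efficacy when `X1 ≥ r1(e)`,
otherwise enrol `n2(X1)` more patients and reject when `X1 + X2 ≥ r(X1)`.
The adaptivity constraint is that `n2(·)` is non-increasing in `X1`.  The
sentinels `r1(f) = −1` (no futility stop) and `r1(e) = n1 + 1` (no efficacy
stop; the efficacy set is empty, which does occur in optimal designs with
large `π0`) are first-class.

Terminal outcomes partition into `G1` (futility stops, `x2` absent), `G2`
(continuation points `(x1, x2)`), `G3` (efficacy stops).  A stage-1 stop is
*not* the same outcome as a continuation point with `x2 = 0`; `x2` is kept
as a missing value, not zero, in memory and in every CSV.  Outcome
probabilities are products of binomial pmfs along the stopping path:
`b(x1; n1, π)` for stage-1 stops and `b(x1; n1, π)·b(x2; n2(x1), π)` for
continuation points.  Internally each point is reduced to
`coef · π^k (1−π)^(m−k)` with integer-exact binomial coefficients, so whole
curves over a π grid are a single vectorised numpy expression.

## Orderings and confidence sets

The tail area of a continuation point is

    Θ(x1, x2) = G3 ∪ { (x1', x2') : x1 ≤ x1'  and
                        (x1+x2)/(n1+n2(x1)) ≤ (x1'+x2')/(n1+n2(x1')) },

with both rate comparisons done by integer cross-multiplication (ties are
in the tail; no floating-point rate is ever compared).  Stage-1 stops are
ordered marginally by response count: the tail of a futility stop is every
outcome with `x1' ≥ x1` (so its tail probability is the plain stage-1
binomial tail), that of an efficacy stop is the efficacy stops above it.
This makes stage-1 limits collapse to classical Clopper–Pearson binomial
limits under every ordering, and places `G1` below `G2` below `G3` in all
of them.

Confidence sets per ordering:

* **RR** — `Ω = Θ` itself (partial order; not exact).
* **PV** — `Ω = {q : p(q) ≤ p(p)}` where `p(·)` is the null tail
  probability at `π0`.  Tail nesting (`q ∈ Θ(p) ⇒ Θ(q) ⊆ Θ(p)`) gives the
  containment `Ω_RR(p) ⊆ Ω_PV(p)` for every point, hence `L_RR ≥ L_PV`
  pointwise.
* **RR-A** — compute every RR limit, then order the whole space by those
  limits (a two-step ordering that totalises RR).  Limit ties are compared
  at 1e-10 (the limits are roots found in floating point) and tied points
  share one confidence set.
* **RR-B / RR-LR / RR-Score** — order `G2` by the pooled rate, the pooled
  rate × `√n2`, or the pooled rate × `n2`.  The statistics are implemented
  exactly as stated, uncentered; the classical sequential-analysis forms
  subtract `π0` first, and a centered variant would order some spaces
  differently, but the uncentered forms are the ones under study here.
  Comparisons use exact rationals (for RR-LR the squared statistic
  `rate²·n2`, which is order-equivalent for non-negative rates), so tied
  statistics are recognised exactly.  With constant `n2` all three reduce
  to the same ordering.

Ties are always *included* in `Ω`; excluding a tied point would break the
coverage argument below.

## Inversion

The exact one-sided `1−α` interval is `(L, 1]` with `Ω`'s tail probability
`P(Ω | π)` exceeding `α` exactly on the reported interval.  `L` is computed
as the lower endpoint of `{π : P(Ω | π) > α}`:

* `P(Ω | ·)` is evaluated on a 513-point grid; if it is monotone
  non-decreasing (always the case when `Ω` is an upper set of the outcome
  order, which covers RR, PV, RR-A, RR-B and most metric sets) the unique
  root of `P = α` is bracketed there and polished with Brent's method
  (xtol 1e-10).
* If `P(Ω | 0) > α` (e.g. `Ω` is the whole space) the limit is 0.
* If the grid shows non-monotonicity — which genuinely happens for RR-LR /
  RR-Score sets on designs with strongly varying `n2`, because the
  uncentered statistic is not monotone in the outcome order — the *first
  upward crossing* of `α` is refined by predicate bisection and a
  `RuntimeWarning` is emitted.  The first-crossing (infimum) definition is
  the one that preserves coverage for a nested family: the non-covered set
  at any `π` is the confidence set of the least extreme point whose limit
  reaches `π`, and `π ≤ L(q)` implies `P(Ω(q) | π) ≤ α` only under the
  infimum definition.  (Taking instead the supremum of `{π : P ≤ α}` looks
  equivalent but is not: for a set whose probability rises and then falls
  back below `α` near `π = 1` it returns a limit near 1 and collapses
  coverage — observed before the fix as ~2% minimum coverage on empty-`G3`
  designs under RR-Score.)
* If `P(Ω | π)` never exceeds `α` the confidence set is empty and the
  degenerate limit `1 − ε` is returned with a warning; this arises only
  for pathological single-point sets of negligible probability.

Limits are stored at full precision; human-readable output rounds to 3
decimals.

## Evaluation

Coverage is `P(L(X1, X2) < π | π)` with strict inequality, evaluated on a
grid (default step 0.001 on (0,1)) augmented with every distinct limit
value ± 1e-9, because coverage is piecewise smooth with jumps exactly at
the limit values and the infimum sits just past a jump.  For the five
total orderings the minimum over this grid is `1 − α` to within root
tolerance; for RR it can dip well below (non-exactness).

Lengths are compared over the continuation set only (stage-1 stops have
identical limits under all orderings): simple average length
`AL = Σ_G2 (1 − L)/M` with `M = Σ (n2(x1)+1)`, expected length
`EL(π) = Σ_G2 (1 − L)·b·b`, and pointwise EL ratios masked where the
denominator vanishes.  `G2(CI)` keeps the continuation points whose
second-stage *rate* `x2/n2(x1)` lies in the exact two-sided
Clopper–Pearson CI of the first-stage rate (closed endpoints, tolerance
1e-12; level 1 returns all of `G2`).  The rate reading is deliberate: the
set-builder form "`X2 ∈ CI`" that sometimes appears would compare a count
against a rate interval.  `G2(CI)` can be empty for tiny `n2` at stringent
levels; consumers (and the acceptance script) must treat that case.

## Synthetic designs

`generate_design(seed)` draws a valid design deterministically: `n1`
uniform on 4..15, futility bound on −1..⌊n1/3⌋, a shape mixture giving
roughly 20% empty-`G3` designs, 20% single-point continuation regions and
25% constant `n2` (Simon-like), otherwise a non-increasing random `n2 ≤ 8`,
and critical values jittered around the null expectation `⌈π0(n1+n2)⌉`.
Defaults `π0 = 0.3`, `π1 = π0 + 0.2`, `α = 0.05`, `β = 0.2` mirror common
phase II settings.  These desk-scale spaces (≲ 150 outcomes) exercise every
structural edge case the inference code must handle, and they are small
enough that coverage can be computed *exactly* by enumeration — so the
exactness results on them are not simulations but finite proofs for those
designs.  What they do not emulate: the generated `(n2, r)` tables are
random-feasible, not optimal for any error-rate target, so operating
characteristics (power, E[N]) are arbitrary, and length comparisons on
them show the same qualitative ordering as on optimal designs
(AL: RR-A ≤ PV ≤ RR-B) but not the published magnitudes, which belong to
specific externally published optimal designs.

## Known limitations

* Upper limits and two-sided intervals for the two-stage design are not
  implemented (the lower-limit construction mirrors directly, but is out
  of scope here).
* Optimal-design search is out of scope; designs are always inputs.
* Point estimation (bias-corrected response rate) and exact p-value
  reporting as inference outputs are not provided; the p-value computed
  here is an ordering device.
* The regression tests against published optimal-design results require
  transcribed `(n2, r)` tables under `tests/data/external/` and fail with
  an explanatory message without them.
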