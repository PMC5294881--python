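# adaptci

Exact one-sided confidence limits for the response rate after an **adaptive
one-arm two-stage clinical trial** with a binary endpoint, and the machinery
to compare the competing limit constructions by coverage and interval length.

## The problem

Phase II oncology trials are commonly run in two stages so that inactive
treatments can be abandoned early.  In the adaptive variant handled here, the
trial enrols `n1` patients, observes `X1` responses, and then

* stops for **futility** when `X1 ≤ r1(f)`,
* stops for **efficacy** when `X1 ≥ r1(e)`,
* otherwise continues with `n2(X1)` further patients — where `n2(·)` is a
  **non-increasing** function of `X1` (the more responses already seen, the
  fewer patients are still needed) — and rejects the null
  `H0: π ≤ π0` when `X1 + X2 ≥ r(X1)`.

After such a trial a one-sided lower confidence limit `L` for the response
rate `π` must be reported, consistent with the one-sided test.  Because the
design is sequential and the second-stage size is data-dependent, naive
binomial intervals are wrong.  The exact construction inverts the
Clopper–Pearson tail argument: order the terminal sample space
`Ω = {G1, G2, G3}` (futility stops, continuation outcomes, efficacy stops) by
some notion of extremeness `φ`, collect for each observed outcome its
confidence set `Ω_φ(X1, X2)` of outcomes at least as extreme, and report

```
(L, 1],   L = lower endpoint of { π : P(Ω_φ(X1, X2) | π) > α }.
```

Six orderings `φ` are implemented:

| name | ordering statistic for a continuation point `(X1, X2)` | exact? |
|----------|--------------------------------------------------------|--------|
| RR | tail-area partial order: stage-1 rate *and* combined rate both at least observed | no |
| PV | exact p-value at `π0` (null probability of the tail area) | yes |
| RR-A | the RR lower limits themselves, used as a second-step total order | yes |
| RR-B | pooled response rate `(X1+X2)/(n1+n2(X1))` (MLE ordering) | yes |
| RR-LR | pooled rate × `√n2(X1)` (likelihood-ratio style) | yes |
| RR-Score | pooled rate × `n2(X1)` (score style) | yes |

The RR partial order cannot rank all pairs of outcomes, and its limits can
under-cover (coverage below `1 − α` at some `π`); the five total orderings
guarantee `P(L < π | π) ≥ 1 − α` for every `π`.  The package also evaluates
the procedures: exact coverage curves, simple average length
`AL = mean(1 − L)` over the continuation set `G2`, expected length
`EL(π) = Σ (1 − L)·P(outcome | π)`, EL ratios, and the "practical" subset
`G2(CI)` of continuation outcomes whose second-stage rate falls inside the
exact two-sided CI of the first-stage rate.

## Worked example

Designs are inputs (JSON or CSV); a generator produces valid random designs
for experimentation:

```
$ adaptci generate --seed 7 -o demo.json
wrote demo.json (hash c584936cc2eb); at pi0: reject 0.498, E[N] 20.0, PET 0.297
```

This design has `n1 = 15`, `r1(f) = 3`, `r1(e) = 15`, and `n2` falling from
8 to 1 as `X1` runs from 4 to 14.  Suppose the trial continued after
`X1 = 5` responses and ended with `X2 = 4` of `n2(5) = 7`:

```
$ adaptci limits demo.json --observed 5,4 -o demo_limits
RR      L(5,4)=0.233
PV      L(5,4)=0.222
RR-A    L(5,4)=0.222
RR-B    L(5,4)=0.233
RR-LR   L(5,4)=0.239
RR-Score        L(5,4)=0.240
```

Each line is the 95% one-sided lower limit for `π` under one ordering: e.g.
under the PV ordering the trial supports `π > 0.222`.  The RR limit is never
smaller than the PV limit (a containment theorem relating their confidence
sets) — but that apparent sharpness is paid for with lost coverage:

```
$ adaptci evaluate demo.json --ordering RR --ordering PV --ordering RR-B --compare -o demo_eval
RR: min coverage 0.9286 at pi=0.423, AL=0.6486
PV: min coverage 0.9500 at pi=0.560, AL=0.6563
RR-B: min coverage 0.9500 at pi=0.611, AL=0.6633
AL(RR) - AL(PV) = -0.0077
AL(PV) - AL(RR-B) = -0.0070
```

The RR procedure dips to 92.9% coverage at nominal 95%, while PV and RR-B
stay exact; among the exact procedures PV gives slightly shorter average
intervals than RR-B here.  The same computations are available in Python via
`adaptci.enumerate_space`, `adaptci.limit_table`, `adaptci.coverage_curve`,
`adaptci.average_length` and friends.

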