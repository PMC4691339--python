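# Methods

## Setting and assumptions

The toolkit models *closed* curation projects: a fixed candidate set of
`n` items, a fixed time budget `T_max`, and an average curation speed `v`
(items per unit time). It deliberately ignores open-ended database
maintenance, curator-level concurrency, fatigue, and the quality–quantity
trade-off; curation quality is assumed constant. Item values are treated
as exchangeable scalars on a bounded scale `[w_min, w_max]` and curation
times as per-item costs that add linearly — no learning effects, no
batching.

## The overhead family

All metrics are kept internally as plain fractions; overhead may exceed 1.
The presentation layer renders whole percentages by rounding half away
from zero (`display_percent`), which is what reproduces printed figures
such as 33% (from 1/3) and 39% (from 7/18). Statements like "a 10-point
precision gain saves 15 overhead points" are arithmetic on these rendered
percentages (33% − 18%), not on the raw fractions.

Four variants are implemented:

| variant | formula | use |
|---|---|---|
| simple | `FP/TP` | binary value, uniform times |
| time-weighted | `FP·T̄_FP / (TP·T̄_TP)` | FPs cheaper to dismiss than TPs to annotate |
| value-weighted | `Σ(w_max−w_i)/Σ(w_i−w_min)` (optionally time-weighted per item) | graded value scales |
| probability-adjusted | expected form with per-item TP probability `p_i`, FPs valued at `w_min` | pre-curation planning |

**Denominator conventions.** The definitional time-weighted form divides
by `TP·T̄_TP`. A second convention, `filtered`, divides by
`(TP+FP)·T̄_TP` — the quick "first approximation" that treats the whole
filtered set as the workload base. Both are exposed through a
`denominator ∈ {tp, filtered}` flag (default `tp`); the IL32/IL10 example
uses `filtered` (7/18 = 39%, and 7/36 = 19% when TPs take twice as long as
FPs).

**Degenerate inputs.** `TP = 0` with `FP > 0` is reported as a distinct
`InfiniteOverheadError` rather than an IEEE `inf`, so downstream
optimizers must handle worst cases explicitly; an empty curated set raises
`UndefinedMetricError`. `F_β(0, 0)` returns 0 by the common convention.

## Toolbox geometry

The *area covered* (AC) by a set of strategies is defined as the region of
the precision–recall unit square weakly dominated by some achievable
operating point: the union of origin-anchored rectangles
`[0, recall] × [0, precision]` for fixed points, plus the region under an
adjustable strategy's curve (including the rectangle left of its lowest
knot). This definition makes "falls inside the AC" provably equivalent to
"weakly dominated by the toolbox", which is asserted as a tested
invariant. The area is computed exactly by an upper-envelope sweep over
the linear segments (breakpoints at segment endpoints and pairwise
intersections), not by sampling; the test suite cross-checks it against an
independent grid-counting oracle at 1000×1000 resolution.

Tie handling: equal points do not dominate each other (the frontier keeps
one representative of duplicated coordinates), but an exact duplicate *is*
inferior — it adds no capability.

Adjustable strategies require strictly increasing recall knots and
non-increasing precision; operating points between knots are linearly
interpolated, and precision/output-size targets are inverted by bisection
(tolerance 1e-12 in recall).

**Strategy selection.** Expected output on a project of `n` items with
base rate `π` is `TPs = nπ·recall`, `m = TPs/precision`; implied `m > n`
marks the option inconsistent. The expected workload is
`TPs·T̄_TP + (m − TPs)·T̄_FP` (or `m·T̄` when only a mean time is known),
and each strategy's application cost is charged against `T_max` before the
feasibility check. Among feasible options the expected TP count is
maximized; ties break toward lower overhead, then smaller output, then
name, so results are deterministic. The base rate `π` is an explicit
required input — it cannot be inferred from the strategy descriptions.

## Planner

* **Ranking ties**: equal estimated value → shorter estimated time first
  (more items per budget), then lexicographic id.
* **Greedy boundary**: an item that does not fit the remaining budget is
  skipped and the next-ranked one tried, rather than stopping — skipping
  weakly dominates stopping for the curated value sum. With uniform item
  times the greedy schedule is provably optimal for `Σw` (tested against
  brute-force subset enumeration at small n).
* **Expected-value ranking** uses `p·w + (1−p)·w_min`, i.e. FPs are worth
  the scale floor; richer two-dimensional rankings are out of scope.
* **Redundancy**: items repeating a `duplicate_key` (within the project,
  first occurrence kept, or against a prior-key set) are revalued to
  `w_min` and tagged; the operation is idempotent.
* **Allocation** of a global budget across projects minimizes `Σ_j O_j`
  where `O_j` is by default the value-weighted overhead of what the
  project would curate under its budget (probability-adjusted or simple
  overhead selectable). Time is discretized into quanta; instances with at
  most 10⁴ budget compositions are solved exactly by enumeration, larger
  ones by greedy marginal assignment polished with pairwise transfers of
  any size until no move improves. Optimality is certified only against
  the exhaustive oracle at small scale. A project allocated too little to
  curate anything contributes the overhead of its single least valuable
  item (its worst single-item outcome), so starving a project is never
  scored as solving it; an unbounded overhead there is capped at a large
  finite penalty (1e9).

## Simulator

The generator emulates the statistical structure the planning model
assumes: items with independent TP labels at rate `π`, per-class mean
curation times, graded or binary values, noisy value estimates and
approximately calibrated TP probabilities. Defaults: `π = 0.3` (a
moderately selective triage stage), binary values (beta(2, 5) on the scale
for graded-value studies), lognormal times with σ = 0.25 and mean TP time
2× the mean FP time — a TP needs storing and annotation, an FP only a
read-and-reject decision — value-estimate noise σ = 0.05, and a logistic
probability model `p = σ(2·(2y−1) + ε)`, `ε ~ N(0,1)`, with an optional
additive logit shift to inject miscalibration (off by default).

What it does **not** emulate: correlated item values, duplicate structure,
drifting value over time, curator heterogeneity, or any text content.
Passing tests therefore demonstrate the correctness of the metrics and
decision rules under the stated independence assumptions, not performance
on any particular corpus.

Randomness: one root seed; each component (labels, values, times, noise,
probabilities, filtering) uses an independent stream spawned from the root
by a fixed label, so adding a component never perturbs existing draws and
identical configurations are byte-identical across runs.

A simulated filter keeps each TP with probability `target_recall` and
admits FPs at the rate that makes the *expected* precision equal
`target_precision`; targets needing more FPs than exist are rejected with
the feasible envelope. The recovery experiment checks that realized
overhead converges to `(1−P)/P` and realized TP production to
`1/(T̄_TP(1+O))`; the standard problem size is n = 10⁴ items with 200
replicates per target, which keeps the full recovery grid under a few
seconds while leaving standard errors of ~0.2% on overhead.

## Known limitations

* The allocator's greedy path is a local search; away from the certified
  small-scale regime it guarantees only budget conservation and
  no-improving-pairwise-move, not global optimality.
* Value confidence intervals are not propagated into overhead; per-item
  values are point estimates.
* The AC of a mixed toolbox combines fixed points and curves by union
  only; no interpolation between separate strategies is assumed.
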