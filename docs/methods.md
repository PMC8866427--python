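# Methods

## Simulated behaviour streams

Time is a discrete 1-second grid; a behaviour occupying `[t, t+dur)`
marks seconds `t … t+dur−1`, and every interval in the package is
half-open. All parameters are integer seconds, so nothing is lost by the
discretization, and it makes the ground-truth activity budget an exact
rational number rather than an estimate.

Streams are **block-randomized**, not Poisson: real behaviour is quasi
regular (an animal that forages roughly every half minute does not produce
memoryless gaps), and block randomization guarantees the true budget is
identical in every replicate, so all replicate-to-replicate variation in
the error is attributable to the sampling rule, not to the stream.

* **Event (frequency) streams** — one 1-s event per `f`-second block,
  start offset uniform on `{0, …, f−1}`. Defaults `f ∈ {3, 30, 300}` give
  true budgets of exactly 1/3, 1/30, 1/300. Event duration is fixed at
  1 s; longer "events" are states and belong to the other family.
* **State (duration) streams** — one contiguous `d`-second bout per 600-s
  block, never crossing a block boundary. Defaults `d ∈ {3, 30, 300}`
  give budgets of exactly 0.5%, 5%, 50% of the hour.

The bout start offset is uniform on `{0, …, 600−d−1}` by default
(`offset_support="exclusive"`): the bout may start at the beginning of its
block but never ends flush with the block end. The inclusive alternative
`{0, …, 600−d}` is one configuration switch away. The choice is visible
only in third-decimal summaries (expected one-zero error for `d=300,
L=50` is 0.0817 exclusive vs 0.0814 inclusive); the exclusive default is
the one whose rounded summaries match the reference tables this package
reproduces. A side effect worth knowing: under either support the
occupancy probability of a given second is not constant across a block
(the last second of a block is rarely or never occupied), which is what
makes pinpoint sampling slightly biased for states at long intervals (see
below).

Randomness policy: each (family, condition, replicate) cell draws from
`default_rng([base_seed, family_code, condition, replicate])`, so any
single replicate is reproducible in isolation and the grid is
embarrassingly order-independent.

## Recording rules

Both rules partition `[0, T)` into `m = ceil(T/L)` half-open intervals;
with `T=3600` and `L ∈ {5, 50, 500}` that is 720 / 72 / 8 intervals, the
last one shorter (`[3500, 3600)`) when `L = 500`. The trailing partial
interval **is kept**: it receives its own pinpoint sample and scores as a
full interval under one-zero, and estimates are unweighted interval
fractions. These conventions are forced by the quantization structure of
the reference results (8-interval outcomes `7/8` and `1` at `L=500`, and
pinpoint extremes at multiples of `1/8`); a 7-interval truncated partition
or time-weighted averaging would produce different third decimals.

* **Pinpoint** reads occupancy at the first second of each interval,
  `t = kL` (`pinpoint_at="end"` switches to the last second). Estimates
  are multiples of `1/m`.
* **One-zero** scores an interval iff at least one of its seconds is
  occupied. Because a scored interval contains at most `L` occupied
  seconds and `mL ≥ T`, the estimate can never fall below the true
  proportion — one-zero overestimation is structural, not incidental.

## Error grids

For each family the grid is 3 conditions × 3 intervals × 100 replicates;
each replicate stream is sampled by **both** methods (paired design — the
paired Wilcoxon post-hocs are meaningless without it), giving 900 sampled
data sets per family per method and 1800 simulated hours across both
families at the defaults. Per-cell summaries are the mean signed error
and the empirical 2.5th/97.5th percentiles, computed with numpy's
linear-interpolation quantile (the conventional default; other quantile
types are a config switch). Tables are written at full precision and only
rounded for display.

Several frequency-family one-zero cells are fully deterministic and have
closed forms used as test oracles: if every interval contains a complete
`f`-block the error is exactly `1 − 1/f`; if `L < f` and `L` divides `f`,
block and interval boundaries align and the error is exactly `(L−1)/f`.

## Inference

* **Friedman test**, blocks = the 9 condition × interval cells, treatments
  = the 2 recording methods, one value per (block, treatment) = that
  cell's mean signed error (absolute errors are a switch; with these data
  the ranking is identical since one-zero errors are positive and larger
  everywhere). The statistic is the classic rank formula
  `χ² = 12/(nk(k+1)) Σ Rj² − 3n(k+1)` with average ranks on ties and no
  tie correction, referred to χ² on `k−1` df; it is implemented directly
  because the scipy routine requires k ≥ 3 and cannot express this
  two-treatment design (scipy serves as a cross-check oracle at k ≥ 3 in
  the tests). Kendall's `W = χ²/(n(k−1))` is 1 exactly when one method
  wins in every block — which is what these simulations produce:
  `χ² = 9, df = 1, p = 0.0027, W = 1` with 9 blocks.
* **Post-hocs**: per cell, a two-sided Wilcoxon signed-rank test on the
  100 paired `one_zero − pinpoint` error differences; zeros are dropped
  before ranking (Wilcoxon's convention; Pratt's is a switch), the exact
  null is used for ≤ 25 non-zero differences and the normal approximation
  with continuity correction beyond. All-zero differences raise an
  explicit degenerate-input error rather than returning a number.
* **Multiplicity**: Benjamini–Hochberg step-up adjustment of the 9 raw
  p-values per family (delegated to statsmodels).

## Numerical and design notes

* Pinpoint is *exactly* unbiased for event streams (every second has
  occupancy probability `1/f`), but **not** for state streams at long
  intervals: exact enumeration over bout offsets gives an expected error
  of −0.0833 for `d=300, L=500` (the 8 sampling instants land on block
  offsets where a 300-s bout is under-represented). The test suite
  therefore checks pinpoint calibration against the enumerated exact
  expectation per cell — zero for all event cells — rather than against
  zero everywhere.
* The `(f=300, L=500)` one-zero cell has exactly two possible outcomes
  per replicate, errors `7/8 − 1/300 ≈ 0.872` and `1 − 1/300 ≈ 0.997`
  (the trailing 100-s interval is scored with probability 1/3); its mean
  at 100 replicates fluctuates around the analytic 0.9133 with an MC
  standard error of ≈ 0.006, so only its percentile structure is asserted.
* Degenerate inputs: `L = T` yields a single interval (one-zero becomes
  "any occurrence", pinpoint reads second 0); `d = 600` collapses the
  offset support to `{0}` and fills the hour; fully tied Friedman input
  returns statistic 0 and p = 1 rather than erroring.
* The Friedman null-calibration test runs at 40 blocks × 4 treatments:
  at the 9 × 2 geometry of the study itself the statistic takes so few
  values that the exact rejection rate at the 0.05 threshold is 20/512 ≈
  0.039, and no implementation could hit 5% there.

## What the simulations do and do not show

The generator emulates behaviours with fixed, known budgets and perfectly
regular block structure, observed without error. It does not model
observer misclassification, drifting behaviour rates within a session,
bouts of variable length, multiple concurrent behaviours, or
autocorrelated placement beyond the block constraint. Conclusions about
the *ordering* of the methods (one-zero's structural overestimation,
pinpoint's near-unbiasedness) are robust to these simplifications; the
specific error magnitudes are tied to the simulated budgets and interval
lengths and should not be read as universal constants. Whole-interval
recording and occurrence/non-occurrence variants are out of scope.
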