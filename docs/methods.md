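# Methods

## The measurement chain

A low-cost optical particle counter (Dylos DC1700 class) estimates number
densities in two size channels — particles larger than 0.5 µm ("total") and
larger than 2.5 µm ("large") — per 0.01 ft³ of sampled air, and prints one
record per minute on its serial port as `<total/100>,<large/100>`. The
firmware's ÷100 is modelled as a configurable `count_scale` (default 100):
parsing multiplies by it, serialization divides (rounding half-up, logged,
when a count is not scale-divisible). Timestamps are assigned client-side,
UTC, floored to the minute; the whole pipeline keys records on
(device, minute). All downstream exposure statistics are on the PM2.5 scale
(µg/m³), so nothing in the analysis depends on the count-scale choice.

Counts are converted to estimated PM2.5 by an ordered piecewise-linear map
`pm = slope_i · x + intercept_i` over the configured channel (`small`, or
`small_minus_large` for fine-fraction conventions). Validity conditions —
first break at 0, strictly increasing breaks, non-negative slopes, no
downward jump at a break — jointly guarantee a monotone non-decreasing,
non-negative map; evaluation additionally clamps at 0. Published
count-to-mass equations are instrument- and aerosol-specific, so the
package does not hard-code one: the default model (0.01 µg/m³ per count
unit, single segment) is a placeholder for plumbing and simulation, and
real studies must supply their own coefficients. The map's inverse (used by
the simulator) takes the smallest channel value achieving a target
concentration, clamping below the map minimum and extrapolating along the
final segment.

## Delivery semantics

The client implements at-least-once delivery: every minute record is
persisted in an sqlite buffer, every flush attempts each pending batch once
(up to 60 records per request, 10 s timeout, one flush per minute — all
configurable), and only records the server *acknowledges* are removed. The
server deduplicates on (device, minute) and acknowledges duplicates as
success, so the stored dataset is effectively exactly-once even when a
timeout fires after the server already received the batch. Invalid records
and malformed batches are rejected *with* acknowledgement, so a client
never retries poison data. Buffer capacity defaults to 9000 records
(> 6 days), matching the instrument's own memory, with oldest-first
eviction and a persisted eviction counter. `legacy_mode` bypasses the
buffer — one attempt per record, failures dropped — to reproduce the
behaviour of a deployment without store-and-forward, where transient link
failures translate one-for-one into lost minutes.

Consequences relied on by the tests: with buffering, any fault plan whose
connectivity returns before the session ends yields zero loss (provided
buffer capacity covers the outage); in legacy mode the lost fraction equals
the injected outage fraction exactly for deterministic plans.

## Simulator

The generator emulates a monitored home at one-minute resolution:

    PM(t) = [ baseline + Σ_events peak · 2^(−(t − start)/halflife) ] · exp(ε_t),
    ε_t ~ N(0, σ_log²)

Each smoking episode is an instantaneous rise followed by exponential decay
— the single-compartment picture of indoor aerosol removal by air exchange
and deposition; the default half-life of 30 min sits in the range typical
of closed living rooms. Noise is multiplicative lognormal because indoor PM
is non-negative and right-skewed. Defaults: baseline 7 µg/m³ (the level
observed as the median of smoke-free homes), σ_log = 0.3; the stock
smoking-home profile adds four episodes per day with peaks of 250–500
µg/m³, which reproduces the qualitative field signature of arithmetic mean
far above median. Counts are obtained by inverting the calibration model
(so simulator and calibration agree by construction) with the large channel
a fixed 3 % of the total.

Transport faults are scheduled outage windows (half-open minute intervals
on the session timeline, during which every request fails), independent
per-request drops with probability `p`, and a fixed latency compared to the
client timeout; a too-slow request is delivered *before* the timeout is
raised, deliberately exercising the deduplication path. Time is simulated —
a shared clock advanced to each record's timestamp — so thousand-minute
sessions run in milliseconds and determinism is exact given the seeds.

What the simulator does not model: aerosol physics (coagulation,
deposition-rate dependence on size, ventilation dynamics), instrument drift
and humidity artefacts, correlated network degradation. Passing tests
therefore demonstrate the correctness of the pipeline's contracts
(delivery, deduplication, accounting, statistics), not the field accuracy
of any particular calibration.

## Analysis

**Loss audit.** Server-held and locally-held series are matched on exact
minute keys; the lost fraction's denominator is the *local* record count
(the instrument memory is the reference). Outage runs are maximal blocks of
consecutive missing minutes on the 1/min grid; the server's gap reports use
the same convention over half-open query windows `[t0, t1)`.

**Agreement.** Bland–Altman on paired per-home summaries: differences
A − B, SD on n−1 degrees of freedom, limits of agreement mean ± 1.96·SD,
plotted against pairwise arithmetic means on a log x-axis (home
concentrations span orders of magnitude).

**Exact tests.** Both small-sample tests are computed from their exact
permutation nulls via dynamic programming over rank sums, which enumerates
the same assignments as brute force (the suite verifies equality against
literal enumeration on hundreds of random instances, and against scipy's
exact methods on tie-free data):

* *Wilcoxon signed-rank*: zero differences dropped before ranking (the
  original convention, and the default of mainstream exact
  implementations), mid-ranks on |d|, two-sided p as the deviation tail
  P(|W − n(n+1)/4| ≥ |w_obs − n(n+1)/4|) over all 2^n sign vectors. All
  differences zero ⇒ p = 1 by convention. Mid-ranks are multiples of ½, so
  doubling makes the DP exact in integers.
* *Mann–Whitney U*: U from mid-ranks of the pooled sample; two-sided p is
  twice the lower-tail probability of min(U1, U2) under the classical
  tie-free null (all C(N, n1) rank splits), capped at 1 — the convention of
  standard exact tables, which reproduces the published eight-home p-values
  (0.686 and 0.486) on data containing a tie. A tie-aware variant that
  permutes the observed mid-ranks is available behind `tie_aware=True`
  (pooled n ≤ 22).

**Summaries.** Per-home arithmetic mean and median (mid-point convention
for even n) of minute PM2.5; across homes, geometric means exp(mean(ln x))
requiring strictly positive inputs. Reported values are rounded to 2
decimals (concentrations) and 3 decimals (p-values); all internal
computation is at full precision.

## Problem sizes and numerical choices

Simulated sessions in the tests and the acceptance script use 1000–2000
minutes per home and eight homes for the agreement study — large enough
that binomial fluctuations in drop-rate checks are small (the p = 0.2
dropout check allows ~4σ ≈ 3.6 % slack) and small enough that the whole
suite runs in seconds. Enumeration oracles are exercised at n ≤ 10 (2^10
sign vectors; C(10,5) splits). Tolerance 1e-9 guards float comparisons at
tail boundaries in both exact tests; equality assertions elsewhere are
exact because the quantities are integer-valued by construction.

## Known limitations

* The placeholder calibration is linear; real count-to-mass equations
  saturate at high loadings. Conclusions about µg/m³ magnitudes from the
  simulator carry the placeholder's units, not a validated calibration.
* The field deployment's own loss statistics (fractions of a percent over
  44 days, longest outage under two hours) depend on its unpublished raw
  minute data; the package reproduces the published *summary-level* results
  exactly and covers the reliability claims with deterministic simulated
  counterparts instead.
* The ingest HTTP layer is single-process stdlib; it is a functional
  endpoint for monitors, not a hardened multi-tenant service.
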