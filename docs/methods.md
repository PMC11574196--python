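# Methods

## The segregation model

A cell's mitochondrial content is a single unbranched array of `n`
mtDNA copies, each copy one of two neutral variants (0/1).  The array
abstraction encodes the one biological constraint a random-pick model
misses: copies lying in the same stretch of the tubular network tend to
be inherited together.  Three stochastic moves act per synchronous
generation, in this order:

1. **Relaxed replication to capacity.**  While the cell holds fewer
   than `n` copies, one existing molecule is drawn uniformly at random
   (with replacement across steps, so the same molecule may template
   repeatedly — a Pólya-urn scheme) and an identical copy is inserted
   immediately to its right.  Replication is a martingale in the
   variant fraction but adds variance; there is no degradation, death
   or selection.
2. **Fission–fusion shuffling.**  The array is cut at `nspl − 1`
   distinct internal boundaries drawn uniformly at random, and the
   `nspl` fragments are concatenated in uniformly random order, never
   reversed.  `nspl = 1` leaves the array untouched; `nspl = n`
   reduces inheritance to hypergeometric sampling.
3. **Division.**  The daughter takes the first `ndau` copies
   (`1 ≤ ndau ≤ ⌊n/2⌋` — the daughter receives the shorter part).
   Because shuffling has already randomised fragment order, the fixed
   left-end convention is distributionally equivalent to a random end
   and simplifies testing.

Snapshots are recorded with every cell replicated back to capacity, so
generation `g` holds `2^g` cells of `n` copies at `t = 1.5 g` hours.
Cells are scored homoplasmic either strictly (variant fraction exactly
0 or 1) or with the empirical h thresholds (≤ 0.33 or ≥ 0.71) applied
to true fractions.  Fragment boundaries are re-drawn every generation;
replication happens at cycle start (equivalently: cycle end, before
the snapshot).  All randomness flows from one seeded
`numpy.random.Generator`; replicate `r` of a configuration uses
`seed + r`.

Founder layouts at fraction `f` of variant 1 (`k = round(n·f)` copies):
`mixed` interleaves maximally (`0101…`), `semi_mixed` uses short
alternating runs (`0011100011` at `n = 10`), `non_mixed` two blocks
(`0000011111`).  A founder with zero copies of one variant is legal
but logged as degenerate.

## Fitting (ndau, nspl)

The observable is the homoplasmic fraction at t = 0, 1.5, …, 7.5 h.
The empirical curve is smoothed by a least-squares logistic
`L / (1 + e^{−r(t−t0)})` (0 < L ≤ 1, r > 0; a flat curve leaves r
unidentifiable and is flagged instead of fitted).  For every grid pair
the simulator runs `n_replicates` (default 10) populations with shared
seeds, and the summed squared distance between replicate-mean and
target fractions is taken over t = 1.5–7.5 h only: every heteroplasmic
founder has fraction 0 at t = 0, so that point carries no information
(it still enters the sigmoid fit).  Ties on the minimum break toward
smaller `ndau`, then smaller `nspl`.  Whether the target is the
smoothed or raw curve, and whether replicate curves are averaged
before the SSE or per-run SSEs are summed, are both switchable;
defaults are smoothed and average-first.  Identifiability is limited
by design: pairs trading more transmitted copies against fewer
fragments form a low-SSE ridge with a negative ndau–nspl association,
so the result object exposes the full surface and the ridge, not just
the argmin.

## Quantification and classification

Per channel and frame: subtract the cell-free background, floor at
zero (intensities are physical), divide by cell volume, then divide by
the per-frame median over all segmented cells, which cancels
photobleaching and acquisition drift.  `h = I_mKate2/(I_NG + I_mKate2)`
is invariant under any common positive rescaling of both channels.
Cells with zero corrected signal in both channels get an undefined h
and are excluded from distributions rather than assigned 0.5.  Note
that the median-normalization step presumes a mixed population: in a
fully homoplasmic population it maps both channels to median 1 and
pushes h toward 0.5, so homogeneous controls should be scored on
volume-corrected intensities (the dark/bright valley threshold exists
for exactly that situation).

The trimodal h distribution at the final timepoint is fitted with a
3-component Gaussian mixture by EM — deterministic initialisation at
the 1/6, 3/6, 5/6 sample quantiles with equal weights and the pooled
variance, tolerance 1e−8, at most 500 iterations (the per-peak
single-curve fits this replaces are not reproducible without the
original procedure).  Homoplasmy thresholds are the crossings of
adjacent weighted component densities, solved in closed form
(quadratic in x; bisection fallback), keeping the root strictly
between the means.  Classification uses strict inequalities, so
boundary values count as heteroplasmic and the three classes partition
[0, 1].  Default thresholds are 0.33/0.71 (the 0.35/0.70 variant is
configurable).  The valley threshold for 24-h dark/bright scoring is
the minimum of a Silverman-bandwidth Gaussian KDE between the two
highest modes (local maxima above 10 % of the global maximum);
unimodal input is an error.

## Lineage correlations

Tracking output defines a pedigree (networkx digraph; one root per
population, forests flagged).  Each cell's h is sampled at its own
first frame with bud-to-mother volume ratio ≥ 0.2 (inclusive, earliest
qualifying frame; cells that never reach the stage are excluded).
Four relations are formed per population — mother vs daughter (M–D),
vs granddaughter (M–GD), and vs herself at the daughter's or
granddaughter's sampling time (M–M_D, M–M_GD) — and summarised by
Spearman rank correlation (average ranks on ties; relations with < 3
pairs or a constant vector are dropped).  Relations are compared by a
two-sided paired t-test across populations, pairwise-complete;
identical vectors give t = 0, p = 1 by convention.  Under strongly
asymmetric transmission (`ndau ≪ n/2`) the generator reproduces the
expected ordering M–M_D > M–D > M–GD.

## Kinetics

Translation-shutoff series are fitted with
`I(t) = A·e^{−kt} + C` by nonlinear least squares; the additive offset
`C` models the bottom plateau (cellular autofluorescence plus
background) that the signal settles on.  `k` is reported per hour with
its standard error from the fit covariance; flat series or fitted
`k ≤ 0` are flagged no-decay rather than failed.  The nucleoid-transfer
estimate is `foci_rate / window × exchange` with defaults 5 min and
47.5 min; at the canonical rate of 1.18 crossings per window it gives
11.2 nucleoids per division, reported to one decimal.

## The synthetic-data generator

The generator emulates what segmentation/tracking tools export from the
time-lapse experiments, on top of a ground-truth simulated lineage.
What it models:

* **Copy-count trajectories.**  Each 1.5-h cycle, the mother transfers
  the daughter's allocation across the bud neck during the first
  47.5 min (the content-exchange window) while replenishing toward
  capacity — dipping below `n` and recovering by cycle end — and the
  bud's count rises from 0 to its allocation, then to `n` by division;
  mother + daughter hold exactly `2n` at cycle end.  Buds appear at
  cycle start (budding initiation coincides with the exchange window)
  and grow linearly to 55 % of the mother volume at separation; a
  newborn daughter grows to full size over her first cycle.
* **Fluorescence.**  Each variant drives its reporter through
  `dP/dt = gain·copies − k·P` (exact exponential-integrator steps;
  synthesis zero inside a configurable chloramphenicol window; protein
  initialised at steady state), so fluorescence lags copy number with
  the measured turnover `k = 0.31 h⁻¹` — the "fossil protein" effect.
  Observed intensity is `P/volume`, attenuated per frame by the
  photobleaching factor, plus cellular autofluorescence, multiplicative
  Gaussian noise, and an additive per-frame background whose true value
  is recorded in the `bg_*` columns (the cell-free measurement).
* **Event streams.**  Foci crossings are i.i.d. Poisson at 1.18 per
  5-min window per mother–bud pair (93 pairs by default); an optional
  per-division dropout probability zeroes a daughter lineage's mtDNA
  (emulating ∆abf2-like loss, which inflates the intensity CV).

Defaults and why: turnover 0.31 h⁻¹ (the measured decay constant);
frame interval 15 min and 1.5-h generations (the imaging and growth
conditions); synthesis gain 40 a.u. per copy per hour and mother volume
40 fL, giving a per-volume signal of ~50–100 a.u. for 16–32 copies —
an order of magnitude above the 5 ± 0.5 a.u. background, as in
well-exposed movies; autofluorescence 20 a.u., chosen so homoplasmic h
peaks land near 0.15/0.85 (autofluorescence in the "absent" channel is
what keeps empirical peaks off 0 and 1); photobleaching 0.995 per
frame and measurement CV 5 %, typical mild values.  Every observable is
a deterministic function of (config, seed), and ground-truth copy
counts always accompany the observable tables.

What the generator does *not* emulate: images themselves, segmentation
or tracking errors, asynchronous cell cycles, cell-size-dependent copy
numbers, protein maturation delays, or spatial network structure.
Passing tests therefore validate the analysis logic and its statistical
behaviour on data with the assumed structure — not the upstream
measurement process.

## Numerical choices and degenerate inputs

Corrected intensities are floored at 0; frames whose corrected channel
is all zero are normalised to 0 with a warning rather than divided by
zero.  The EM fit refuses < 30 points, values outside [0, 1], or
constant input; non-convergence raises with diagnostics (expected on
deliberately unimodal data, where a 3-component mixture is
unidentifiable).  `ndau = 0` is rejected (a daughter must exist); odd
`n` caps `ndau` at `⌊n/2⌋`.  Curve fits use scipy's
trust-region-reflective least squares with bounds (`0 < L ≤ 1`,
`r > 0`; `C ≥ 0`) and data-driven starting values.

## Known limitations

* The simulator's per-generation heteroplasmy variance is governed by
  the Pólya replication scheme plus contiguous-block inheritance; with
  the documented conventions it segregates faster than some published
  accounts of comparable parameter settings, and its segregation speed
  is not invariant under copy-number rescaling at fixed transmitted
  fraction (the Pólya variance contribution scales as ~1/n).  The SSE
  surface and ridge are the trustworthy outputs; absolute parameter
  values should be read with the same caution as in any
  simulation-based fit.
* Generations are fully synchronous; real lineages desynchronise.
* The mixture-based thresholds assume three resolvable modes; sparse
  or early-timepoint data will not support them.
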