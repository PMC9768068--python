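# Methods

This note records the models, conventions and design choices behind
`hrvaging`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Preprocessing chain

Input files are single-column text: either RR intervals or monotone
R-peak times, in seconds or milliseconds.  Units are auto-detected by
magnitude (median < 10 ⇒ seconds); a monotone increasing column is taken
as beat times and first-differenced.  All internal computation is in ms.

1. **Range filter.**  Intervals outside 50–240 ms (250–1200 bpm, the
   physiological murine range) are replaced by linear interpolation
   between the nearest in-range neighbours.  Linear interpolation is the
   simplest scheme that preserves the local mean; out-of-range values at
   the sequence edges have no neighbour on one side and are dropped
   rather than extrapolated.  Interpolants always lie within the range,
   so the filter is idempotent.
2. **Ectopic removal.**  Intervals beyond ±2 sample SD of the segment
   are deleted in a single pass.  The pass is deliberately not iterated:
   re-applying a trimming rule to its own output shrinks the SD each
   round and can cascade on heavy-tailed data, so repeated application is
   *not* a no-op and is avoided by design.
3. **Windowing.**  Non-overlapping windows accumulate beats while the
   running duration is below 180 s (the period matching the lower VLF
   edge), so a window may exceed 180 s by at most one interval.  The
   first 120 s of blocked recordings are discarded (drug-onset
   transients).  A trailing remnant shorter than half a window is
   discarded — long enough fragments still resolve the spectrum, shorter
   ones bias band powers.  Windows with fewer than 50 beats are dropped.
4. **Stationary segment.**  Time-domain/fragmentation/nonlinear metrics
   use one 512-beat segment (spectral and QC stages use the 3-min
   windows): among all contiguous runs of 512 beats, the one minimising
   |least-squares slope| / SD of the run is selected; ties resolve to the
   earliest start.  A run whose best score still implies a drift larger
   than 3 SDs across its length is flagged non-stationary.

## Metric conventions

Sample statistics use the N−1 denominator throughout.  Zero increments
(ΔNN = 0) count as inflection points (the defining condition is ≤ 0),
break acceleration/deceleration runs, and break alternation runs
(alternation requires a strict sign change every beat).  Segment
"length" for the short-segment metric PSS counts NN intervals — a run of
k increments spans k + 1 intervals — with the threshold at 3 intervals.
PIP uses the full interval count N as its denominator.  Sample entropy
uses m = 2, r = 0.2·SD, Chebyshev distance, self-matches excluded, and
the same N − m template starting points at both lengths; a zero-variance
segment returns 0 by convention.  DFA is first-order (integrate the
mean-centred series, linear detrend per non-overlapping box, RMS
fluctuation), with α₁ fitted over 4–15-beat boxes and α₂ over 16–64, the
conventional short/long HRV ranges.  Small boxes carry the well-known
upward DFA-1 bias (white noise measures α₁ ≈ 0.59 rather than 0.5), so
calibration checks against known processes use the asymptotic 16–64
range; α₁ remains a comparative, not absolute, index.

Poincaré dispersions follow SD1² = Var(ΔNN)/2 and
SD2² = 2·Var(NN) − Var(ΔNN)/2, which satisfy SD1² + SD2² = 2·Var(NN)
exactly and agree with the ±45° principal-axis projections of the lag-1
return map up to O(1/N) edge effects.

## Spectral estimation

The irregularly sampled RR series is cubic-spline interpolated against
cumulative beat time and resampled at 20 Hz — comfortably above twice the
5 Hz HF edge — then mean-centred.  The default estimator is Burg's
autoregressive method at order 30, evaluated on a 0.002 Hz grid (fine
enough to resolve the VLF band) and rescaled so that the integral over
[0, Nyquist] equals the tachogram variance (Parseval contract).  The
Welch path is the independent cross-check of that contract and therefore
is *not* rescaled; it uses rectangular, non-overlapping segments sized to
tile the series, for which the averaged-periodogram integral equals the
series mean square by construction.  Band powers are trapezoidal
integrals with edge closure by interpolation, so refining the grid
changes them by < 1%.  LF% and HF% are normalised by (total − VLF); VLF%
by total power.  The spectral slope β is the least-squares log–log slope
over 0 < f ≤ 0.152 Hz.

Shifting all intervals by a constant leaves the variance and hence the
total power unchanged, but also stretches the beat-time axis, so
modulation frequencies move — exact shift-invariance of the whole
spectrum is impossible for a tachogram-based estimate and is not
claimed.

## Blockade quality control

The criterion works entirely on window spectra.  The representative peak
frequency is the mean over *basal* windows of the HF-band argmax (the
peak search is restricted to 1.24–5 Hz; a full-spectrum search is
available by passing an explicit band).  Each mode's peak height is
normalised by (summed total power × number of windows), exactly as the
defining equations read, even though the sum already runs over windows —
the double normalisation cancels in the ratio of modes when window
counts match and otherwise weights the longer (blocked) recordings down,
which is the intent of comparing *per-window* quantities.  PSD values at
f̄ are taken at the nearest grid point.  Ratios exactly at 0.5 / 0.7 fail
(strict inequalities).  A missing state makes the pair undecidable:
excluded from the pass-rate denominator and from downstream analysis in
both states.

## Longitudinal models

Metrics are modelled per state in two age periods, 6–21 and 21–30
months, with the boundary visit in both — trajectories bend too sharply
at ~21 months for one polynomial.  The full model is a quadratic with
random intercept, slope and curvature per mouse, estimated by REML
(statsmodels MixedLM; L-BFGS with BFGS and Powell fallbacks).  Age is
centred at the period midpoint for conditioning; coefficients and their
delta-method standard errors are reported on the original months scale.
If the random-curvature fit fails to converge or its covariance is
singular (smallest variance < 1e-8 of the residual), the b_i2 term is
dropped; with fewer than three distinct ages the model is linear.  When
a retained random-effects covariance is singular, mouse-level deviations
are not identifiable and the BLUPs are zero.

Rates are exact derivatives of each mouse's fitted trajectory, evaluated
by default at 6 months (early) and 24 months (late), where the rate
variability across mice is compared between periods with the
Pitman–Morgan test, t = (s₁² − s₂²)√(n−2) / (2 s₁ s₂ √(1−r²)) on n−2 df,
algebraically identical to testing cor(x+y, x−y) = 0.

The autonomic signature is intrinsic (abk) minus basal — positive means
blockade lengthens the RR interval — with a sign switch exposed for the
opposite convention.  Baseline normalisation divides each mouse/metric
trajectory by its 6-month value and skips trajectories with a missing or
zero baseline.

The loess smoother is a hand-rolled local quadratic with tricube
weights over a span of 0.75 of the points (the library smoother is
locally linear and provides no uncertainty): pointwise fits are linear
in y, so the 95% band comes from σ̂‖l(x)‖ with σ̂² the residual variance
on n − tr(L) effective df.  Local quadratics reproduce straight-line
data exactly.

Repeated-measures ANOVA on age uses the exact balanced F test where the
design is complete and a random-intercept mixed model with a Wald test
on the age contrasts otherwise.  Rate clustering is agglomerative with
distance 1 − |Pearson r| and average linkage — the absolute value makes
mirror-image metrics (e.g. %HF and %VLF rates) cluster together — with
flat clusters cut at height 0.6 by default (|r| ≈ 0.4 average between
joining groups, the mid-height of a 0–1 dendrogram); dendrograms are
serialised as Newick.  Correlation tables report raw two-sided Pearson
p-values with pairwise-complete deletion (a Benjamini–Hochberg option is
deliberately not applied by default, matching the reporting convention
for these tables); the combined table carries the early period above the
diagonal and the late period below.

## Synthetic cohort: what it emulates, and what it does not

Each recording is built as mean level + deterministic modulations +
long-range noise + structured alternans + outliers:

* **Mean RR**: 100 ms at 6 months, flat to 21 months, then a quadratic
  rise reaching +50% (intrinsic) or +20% (basal) at 30 months.
* **Aging-rate latent**: one per-mouse factor γ ~ N(0, 0.3), clipped to
  [−0.8, 2], dilates effective age beyond 21 months and drives *all*
  late-life schedules (mean-RR rise, HF decline, VLF growth, α₂ rise,
  alternans).  This shared latent is what makes the late-period rates of
  mean RR, %VLF, %HF, α₂ and PAS correlate across mice, the structure
  the clustering stage is designed to detect.  Effective age is capped
  at ~34 months so the fastest ager's RR stays physiological, and the
  schedules extend to 34 months so fast agers keep differentiating
  rather than pinning at the 30-month value.
* **HF modulation**: a respiratory sinusoid, 6 ms at 6 months, whose
  amplitude declines with age and whose frequency slows from 2.5 Hz
  toward ~2 Hz (breathing slows in old mice, which also keeps the
  modulation resolvable as the beat rate falls); blockade retains 25% of
  its amplitude (~6% of its power) — enough residual intrinsic
  variability to be realistic while keeping young basal HF% at least
  twice the blocked value.
* **Slow structure**: a 0.05 Hz VLF oscillation with amplitude rising
  1 → 4.5 ms across life (driving %VLF and total power upward), and
  long-range 1/f^β noise (2 ms, near-constant amplitude) whose DFA
  target follows 0.9 → 1.5.  The noise is synthesised spectrally with
  PSD ∝ f^(−β), β = 2α − 1, for which DFA-1 measures α = (β+1)/2
  continuously across the stationary and non-stationary regimes.  A
  5-beat moving average smooths beat-scale roughness — raw differenced
  noise alternates sign on most beats, which real pacemaker output does
  not.
* **Alternans**: spontaneous ABAB runs are first broken (single-beat
  midpoint repairs), then alternation runs (length 4 + geometric) are
  injected on linear local baselines with zero-increment guard beats
  until the target coverage (5% of beats at 6 months rising steeply
  after 21) is reached, so the measured PAS tracks the knob to within a
  few points.  The alternation amplitude scales with the local increment
  size and shrinks as 1/√coverage, so the total alternans power — and
  hence its high-frequency contribution — stays roughly constant as PAS
  grows; without this, rising alternans coverage would push HF% back up
  late in life.
* **Outliers and dropout**: ectopic shifts of ±~60 ms at rate 0.002 per
  beat; survival is certain through 24 months and then decrements with a
  0.25 per-visit hazard, reproducing a long-lived-cohort design with a
  shrinking late-life n.
* **Durations**: 360 s basal and 900 s blocked recordings (blocked runs
  are recorded much longer in practice, and their first 120 s are
  discarded) — yielding two 3-min windows per basal and four per blocked
  recording.

What the generator does **not** emulate: respiratory-frequency drift and
cardiorespiratory coupling, circadian or activity-driven nonstationarity,
true arrhythmias (beyond symmetric ectopic shifts), state-dependent
noise colour, or any biophysical pacemaker-cell model.  Passing tests on
these cohorts therefore demonstrate that the pipeline recovers known
structure of this kind — not that it would be robust to every artefact
of real telemetry data.

A second, table-level generator draws metric values directly from the
quadratic mixed model with chosen fixed effects, random-effect SDs and
residual σ, for testing the longitudinal machinery against exact truth.

## Numerical choices and degenerate inputs

Metrics requiring more data than a window holds return NaN rather than
raising, so short windows yield the defined subset.  SD ratios, spectral
percentages and entropy return NaN markers on degenerate input (zero
variance, zero denominators) instead of exceptions.  Band integration
closes band edges by interpolation.  The AR spectrum of a constant
series is identically zero.  Random streams are derived from
(seed, mouse, age, state) via CRC-hashed seed sequences, so any
recording can be regenerated in isolation and cohorts are byte-identical
across reruns.

## Problem sizes used by tests and the acceptance script

Oracle comparisons run on 100 random sequences of ≤ 300 beats; DFA
calibration uses 20 seeds at N = 2¹⁴; mixed-model recovery uses 200
cohorts of 30 mice × 6 ages (the acceptance script reports a 50-cohort
summary of the same study); statistical calibration uses 1000 null
replicates; the end-to-end study runs the full 56-mouse default cohort.
Example scripts use reduced cohorts (5–10 mice) chosen to finish in
about a minute while still exercising every stage.

## Known limitations

* α₁ is reported with the standard small-box bias; no bias correction is
  applied.
* The Burg/Welch agreement contract is on total power; the two
  estimators differ in peak sharpness by construction.
* MixedLM occasionally converges to a boundary (zero random-effect
  variance) on small or weakly informative cohorts; rates then collapse
  to the fixed-effect rate, and such metrics drop out of rate clustering
  as zero-variance columns.
* The loess band is a pointwise Gaussian band on the linear-smoother
  variance; it ignores smoothing bias and between-mouse correlation of
  repeated measures.
* QC pass rates on synthetic cohorts are near 100% by construction
  (the generator's blockade is complete); they are not a model of any
  laboratory's empirical disqualification rate.
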