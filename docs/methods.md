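# Methods

## The validation problem

A temperature-based algorithm produces one estimated day of ovulation
(A-EDO) per menstrual cycle from the daily overnight BBT series. The
reference standard is the urinary LH surge: the reference estimated day
of ovulation (LH-EDO) is the day after the surge, since ovulation
typically follows the surge within about 24 hours. Validation has two
levels:

1. **Cycle level (concordance).** The difference d = A-EDO − surge day
   is tabulated per cycle; the estimate agrees with the reference when
   d ∈ [−1, +3], i.e. the A-EDO lies within ±2 days of the LH-EDO.
   Larger d is a *delayed* estimate, smaller an *early* one. The mean,
   sample standard deviation (n−1) and integer histogram of d are
   reported.
2. **Day level (diagnostic metrics).** Each cycle day is labelled by
   membership in the predicted fertile window versus the reference
   fertile window: TP (both), FP (predicted only), FN (reference only),
   TN (neither). All days of every evaluable cycle are classified,
   including days with missing temperatures — windows are defined on
   day indices, not on recorded values. Pooled counts give sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, PPV
   TP/(TP+FP) and NPV TN/(TN+FN). A table with FP = FN makes
   sensitivity equal PPV and specificity equal NPV identically; the
   suite asserts this as a property.

## Windows

Two closed-interval conventions are implemented, both clipped to
[1, cycle length]:

| mode | reference window | predicted window | width |
|---|---|---|---|
| `SURGE10` (default) | [surge−6, surge+3] | [A-EDO−7, A-EDO+2] | 10 days |
| `WILCOX6` | [LH-EDO−5, LH-EDO] | [A-EDO−5, A-EDO] | 6 days |

`SURGE10` is the ±2-day accuracy band around the ovulation estimate
plus the five preceding days (sperm survival); when A-EDO = LH-EDO the
two SURGE10 windows coincide day for day, so a perfect detector yields
FP = FN = 0 — the suite asserts this window-identity invariant on
random cycles. `WILCOX6` is the classical six fertile days (ovulation
day plus the five preceding). Published day-level denominators in this
literature are closer to six fertile days per cycle than ten; both
modes are therefore exposed as a pipeline parameter rather than the
package resolving the discrepancy silently.

The peri-ovulatory period (A-EDO ±2 days) is provided as a separate
helper.

## Confidence intervals

All proportions carry two-sided exact Clopper–Pearson intervals
(inverted binomial tails, computed via the beta quantile form in
statsmodels), with boundary cases pinned exactly (lower bound 0 at zero
successes, upper bound 1 at full successes). The choice is not
cosmetic: on the worked-example counts the Clopper–Pearson bounds
reproduce the reported intervals at one-decimal rounding where Wald
fails outright and Wilson differs in the last digit of the specificity
upper bound. Percentages are formatted to one decimal with
round-half-up, matching the convention of published tables. An
independent bisection inversion of the binomial tails (scipy.stats.binom)
serves as the test oracle at 1e-9 agreement.

## The step-fit detector

The deployed commercial algorithms in this space are trained neural
networks; this package instead ships a fully transparent changepoint
detector with the same contract (daily temperature series in, calendar
day out), behind an interface that admits other detectors.

Preprocessing: interior missing days are linearly interpolated between
the nearest recorded neighbours and edge gaps take the nearest recorded
value (`numpy.interp`); the complete series is padded to exactly 35
values by repeating the final observation, a fixed-length input
convention only — padded days are excluded from all fitting, and the
suite asserts the estimate is identical to a fit on the observed days
alone.

Detection: for every candidate rise day τ in
[`search_start`, L − `search_end_offset`] (defaults 6 and 4, so both
segments always hold several days), the series is split into a low
segment (days < τ) and a high segment (days τ..L) and the two-mean fit
is scored by residual sum of squares, computed in one vectorised pass
via prefix sums; RSS(τ) = Σx² − n₁m₁² − n₂m₂². The minimising τ (ties
to the earliest) is the estimated first elevated day and the A-EDO; the
fitted step m₂ − m₁ must reach `min_shift_c` (default 0.10 °C, the
smallest luteal plateau amplitude reported in practice) or the cycle is
NOT_DETECTED and excluded, with the best fit retained as a diagnostic.
The estimator is location-invariant and recovers a noise-free step
exactly for any amplitude ≥ `min_shift_c`. An exhaustive direct-sum
scan is the test oracle.

The A-EDO convention is the first day of the elevated segment — one day
after the surge in a concordant cycle, consistent with reference
estimates that place ovulation the day after the surge.

## Eligibility and exclusions

Screening requires temperature coverage ≥ 80%, length 24–35 days and,
when estimable, a luteal phase of 9–20 days. The luteal length is taken
as length − LH-EDO + 1 when a valid surge exists, else
length − A-EDO + 1 when the detector fired, else unknown (the criterion
then passes vacuously); the reference estimator is preferred because it
is the study's anchor. Cycles with no positive LH test, an ambiguous
positive pattern (anything other than one singleton or one consecutive
pair), or no detected temperature rise are excluded from metrics and
concordance. Nothing is dropped silently: every run emits a manifest
whose counts reconcile exactly (read = eligible + ineligible;
eligible = evaluable + excluded-with-reason).

## Luteal profiling

Anchored on the surge day a (fallback: A-EDO), with baseline = mean
temperature over days [a−7, a−1] and plateau = mean over
[a+3, min(a+9, L)]:

- **amplitude** = plateau − baseline; classes LOW < 0.25 ≤ MODERATE
  ≤ 0.40 < HIGH (°C). The anchor amplitudes seen in practice are
  ≈0.1–0.2, ≈0.3 and ≈0.5 °C; the cuts bisect those anchors and are
  configurable, as are all thresholds below — the underlying classes
  are qualitative and these numeric boundaries are conventions of this
  package.
- **rise class**: RAPID iff the half-amplitude level
  (baseline + amplitude/2) is first reached within 2 days after the
  anchor, else SLOW_DELAYED.
- **premature decline**: mean of the last 3 cycle days below
  half-amplitude while amplitude ≥ 0.15 °C (no decline is claimed when
  there was nothing to decline from).
- **fluctuation index**: standard deviation of luteal residuals about a
  3-day centred moving average; FLUCTUATING above 0.10 °C. Detrending
  makes any smooth plateau — flat, ramped or declining — score ~0, so
  the index isolates day-to-day irregularity.

## The synthetic generator

`SimulationConfig` defaults define the emulated population: cycle
lengths uniform on 24–35 days and luteal lengths uniform on 9–20 days
(redrawn until at least 9 follicular days remain, which also keeps
every default-drawn cycle eligible); per-cycle baseline N(36.40,
0.10²) °C; plateau amplitude 0.15/0.30/0.50 °C with equal probability;
a 0.10 °C nadir dip on the two pre-ovulatory days; i.i.d. Gaussian
noise with s.d. 0.05 °C (an AR(1) option, default off, adds plateau
autocorrelation); 5% missing days; LH positive on the surge day
(= ovulation − 1) with a 10% chance of a consecutive double positive;
3% delayed-rise and 3% early-rise discordance shifting the temperature
rise ±3 days from ovulation. Plateau shapes mix RAPID (step at the
rise day), SLOW_DELAYED (linear 7-day ramp) and PREMATURE_DECLINE
(step, then a fall to baseline over the last 3 days) at 0.70/0.15/0.15 —
rapid-dominant because slow rises and premature declines are presented
in this literature as minority patterns. Emitted temperatures are
quantised to 0.01 °C (device-class resolution; makes CSV round-trips
exact). Everything is a deterministic function of the seed.

What the generator does *not* emulate: hormone kinetics, within-woman
cycle-to-cycle correlation, environment-driven artefacts, pregnancy
cycles, or the heavy-tailed noise of real skin sensors. Passing
recovery tests on this cohort therefore demonstrates correctness of the
pipeline arithmetic and reasonable detector behaviour under the stated
noise model — not field performance of any device.

## Experiment design in the tests and acceptance script

Parameter-recovery experiments (rise-day recovery, end-to-end
sensitivity/specificity, amplitude-class recovery) condition the
generator on the RAPID step shape: a 7-day linear ramp has no
well-posed single changepoint — the least-squares fit lands mid-ramp,
about +2.6 days after the ramp start — so "the true rise day" is only
an exact target for the step template (this is also the only shape for
which zero noise implies exact recovery). The discordance-labelling
check likewise uses step-shaped cycles so that the discordance mode is
the unique mechanism producing delayed or early estimates; on the
default mixture, slow-ramp cycles are a second genuine source of
delayed estimates and the cross-tabulation against ground truth would
conflate the two. Cohort-level summaries (mean difference, concordance
proportion) use the full default mixture.

Problem sizes: unit tests use cohorts of 20–300 cycles; oracle
equivalence and recovery checks use 500; marginal and concordance
checks 1000. The full suite runs in well under a minute.

## Known limitations

- The step detector is retrospective (whole-cycle); prospective
  day-by-day prediction is out of scope.
- A slow, gradual luteal rise genuinely delays the changepoint
  estimate; this is a property of any two-level fit, reported honestly
  by the concordance categories rather than corrected.
- Exact binomial intervals are conservative (coverage ≥ nominal),
  which is the standard trade-off accepted for validation tables.
- Luteal class thresholds are conventions; comparisons across studies
  using different boundaries are not meaningful without recalibration.
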