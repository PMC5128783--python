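# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open.

## Study design emulated by the generator

Three farms × 12 cows, four one-week experimental periods: a baseline
week (B) before the robot scraper operates and three test weeks
(T1–T3). HRV and behavior are measured on days 2 and 4 of each
period; fecal cortisol-metabolite samples are taken on days 2, 3
and 5. Behavior is observed 14 h per day (midnight–4 a.m.,
10 a.m.–3 p.m., 7 p.m.–midnight); HRV windows for active cows come
from noon–3 p.m. and for resting cows from 9 p.m.–midnight; robot
proximity windows from 10 a.m.–3 p.m. All clock intervals are
half-open `[start, end)` in timezone-naive local time, so abutting
windows never double-count.

## Interbeat intervals

**Generative model.** Intervals are i.i.d. Gaussian with mean
`mean_ibi` (750 ms active, 900 ms rest) and sd `true_rmssd/√2`,
truncated to (0.5, 1.5)·`mean_ibi`. Because
`E[(x_{i+1}−x_i)²] = 2σ²`, the long-run RMSSD equals `true_rmssd`
by construction. This is deliberately not a physiological point
process (no respiratory sinus arrhythmia, no autocorrelation): the
analysis consumes only the time-domain RMSSD statistic, and the i.i.d.
model keeps its expectation analytically controllable. Passing tests
therefore say nothing about frequency-domain structure in real herds.

**Artifact injection** inverts the five-type correction taxonomy:
missed beats merge two adjacent intervals; spurious beats split one
interval at a uniform(0.3, 0.7) fraction; boundary jitter moves one
beat time by ±30% of the interval (above the 20% detection threshold
by design); single outliers scale one interval by a factor outside
[0.8, 1.25]. Every mechanism conserves total beat-train duration; for
the single outlier the compensating duration is spread uniformly over
all unmodified intervals (sub-millisecond each, leaving successive
differences essentially untouched). Default contamination is 2% of
intervals (0.5% per mechanism), below the 5% window-rejection
threshold; `stress_preset()` provides 8% to exercise rejection.
Contamination sites keep ≥3 intervals of separation, so injected
artifacts never coalesce into untypable runs.

**Detection** is a single forward pass: interval *i* is flagged when
it deviates from the running reference by more than 20%; the reference
advances only across accepted intervals, so one artifact does not
cascade onto its normal successor. (The scan is implemented with a
jump-ahead over a vectorised candidate list; a property test pins it
to the plain reference loop.)

**Classification** works per flagged run against a local median (the
5 most recent unflagged intervals; series fallback near the start):
a wide/narrow pair whose sum is within the threshold of twice the
local median is a boundary-shift pair (types 2/3); a double-narrow
pair (< 0.75× median each) summing to the median is a spurious beat
(type 5); a single interval above 1.75× the median is a missed beat
(type 4); any other single flag is a type-1 outlier. The 1.75/0.75
factors are operational cut-offs separating missed-beat (≈2×) from
jitter (≈1.2–1.5×) magnitudes; both are config-exposed, as is the
median window. Runs of three or more flags are never typed or
repaired — their window is rejected outright.

**Correction**: type 1 → mean of the flanking unflagged intervals
(two-point linear interpolation at the midpoint, the only consistent
reading for a single missing value); types 2/3 → both intervals
replaced by half their sum; type 4 → split into two equal halves;
type 5 → merged. Types 2–5 conserve duration exactly. Flagged runs
touching a series boundary lack context and are dropped. The window
report counts flags before correction (rate = flagged/total), and a
window is accepted iff rate < 5% and the longest flagged run ≤ 2.

Corrections mildly smooth genuine variability (each corrected site
zeroes one or two successive-difference terms), deflating recovered
RMSSD by ≈0.7–1% at 2% contamination — well inside the 2% recovery
tolerance and the 5% round-trip band the tests enforce.

## RMSSD windows

Windows are time-defined: all intervals whose onset lies in
`[t0, t0+300 s)`, requiring ≥90% duration coverage. State windows
take the earliest 5-min span of continuous qualifying behavior
(abutting qualifying events merge) whose corrected window passes QC,
scanning candidate starts at 60-s steps; absence of a qualifying
window is recorded as missing, mirroring the study's missing-data
mechanism, and exactly one window per cow-day-state is emitted.
Proximity pairs take the first route pass whose near (distance
minimum) and far (maximum) windows both lie wholly inside the
10 a.m.–3 p.m. block, with the cow lying throughout and QC passed; a
far window overlapping the near window is taken from the next pass.
Ties inside a pass resolve to the earliest sample.

## Behavior

Bouts follow an alternating-renewal (semi-Markov) process:
exponential dwell times with behavior-specific means (lying 40,
feeding 20, standing 10, locomotion 2, other 5 min — plausible bout
scales, not fitted values), jump probabilities proportional to
budget/mean, and a stationary start (initial state by occupancy
share; the exponential residual is again exponential). Started
stationary, expected occupancy over any horizon equals the latent
budget exactly — the 1%-tolerance budget-recovery checks lean on this,
not on asymptotics. States are mutually exclusive; the unbudgeted
remainder is `other`; feeding is disjoint from standing.
Time budgets clip events to the observation windows (never drop
them), subtract exclusion intervals (assumed mutually disjoint), and
derive `standing_total = standing_cubicle + standing_walkway`.

The robot path is the rectangular pen perimeter (default 25 × 10 m)
traversed at the farm's working speed (4.0 or 5.5 m/min), sampled at
1 s; the cow lies at a fixed interior position off the symmetry axes,
so each pass has a unique distance minimum and maximum.

## Cortisol metabolites

Samples are log-normal with median equal to the latent concentration
and log-sd `ln(1+cv)` (default cv 0.2), three samples per cow-period.
The log transform used in analysis makes this the natural error
model; no circadian rhythm is simulated.

## Cohort truth and defaults

Latent values are `period mean + farm + cow(farm) + cow×period`
effects, independently Gaussian, floored at 5% of the period mean.
Observed cow-day records add a multiplicative Gaussian day residual
(default cv 5%) so measurement day is a non-degenerate replicate.
Where a cow's behavior budgets exceed the observable day after adding
random effects, they are rescaled proportionally to 97% of it.

Period-mean defaults are the study's reported values where printed;
the remaining cells (RMSSD_a in T2/T3, RMSSD_r in T3, lying in T1,
feeding in T1/T3, locomotion in B/T2, cortisol in T1) are invented
plausible values of the same order. The reported standing components
are not additive with the reported standing totals (each response has
its own missing-data pattern), so the generator keeps the cubicle
values and assigns the walkway the total-minus-cubicle remainder.
Variance-component sds are free parameters — the study reports none —
chosen once to give SEM magnitudes of the order of the published
error bars (RMSSD: farm 0.4, cow 0.9, cow×period 0.45 ms; behaviors:
8–12/20–30/12–18 min; cortisol: 1/2/1).

## Mixed models

All responses are fitted as variance-components models with period
(or position × period for the proximity model) as fixed effects and
random intercepts for farm, cow within farm and cow×period.
Transforms: HRV `ln(ln x)` (the literal double-logarithm; an
`ln(x+1)` variant would only relabel the scale of monotone contrasts),
cortisol `ln x`, standing `√x`, others identity.

Estimation maximises the restricted likelihood with the residual
variance profiled out, over non-negative variance ratios, by bounded
L-BFGS-B from three deterministic starts (near-zero, 0.5, 2.0);
convergence at a relative criterion of 1e-10, boundary estimates
reported as exact zeros. The fit is a deterministic function of the
data (row-permutation invariance is property-tested) and matches
both the closed-form balanced one-way ANOVA estimators and
statsmodels' MixedLM.

Satterthwaite df for a contrast `c`:
`df = 2·g(θ̂)² / (∇g' W ∇g)` with `g(θ) = c'(X'V(θ)⁻¹X)⁻¹c`, `W` the
inverse observed information of the restricted log-likelihood over
the variance components (central finite differences, relative step
1e-5) and `∇g` by the same differencing. Components estimated on the
zero boundary are excluded from the differentiation; if all are, the
df collapses to the OLS residual df `n−p`. The df is capped at `n−p`
as a numerical guard. Agreement with lmerTest is exercised in the
test-suite (df to ~0.1%). In the balanced two-day design the df sits
at the cow×period cell stratum (≈ cells − cows − periods + 1 = 105)
whenever that component is positive, and at `n−p` otherwise; it is
insensitive to the component's share in between.

Outlier handling is a single pass, matching the small removal counts
a one-shot trim produces: fit, drop observations with standardized
marginal residuals (`r_i / √V̂_ii`) outside ±2.5758 (the two-sided
99% normal band), refit once; removal that would empty a farm or
period level is an error. Reported per-period means and SEMs are
raw-scale arithmetic means of the analysed observations; tests are on
the transformed scale. P-values are unadjusted pairwise, as is usual
for this design; a Holm flag is deliberately not defaulted on.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (default 20130107)
and is bit-reproducible; the CLI pipeline is a pure function of
(config, seed). The recovery computations use ≥1,000 five-minute
windows for RMSSD, 10,000 cow-days per behavior setting and 10,000
samples for cortisol; the null-calibration check uses 500 replicate
cohorts at the study's size (36 cows × 4 periods × 2 days). These
sizes put Monte-Carlo error comfortably below the 1–2% recovery
tolerances while keeping the whole suite in the ten-minute range.

## Known limitations

- No habituation/sensitization dynamics, circadian cortisol rhythm,
  robot collision behavior, or vendor IBI file formats (the text
  dialect is a stand-in; the original recorder format is proprietary).
- The IBI model is i.i.d.; detection behavior on strongly
  autocorrelated beat trains is untested.
- Only the described five-type manual correction is modelled; any
  vendor-software pre-correction that preceded it in the original
  workflow is not.
- Whether the "corrected error rate" counts intervals before or after
  correction is ambiguous in the source protocol; flagged/total
  before correction is implemented.
- Transition movements (standing up / lying down) are credited to the
  target state, following the ethogram definitions.
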