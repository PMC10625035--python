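# Methods

This note documents the modelling choices behind `pedipace`: what the
model assumes, where each default comes from, what the synthetic data do
and do not emulate, and the numerical conventions the code commits to.

## The cost model

**Structure.** One "alive with pacemaker" health state plus an optional
absorbing exit state.  A patient enters at cycle 0 with the implantation
cost accrued undiscounted; each follow-up cycle t = 1..H applies, in
order: an exit draw (annual attrition probability q), one Bernoulli draw
per major complication at its annual probability, one Poisson draw per
minor event at its annual frequency.  Costs accrue at cycle end at the
event's mean unit cost, discounted by (1+r)^-t.  There is no half-cycle
correction and no time dependence in the event probabilities: rates are
estimated by pooling events over all follow-up years, so the model's
annual hazards are constants by construction.

This is deliberately the *minimal* structure consistent with annual
per-event probabilities.  Published 20-year means for this population sit
well below the zero-attrition expectation of that minimal structure
(about $230.6k vs $180.7k direct at the reference inputs), which is why
the attrition parameter exists: `calibrate_attrition` back-solves, by
bisection on the closed form, the constant annual exit probability that
reproduces a target mean (≈5.9%/yr for the reference target).  The
parameter is a transparent stand-in for whatever exit/survival mechanism
the richer unpublished model contained, not a mortality estimate; the
pipeline manifest reports the calibrated value and the indirect-cost gap
it implies (the calibrated model lands ≈$1.9k below the published
indirect mean, i.e. a single exit rate cannot reconcile both streams
exactly).

**Closed form as oracle.** Because draws are independent across cycles
and event types, the expected total cost is
`implant + Σ_t (1-q)^t (1+r)^-t Σ_e rate_e·cost_e`.  The simulation is
tested against this expression (3-SE agreement at N = 10^5), and the PSA
uses it as its default inner evaluator so that the PSA's spread is pure
parameter uncertainty with no Monte-Carlo noise.  The PSA accumulates the
per-cycle sum in the same floating-point order as the closed form, so a
spec of point masses reduces to the base case bit-for-bit.

**Dispersion.** The published "(SD)" for the base case is ambiguous
between across-patient SD and SE of the mean; results objects therefore
expose both.  With unit costs fixed at their means, across-patient SD
comes from event-count variation only (≈$56k direct at the reference
inputs).  Optional per-patient sampling of the implantation cost
(`sample_implant_cost`, zero-truncated Gaussian) roughly doubles it; a
zero SD degenerates to the point mass without consuming random numbers,
so the flag is then a no-op.

**Reference inputs (2018 USD).** Annual probabilities 2.0% (malfunction
requiring lead-and-generator replacement), 11.2% (generator change),
0.6% (infection); annual frequencies 1.5 (clinic visit), 0.9 (device
check), 1.8 (ECG), 0.1 (Holter), 0.1 (EP catheterization); LOS means
(SDs) 13.005 (13.166), 3.156 (3.586), 0.322 (1.039), 12.679 (15.573)
days for implantation and the three majors, 0.125 d for clinic-type
events and 1.0 d for EP catheterization; direct costs 108,052 (109,053),
52,720 (52,720), 41,797 (11,050), 91,653 (112,100) and 219/463/289/963/
5,894 for the minors; discount 3%/yr; horizon 20 y.  Cardiac
rehabilitation is carried in the taxonomy with rate 0 (no published
inputs).  Major-event "annual %" is interpreted as events per person-year
read as an annual probability — a standard small-rate approximation.

**RNG contract.** The simulator spawns one `SeedSequence` substream per
draw purpose (exit, each event type, implant cost) and draws
patient-indexed matrices, so patient i's history depends only on
(seed, i) and results cannot depend on evaluation order.  Results are
bit-reproducible for equal seeds and differ for unequal ones.

## Probabilistic sensitivity analysis

Families follow the standard health-economics convention, since none are
published for this analysis: beta for probabilities, gamma for positive
costs, point mass where no SD is available (all minor-event inputs).
Hyperparameters are moment-matched: gamma shape = (mean/SD)^2, scale =
SD^2/mean; beta α = mean·m, β = (1−mean)·m with m an effective sample
size (default 255, the follow-up cohort size) because probabilities carry
no published SD.  Lengths of stay do not enter the cost model directly
(they act upstream, through the billing regressions), so they are not
varied.  The default 10,000 draws give a PSA mean within Monte-Carlo
error of the base case and an SD dominated by the implantation-cost
uncertainty (≈$117k direct) — an order of magnitude above the base-case
SE, as expected when parameter uncertainty is switched on.  Draw count
and families are flagged as package conventions in the output metadata.

## The synthetic cohort generator

The generator emulates the institutional database the analysis assumes:
per patient, one index CHS 0–30 days before a pacemaker implantation at
age < 4 years, then per follow-up year Bernoulli majors and Poisson
minors with uniform within-year dates; optional exponential censoring
emulates variable follow-up.  Design choices that matter:

- **LOS is gamma**, moment-matched to the configured mean/SD.  A
  truncated normal was rejected: clipping at zero with these SDs (e.g.
  0.322 (1.039) d) shifts means by tens of percent and would defeat the
  parameter-recovery contract the generator exists to support.  Clinic-
  type events use the fixed 0.125-day visit.
- **Billing is linear in LOS** with per-event intercept/slope derived so
  the line passes through (LOS mean, cost mean) and the charge-on-LOS
  R² matches the published value for that event type (0.838
  implantation, 0.864 infection, 0.23 malfunction, 0.007 generator
  change).  Noise is a conditional gamma around the linear mean — it
  preserves the conditional mean exactly and keeps charges positive.  An
  additive-Gaussian mode with clip-at-zero accounting (warning above 5%
  clipped) is available but biases means at these noise levels, which is
  why it is not the default.
- **Indirect cost is deterministic**: per-visit + per-day × LOS, with
  the default coefficients fitted by OLS to the six published
  (LOS, indirect) pairs (per_visit ≈ $76.66, per_day ≈ $557.76).  Note
  the published pairs are not exactly linear: the fitted line prices a
  0.125-day clinic visit at $146.38, not the published $136 — the
  generator-change row sits well off the line, and no unweighted OLS on
  those pairs can reproduce the $136 figure.  The package treats the OLS
  fit as the model and documents the discrepancy rather than forcing the
  point.
- **Person-years** are counted in completed annual cycles
  (ceil(last event day / 365.25)): events live on an annual grid, so a
  patient whose last event falls in cycle t was observed for t whole
  annual trials.  Using the raw last-event time would systematically
  drop about half a year of exposure per patient and bias every rate
  upward by ~2.5%.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: no lesion-complexity or surgeon
structure, no time trends in event hazards (real early post-implant years
are busier), no correlation between a patient's LOS and their event
propensity, no billing inflation across calendar decades, and no
informative censoring.  Parameter recovery on this generator shows the
estimators are consistent under the model's own assumptions, nothing
more.

## Cohort costing and extrapolation

Patients split by clinical course: *complication* = at least one
malfunction-replacement or infection event (a generator change is routine
maintenance and does not qualify).  Cumulative curves bin events at
floor(days/365.25) and average over patients still under follow-up at
each year — the varying-n convention, not last observation carried
forward — so group means need not be monotone even though every
per-patient curve is.  The 20-year value is extrapolated by OLS on the
mean curve over observed years 10–19 (≥3 points required); an exactly
linear curve reproduces its year-20 value exactly, and a flat curve is
returned as a perfect zero-slope fit.  On reference-parameter synthetic
cohorts the implantation year carries ~45% of the 20-year direct total,
inside the broad published 35–50% band.

## Trend analytics

CAGR uses raw single-year endpoints over the elapsed span
(n_years = last − first; 58 for 1960–2018), with an optional 3-year
endpoint average for noisy series.  Count trends are Poisson GLM fits of
counts on calendar year (years re-origined to the first year for
conditioning; the slope is unchanged and the intercept is the log level
at the first year); no exposure offset is used, matching the headline
counts being raw volumes.  On an exactly exponential series the GLM slope
equals log(1+CAGR) to 10^-6.  The implants-per-surgery rate is a plain
yearly ratio with zero-surgery years emitted as missing.

## Numerical conventions

- Sample SDs use the n−1 denominator throughout; a single observation
  reports SD 0 with a logged caveat.
- A constant sample reports SD exactly 0 (guarding against ~1e-11
  pairwise-summation noise).
- The 30-day postoperative window is inclusive; the age-4 cutoff is
  strict; both are configurable.
- Rate CIs: Wilson on person-year trials for probabilities, exact
  (Garwood) Poisson for frequencies.
- Currency serializes at 2 decimal places; event tables round-trip
  byte-identically after one write/read cycle
  (`float_precision="round_trip"` on read).
- Bisection tolerance for attrition calibration: $1 on the closed-form
  mean.

## Problem sizes

Defaults mirror the study conditions: 10,000 simulated patients, 20-year
horizon, 10,000 PSA draws, synthetic estimation cohorts of 10,000
patients (~2×10^5 person-years).  The test suite exercises the same code
at these scales where the contract demands it (oracle agreement at 10^5
patients, parameter recovery at 10^4×20 person-years) and at smaller
cohorts elsewhere; `scripts/acceptance.py` states the size used alongside
every quantity it reports.

## Known limitations

- Constant hazards: no early post-implant clustering of events.
- The attrition parameter conflates death, transfer of care and device
  explantation; it is calibrated, not estimated.
- Unit costs enter the simulation at their means; within-event cost
  variance affects only the PSA, not the base-case SD.
- The indirect model assumes one accompanying adult and on-the-ground
  costs only; it inherits the nonlinearity mismatch described above.
- No utilities, QALYs or cost-effectiveness ratios: this is a
  cost-of-illness model only.
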