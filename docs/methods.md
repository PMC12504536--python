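# Methods

## The estimand

For a time-to-event outcome, each physical-activity intensity (light,
moderate, vigorous: LPA, MPA, VPA, in minutes/day) has a dose-response
curve HR(d) giving the hazard ratio at daily dose d relative to an
intensity-specific referent. At a risk-reduction level ℓ% (HR target
1 − ℓ/100), inverting each curve gives the minutes of that intensity
needed to reach the same relative risk. The ratio d_MPA(ℓ)/d_VPA(ℓ) is
the "minutes of MPA equivalent to one minute of VPA" at level ℓ; the
headline summary is the median of this ratio over ℓ ∈ [5%, 35%], and
likewise for LPA. A secondary LPA-per-MPA figure is the quotient of the
two VPA-anchored medians.

Doses are counted as minutes *above the intensity's referent*: 0 min/day
for VPA and MPA, the cohort minimum for LPA (everyone accumulates some
light activity; the empirical floor in the motivating cohort is
37.9 min/day). For VPA/MPA the two conventions coincide; for LPA the
incremental convention keeps the closed-form identities below exact,
which is why we chose it.

Under log-linear truth, HR_V(d) = exp(β_V d) and HR_M(d) = exp(β_M d),
the per-level ratio is level-independent and equals β_V/β_M — the
closed-form oracle used throughout the tests.

## Hazard models

- **Families.** Cox proportional hazards for the all-cause-mortality
  analogue; Fine–Gray sub-distribution hazards for disease outcomes with
  competing events. The Fine–Gray fit is the weighted-Cox estimator on
  expanded counting-process data: a subject with a competing event at T
  stays in later risk sets with inverse-probability-of-censoring weight
  G(t−)/G(T−), where G is the Kaplan–Meier estimate of the censoring
  distribution. Weights enter the partial likelihood only at
  event-of-interest times, so the expansion breaks intervals exactly
  there (keeping it far smaller than breaking at every censoring time).
  With no competing events the expansion is the identity and the two
  families agree exactly; point estimates were checked against
  `cmprsk::crr` during development (agreement to 7 decimals on a 1,500
  subject fixture).
- **Dose terms.** Restricted cubic splines (truncated-power natural
  splines, cubic terms scaled by the squared boundary-knot span) with
  knots at the 10th/50th/90th percentiles of the winsorized dose. A
  linear-dose mode (`knot_percentiles=None`) is provided and is the
  matched model family for validation under log-linear truths; the spline
  path is validated separately by the nonlinearity-test calibration.
- **Mutual adjustment.** Each intensity model adjusts linearly for the
  energy-expenditure volume of the other two intensities, computed as
  MET-weighted minutes (defaults 2/4/8 MET-min per LPA/MPA/VPA minute;
  configurable, with an unweighted-minutes mode) plus the named
  confounders.
- **Ties.** Efron's correction by default (Breslow available). Synthetic
  event times are continuous, so the choice is immaterial there; tied
  fixtures are cross-checked against lifelines.
- **Optimisation.** Newton–Raphson with step-halving on the log partial
  likelihood. Convergence when the largest score component is below 1e-8;
  for large weighted problems whose floating-point summation noise floor
  sits above that, iteration stops when an accepted Newton step is below
  1e-9 in coefficient units, or when a step under 1e-6 yields a relative
  log-likelihood gain under 1e-12 (the next iterate is then quadratically
  accurate). Maximum 50 iterations; failure raises with the likelihood
  trace. Coefficients match lifelines to ~1e-7 (bounded by lifelines' own
  stopping rule) and a brute-force Newton solve of the explicit partial
  likelihood to 1e-8.
- **Diagnostics.** Departure from linearity: joint Wald chi-square on the
  nonlinear spline coefficients. Proportional hazards: Grambsch–Therneau
  slope test on scaled Schoenfeld residuals (s* = d·s·V̂), with the
  Kaplan–Meier time transform by default (identity and rank transforms
  available). Both hold their nominal 5% size under the null in the
  acceptance simulations.

## Cohort preparation

Order matters and is logged: (1) drop prevalent cases of the outcome;
(2) drop subjects whose *analytic* event falls within the first 12 months
(landmark against reverse causation — early competing events and early
censoring are retained); (3) winsorize each intensity at its own 97.5th
percentile. The winsorization threshold is the largest observed order
statistic at or below the requested percentile, making the operation
exactly idempotent. Knot placement (linear-interpolation percentiles,
computed over all participants) happens after winsorization, inside any
bootstrap resample.

## Dose-response curves and inversion

HR(d) = exp([B(d) − B(ref)]·β) on a 0.1 min/day grid from the referent to
the winsorized maximum — fine enough that the interpolation error of
inversion is far below the 0.01-min reporting precision. Pointwise
log-scale standard errors come from the delta method on the spline
coefficient covariance (checked against parametric-bootstrap draws).
Curves are not forced monotone; inversion takes the *first* crossing of
the target HR, linearly interpolated, and returns "undefined" when the
curve never reaches the target. Undefined levels are excluded from the
median (a cap-at-maximum-dose mode exists and is flagged in output); this
mirrors how light activity attains only modest risk reductions, so its
equivalence is summarised over the achievable part of the band. The level
grid runs in 0.1% steps by default ("continuous increments"), with a 5%
reporting mode.

## Bootstrap confidence intervals

Percentile intervals (2.5th/97.5th of B resampled values) at the rounded
HR levels 0.65, 0.70, …, 0.95 and for the band median. Two modes, always
recorded in output:

- **cohort** (principal): resample subjects with replacement and re-run
  winsorization → knots → fits → curves → inversion inside every
  resample. Resamples without any event of interest are redrawn (logged,
  capped at 100 per resample). Knot refitting inside the resample is the
  default; a frozen-knot flag exists.
- **curve** (fast approximation): draw coefficient vectors from
  N(β̂, V̂) and rebuild curves without refitting — a literal reading of
  bootstrapping "model-predicted values".

Default B=1000; desk-scale runs use B=200. The two modes agree on
interval width within Monte-Carlo slack on large log-linear scenarios,
and the cohort mode attains ~95% empirical coverage of the known ratio in
the acceptance simulation.

## Synthetic cohort generator

What it emulates: right-skewed, correlated intensity exposures
(multivariate log-normal on the log scale; LPA gets a +37.9 min/day
location offset so the marginal has a hard floor like the empirical
referent); a few confounders with realistic effect sizes (age ~N(61.6,
7.9²) years with log-HR 0.07/year, sex with −0.35, a standardised
lifestyle score with −0.10, all centred in the linear predictor);
cause-specific exponential event and competing hazards scaled by
exp(linear predictor); administrative censoring at a 9.7-year horizon
minus a U(0, 3.4)-year entry stagger, giving censoring times with mean
8.0 and SD ≈ 0.98 years; and a 5% prevalent-disease fraction so the
exclusion filters have work to do. The default baseline hazard
(0.0046/person-year) mirrors a mortality-scale outcome; the named
log-linear validation scenario uses an event-rich 0.02/person-year so
parameter-recovery checks at n = 20,000 rest on ~1,700 events — standard
practice for simulation validation, chosen when the scenario was defined.
Dose-response truths can be null, linear, or piecewise-linear ("spline")
in the log hazard.

One integer seed drives named substreams (exposures, covariates, events,
censoring, prevalence) keyed by a CRC32 of the stream name, so adding a
stream never perturbs the others and cohorts are bit-reproducible.

What it does not emulate — and hence what passing tests do not show about
real data: raw accelerometer signal, wear-time/non-wear structure, and
intensity classification error; measurement error and within-person
day-to-day variability in exposure; non-proportional or time-varying
effects (except in diagnostic power fixtures); informative censoring;
calibrated UK Biobank exposure marginals (the log-normal parameters are
plausible placeholders, not estimates).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| winsorization percentile | 97.5 | % | blunt sparse upper tails before knots |
| knot percentiles | 10/50/90 | % of winsorized dose | standard 3-knot natural spline |
| referents | 0 (VPA/MPA), cohort min (LPA) | min/day | anchor HR = 1 at the attainable minimum |
| risk band | 5–35 | % risk reduction | region where curves are comparably shaped |
| level step | 0.1 (reporting: 5) | % | continuous vs tabular summaries |
| dose grid step | 0.1 | min/day | inversion error ≪ 0.01-min reporting |
| MET weights | 2/4/8 | MET-min per min | energy-expenditure volume adjustment |
| B | 1000 (desk: 200) | resamples | percentile CI resolution |
| landmark | 1.0 | years | reverse-causation guard |

## Known limitations

- Fine–Gray standard errors are model-based (inverse information on the
  weighted likelihood), not the robust sandwich of `crr`; they sit
  between the naive and robust variants and are used only for z-scale
  screening, never for the bootstrap intervals.
- The ratio estimator is heavy-tailed when the denominator slope is weak
  (few events or small effects); percentile intervals remain valid but
  wide, and the median-over-levels is reported as NaN when the VPA curve
  reaches no level in the band.
- Equivalence ratios compare *incremental* minutes above each referent;
  for LPA this differs from an absolute-minutes reading by
  referent/d_VPA at each level.
- The generator's exposure distribution is not calibrated to any real
  cohort; recovery results demonstrate estimator correctness, not
  real-data effect sizes.
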