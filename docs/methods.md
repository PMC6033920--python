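# Methods

## Thermal-time models

All four methods share the cardinal-temperature triple (T_b, T_opt, T_u),
strictly ordered, in °C.  Shipped sets: corn (8, 33, 40); spring wheat
(0, 24, 42); winter wheat (0, 24, 45) for the vegetative phase
(sowing–heading) and (8, 29, 40) for the reproductive phase
(heading–maturity).

**Method 1** (daily, linear): DTT = 0 for T_avg < T_b; T_avg − T_b for
T_b ≤ T_avg ≤ T_u; T_u − T_b above, with T_avg = (T_max + T_min)/2.

**Method 2** (daily, clamped): T_m = min(T_max, T_u), T_n = max(T_min, T_b),
and the middle branch uses (T_m + T_n)/2 − T_b.  Which branch applies is
selected by the *unclamped* T_avg, so the two linear methods are identical
whenever the whole day lies inside [T_b, T_u], and method 2 credits less
(more) than method 1 on days whose maximum (minimum) pokes beyond a
threshold.

**Method 3** (hourly, bilinear): HTT rises as T_h − T_b up to T_opt, falls
along (T_opt − T_b)/(T_u − T_opt)·(T_u − T_h) to zero at T_u, and is zero
outside [T_b, T_u].  The sub-optimal branch is T_h − T_b: that is the only
reading continuous at T_opt and consistent with a response that "rises
linearly to the optimum".

**BFM** (hourly, beta): the beta-distribution-shaped response

HTT(T_h) = (T_h−T_b)/(T_opt−T_b) · [(T_u−T_h)/(T_u−T_opt)]^q · (T_opt−T_b),
q = (T_u−T_opt)/(T_opt−T_b),

zero at and outside the thresholds, maximal (T_opt − T_b) only at T_opt.
Because q < 1 for all shipped crops, the response has a vertical tangent at
T_u: it is continuous there but only Hölder-continuous of order q, which is
why grid-based continuity checks refine like h^q rather than h.  The
exponent is computed once per cardinal set.  Temperatures outside
[T_b, T_u] are masked before the fractional power is evaluated, so no
negative base is ever raised to a non-integer exponent.

Daily DTT for the hourly methods is the mean of 24 HTT values (Σ HTT / 24).

### Branch boundaries

All interval conditions are closed on the left and, where the formula is
continuous, on the right.  The choices are value-neutral: at T_avg = T_b the
linear middle branch evaluates to 0, at T_avg = T_u it evaluates to
T_u − T_b, and the hourly responses agree at all three cardinal points.

### Hourly disaggregation

Recorded hourly temperatures are rarely archived alongside daily extremes,
so the hourly methods accept either native 24-value profiles or a
disaggregation of (T_max, T_min).  The default scheme is a single cosine
wave T_avg + (T_max − T_min)/2 · cos(2π(h − 14)/24): maximum at 14:00,
minimum at 02:00, exactly spanning the recorded extremes.  The peak hour is
configurable and the scheme registry is pluggable; a smooth deterministic
scheme keeps the hourly methods a pure function of the daily record.  This
is a modelling choice, not a physical claim — real diurnal cycles are
asymmetric (slow nocturnal cooling, sharper morning warming), so methods 3
and BFM inherit whatever bias the scheme has near sunrise/sunset hours.

## Phenology calibration and prediction

Sowing day is day 0.  A stage observed n days after sowing accrues the DTT
of days 0..n−1 — a half-open window, stated explicitly because different
conventions differ by one day of thermal time.  Per stage and method the
across-year mean GDD is the requirement; the sample SD (n−1 denominator,
appropriate for the small annual samples involved) measures its spread.

CV in days = SD_GDD / GDD_m, where GDD_m is the across-year mean of
(stage GDD ÷ days after sowing).  The alternative pooled reading (total GDD
over total days) differs only in the third decimal for balanced records.
CV is also reported as a percentage of mean days after sowing.

Prediction: the stage date is the first day d whose cumulative GDD reaches
the requirement (reported as d+1 days after sowing, matching the
accumulation convention).  A threshold that is never crossed within the
weather window is reported as a missing prediction, not an error.  For
winter wheat the cardinal set switches at the *observed* heading date
during calibration and at the *predicted* heading crossing during
prediction — prediction cannot look at observations.  The sowing→emergence
sub-period uses the vegetative set.  By default requirements are calibrated
on all years (in-sample, which is what a CV of annual requirements
measures); a leave-one-year-out mode gives an out-of-sample evaluation.

Willmott's refined index of agreement d_r is computed with scale factor
c = 2 over (observed, predicted) days after sowing, per season across that
season's stages; it is 1 only for exact agreement and bounded in [−1, 1].

### Sensitivity analysis

One cardinal temperature at a time is shifted by −4, −2, −1, +1, +2 or
+4 °C (in every phase for multi-phase crops), requirements are recalibrated
and the CVs recomputed.  T_opt rows exist only for method 3 and BFM — the
linear methods do not use the optimum.  A delta-0 control row per
combination carries the unperturbed CV as an internal consistency check.
Shifts that break T_b < T_opt < T_u are kept in the output as `skipped`
rows with the reason, never silently dropped.

## Dry-matter fitting

Biomass is normalized by Y_m (default: the observed maximum, overridable)
and fitted with y = 1/(1 + exp(a + b·GDD)) by least squares.
Initialisation is deterministic: y clamped into [1e-3, 1−1e-3], logit
regressed on GDD by OLS, then Levenberg–Marquardt refinement on the
unclamped residuals (xtol = ftol = 1e-14).  Saturated observations (y = 1)
are retained; the clamp exists only inside the initialisation.  Fits need
at least three observations and warn when the data do not straddle
y = 0.5, where (a, b) are weakly identified.  RMSE is reported on the
normalized scale.

## Synthetic studies

The generator emulates the *structure* of multi-year station data, not any
particular station: daily mean = annual mean + amplitude·sin(2π(doy −
phase)/365) with the minimum in mid-January, plus stationary AR(1) noise
(lag-1 autocorrelation 0.6 — a realistic day-to-day persistence for
mid-latitude anomalies), and a diurnal range jittered at 15 % relative SD,
floored at 0.5 °C.  With noise SD 0 the series is exactly periodic and
seed-independent.  Two presets:

* `arid-hot` — annual mean 15 °C, amplitude 16 °C, diurnal range 14 °C,
  noise SD 2.5 °C: a continental desert where almost every summer day's
  maximum exceeds the wheat optimum of 24 °C.
* `temperate-mild` — annual mean 13.5 °C, amplitude 9 °C, diurnal range
  8 °C, noise SD 1.5 °C: summer maxima stay below the corn optimum of
  33 °C.

Ground-truth stage thresholds are anchored in *days*: canonical mean
days-after-sowing per stage (e.g. corn maturity at 103 days from a May 1
sowing; spring wheat maturity at 109 days from March 25; winter wheat at
209 days from October 10) are converted to GDD thresholds by accumulating
the generating method over a reference season.  This keeps thresholds on
the natural scale of whichever method generates the truth.  Stage dates are
then the first threshold crossings per season; optional ±k-day uniform
observation jitter is restored to developmental order by a running
maximum.  Seasons whose thresholds are unreachable are skipped and
reported.  Every generated study carries a JSON ground-truth sidecar
(thresholds, generating method, crop, logistic coefficients, seeds);
recovery tests read the truth from the sidecar.

The climate-contrast ensemble generates stage dates under BFM in the
`arid-hot` preset: the premise being probed is that the real developmental
response is beta-shaped, and the question is how consistently each clock
describes such seasons.  The mild-climate agreement check generates under
method 1 instead, where all four methods should (and do) agree within a
day.  What these synthetic studies cannot show: real weather has weather
fronts, heat waves and asymmetric diurnal cycles that the sinusoid+AR(1)
model smooths away, and real phenology carries observer error structured
by stage, so passing recovery tests demonstrate internal consistency of
the pipeline, not field accuracy.

## Problem sizes and numerical choices

Synthetic studies use 6–10 seasons, matching the 8–14-year station records
such comparisons are usually run on; hourly computation is vectorised so a
season is a (days × 24) array operation.  Logistic recovery uses 20-point
designs over 0–2000 °Cd with noise SD 0.02 across 20 seeds.  Formula
cross-checks compare against 50-digit decimal transcriptions (powers via
exp·ln) on 10,000 random cardinal-set/temperature draws.

## Known limitations

* Round-trip stage prediction is exact to ±1 day only when the threshold
  crossing happens during active accumulation.  Winter-wheat stages that
  cross in mid-winter sit on near-zero daily DTT, so a sub-degree-day
  threshold difference can move the crossing by several calendar days, and
  a shifted predicted heading moves the phase switch for later stages; the
  round-trip tests assert a wider band there.
* No photoperiod, vernalization, soil temperature, chilling or
  evapotranspiration; no spatial interpolation between stations.
* The dry-matter module fits pooled observations per dataset by default
  (per-year fitting is a flag away at the library level); no Gompertz or
  expolinear alternatives.
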