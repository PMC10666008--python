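# Methods notes

This note documents the modelling choices, exposure definitions, QC rules,
numerical conventions and the synthetic-data design behind `heatwear`,
including the places where the design was genuinely open and what the
package chose.

## Exposure processing

**Windows.** The day window is [06:00, 22:00) local time and the night
window [22:00, 06:00) of the following morning; the night labelled with
date *d* spans *d* 22:00 → *d*+1 06:00, and all joins of nighttime outcomes
to exposures use that convention. These cut-offs round the cohort's
typical sleep onset (~22:00) and offset (~06:00) to whole hours. Rainfall
is totalled over the calendar day of the label date for both day and night
outcomes; an alternative preceding-24-h accumulation for nights was
considered and rejected for simplicity and because daily rain totals in
this climate are dominated by afternoon convection either way.

**Heat index.** The US National Weather Service algorithm is °F-native, so
inputs are converted to °F, the simple-formula branch is used when the
apparent temperature is below 79 °F, otherwise the Rothfusz regression with
the published low-RH (< 13%) and high-RH (> 85%) adjustments, and the
result is converted back to °C. Full precision is kept internally; CSV
outputs are readable at full float precision and any display rounding is
0.1 °C. NaN inputs propagate to NaN, never to zero.

**WBGT.** The outdoor estimate is the standard composition
WBGT = 0.7·Tnwb + 0.2·Tg + 0.1·Ta. The natural-wet-bulb and globe
sub-estimators are deliberately pluggable (callables receiving
temperature, humidity, radiation, wind). The defaults are the package's
own simple approximations:

* Tnwb = Tw + 0.0021·S / (1 + 0.15·u), where Tw is the Stull (2011)
  psychrometric wet bulb from temperature and humidity, S is global
  radiation (W/m²) and u wind speed (m/s): solar loading raises the wet
  bulb, ventilation removes the excess, and at night the estimator reduces
  to the psychrometric wet bulb;
* Tg = Ta + 0.0130·S / (1 + 0.30·u): a radiative excess over air
  temperature proportional to radiation and damped by wind.

Only the composition arithmetic and monotonicity contracts (WBGT never
decreases with radiation) are treated as testable guarantees; the
sub-formula constants are documented approximations a user can replace
with a calibrated estimator for their instrumentation.

**Extreme indexes and boundaries.** Heavy-rain days (rain ≥ 20 mm), hot
days (Tmax ≥ 35 °C), heat-stress days (WBGT_max ≥ 30 °C) and heat-stress
nights (HI_min ≥ 25 °C) use inclusive thresholds; tropical nights require
Tmin strictly > 20 °C. These semantics are encoded once, in
`thresholds.Thresholds`, and every flag is computed from that object. A
day/night window with zero observations yields missing summary fields and
missing flags — never false-by-default — and no imputation is performed
anywhere in the pipeline.

**Geodesy.** Village-to-station distances use Vincenty's inverse method on
the WGS 84 ellipsoid (ellipsoidal, not spherical). Vincenty can fail to
converge only for near-antipodal pairs, far outside any study region;
tests pin the implementation to reference distances from an independent
ellipsoidal solver to sub-metre agreement. Nearest-station ties break
lexicographically by station id so assignment is deterministic.

## Wearable QC

* **Steps.** Duplicate (participant, timestamp) epochs are collapsed and
  zero-step epochs removed (the device cannot distinguish a true zero from
  non-wear). Wear time on a date is the sum of gaps ≤ 1 h between
  consecutive epochs plus one 15-minute epoch width, so a contiguous
  15-min grid covering [08:00, 18:00) counts as exactly 10 h; a gap
  longer than 1 h is non-wear and contributes nothing. Days with < 10 h
  wear are excluded (missing, not zero).
* **Sleep.** Records are assigned to the night of their onset (onsets
  after midnight belong to the previous night). Rules in order: drop
  records outside the 17:00 → 13:00 window; drop spans < 3 h
  (device-flagged invalid); drop records that mutually overlap within a
  night (only the overlapping records, not the whole night, unless none
  remain); merge the remainder — durations summed, inter-record gaps added
  to wake-after-sleep-onset, earliest onset and latest offset kept.
  Durations are carried at second resolution and reported in hours.
* **Heart rate.** Samples are deduplicated, values above the age-predicted
  maximum (208 − 0.7·age, age at study start) dropped, rounded to integer
  bpm, and aggregated to 15-min bins (mean/min/max). A participant-day
  qualifies with ≥ 8 populated day bins (2 h); a night with ≥ 4 populated
  bins (1 h at one sample per 15 min) — bin coverage, not raw sample
  counts, was chosen as the reading of the daytime rule. The nightly
  outcome is the mean of the qualifying night bins' means.
* **Completeness.** Participants qualify per stream when their valid
  days/nights reach 25% of study days (configurable; 50% is the standard
  sensitivity setting). Per-stream rather than global accounting was
  chosen so that one failed sensor does not discard a participant's other
  streams.

Every exclusion carries a machine-readable reason code (duplicate,
zero_steps, window, short_span, overlap, hr_ceiling) and the QC report
counts them, which is what makes the generator's injected-violation ledger
exactly checkable.

## Models

Estimation uses `statsmodels` MixedLM with a per-participant random
intercept and maximum likelihood (not REML), so that likelihood-ratio
tests across fixed-effect specifications are valid. AIC is computed as
2k − 2·loglik with k counting the fixed effects plus both variance
parameters. Confidence intervals are Wald ±1.96·SE and p-values
large-sample normal; with thousands of observations per fit the
small-sample df correction would not change any qualitative decision, and
this convention is stated rather than configurable.

Covariate selection is hierarchical: candidates are offered in the fixed
order month, weekend, age group, sex, BMI group (the order is a package
convention — the covariate set, not the order, is what the procedure is
sensitive to in practice) and each is kept iff the LRT p-value is below
5%. All stepwise fits share one listwise-complete data frame over the base
terms plus all candidates so every test compares identical rows. The
published workflow's visual residual inspection for curvature is replaced
by an automated LRT on the squared heat term at the same 5% level, with
the residuals-vs-heat table exported so a human can still look.

Marginal ("combined") effects in a quadratic model are reported as
b1 + b2·(2x + 1) — the exact predicted change for a +1 °C step from x —
evaluated at 20 °C and 30 °C, always from full-precision coefficients.
Note that rounding coefficients before computing combined effects can
change them materially (606 and −12 give +114 at 20 °C, while slightly
different unrounded coefficients can give +146), which is why the package
never derives effects from rounded values.

Subgroup sensitivity adds interactions between the heat term(s) and one of
age group, BMI group, sex or month (treatment coding with the
lowest-sorted level as reference, i.e. January for months present);
when the interaction LRT is significant at 5% the model is refitted per
level and heat estimates with marginal effects tabulated. Extreme-weather
contrasts refit the selected model with binary heat-stress and heavy-rain
flags in place of the continuous exposures.

LOSO cross-validation refits on all other participants and predicts the
held-out rows from fixed effects only — the random intercept of an unseen
subject is by construction unavailable — scoring R² = 1 − SSE/SST (SST
about the held-out subject's own mean; undefined when SST = 0, reported
missing) and RMSE, with means over per-participant values. Because most
variance is between-person, mean LOSO R² is small or negative even when
exposure effects are precisely estimated; this mirrors what such designs
show on real data and is a property of the prediction target, not a fit
failure.

The design calculation is Cochran's sample size for a proportion with
finite-population correction, n0 = z²p(1−p)/e², n = n0/(1+(n0−1)/N),
rounded to the nearest integer.

## Synthetic data

The generator emulates the study's data-generating process on the linked
scale first — per-day and per-night outcomes from the configured fixed
effects, participant intercepts and Gaussian noise — and then decomposes
those values into raw streams. This guarantees that ground truth survives
QC exactly when no violations are injected (sleep durations round-trip to
second resolution; step totals exactly; HR nightly means to within sample
rounding), which is what makes end-to-end recovery testable.

Default conditions: 60 participants for 120 days from 1 August (rainy
into cool-dry season), 2 stations serving 5 villages; cohort margins
~50% female, age 43 (SD 13), BMI 22.3 (SD 2.7); sleep effects −0.04 h/°C
HI_min, +0.01 h/mm rain, +0.1 h weekends (residual SD 0.9 h, intercept SD
0.6 h); an inverted-U activity response peaking near 27 °C WBGT with
−39 steps/mm rain; a null heat effect and −0.04 bpm/mm rain effect for
nighttime heart rate; and a −0.24 h sleep shift on heat-stress nights in
the binary-exposure variant. Missingness is applied per stream at roughly
the completeness levels such wearable deployments achieve (half of days
for steps and sleep, four fifths of nights for heart rate), as
participant-day deletion — the generator does not attempt to model the
politically and logistically driven missingness mechanisms of real
fieldwork, so passing recovery tests demonstrates robustness to random
missingness only.

Weather is a seasonal-mean plus diurnal sinusoid with day-level and
interval noise for temperature; humidity anti-correlated with the
temperature anomaly and raised on rain days; rain as per-day Bernoulli
draws (probability 0.35/day in the rainy season, near zero otherwise) with
gamma totals spread over a few afternoon intervals; radiation following a
solar arc attenuated under rain; small-variance wind. Seasonal means
(27.6 / 26.8 / 31.1 °C for rainy, cool-dry, hot-dry) and diurnal
amplitudes were set to reproduce the broad seasonal structure of Sahelian
station data. This is statistical texture, not micrometeorology: no
advection, no storms with structure, no sensor drift.

QC-violation injection (duplicates, zero epochs, afternoon naps outside
the sleep window, short fragments, overlapping records, HR spikes above
the Tanaka ceiling) is off by default and switched on per rate; every
injection increments a ledger keyed by the same reason codes the QC audit
uses, and the correspondence is exact by construction (an injected overlap
counts 2, since the colliding pair is dropped).

All randomness flows from a master seed through fixed per-component
streams (sites, weather per station, cohort, linked outcomes, raw-stream
decomposition), so components can be regenerated independently and
identical (config, seed) pairs produce byte-identical files.

## Test calibrations and problem sizes

The repeated-simulation checks run at the default 60 × 120 study size:
95% CI coverage of each true sleep fixed effect across 100 seeded
replicates (required in ≥ 90), and LOSO equivalence against a naive refit
loop at 10 participants. The AIC metric-discrimination check uses a
strong-signal variant of the activity model (curvature scaled up threefold
with the peak kept at 27 °C, residual SD 1500 steps): at paper-scale
coefficients the inverted-U varies by only ~±150 steps across the
observed 24–32 °C WBGT range, which no information criterion can separate
from noise at this study size, so the check is framed as "AIC recognises
the true exposure metric when an identifiable signal exists" — the two
candidate metrics are naturally decorrelated (r ≈ −0.5) by the seasonal
structure, humid rainy days having high WBGT but moderate temperature.

## Known limitations

* One station per participant for the whole study; mobility and
  within-village microclimate are out of scope.
* WBGT sub-estimators are uncalibrated approximations; treat absolute
  WBGT values as estimates and prefer the pluggable interface for
  calibrated work.
* The LOSO R² definition (per-subject SST) is one of several in use;
  comparisons across studies should check definitions.
* MixedLM boundary fits (intercept variance → 0) are accepted and match
  pooled OLS; truly singular designs raise a diagnostic error rather than
  silently degrading.
* Timestamps are naive local time throughout; multi-timezone deployments
  would need explicit offsets before the day/night windowing.
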