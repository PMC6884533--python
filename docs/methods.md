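# Methods

This note documents the models, estimators, and numerical choices behind
`wavecatch`, and what the synthetic scenarios do and do not establish about
real data.

## CPUE construction

Daily records `(date, catch_kg, effort_person_days, region)` are pooled per
calendar month: `CPUE_m = Σ catch / Σ effort`. The pooled ratio — rather
than the mean of daily catch/effort ratios — weights each person-day
equally, is robust to tiny-effort days, and is bounded by the month's
extreme per-record ratios. Months without records are *missing*, never
zero: zero CPUE is an observation, absence is not.

Seasonal (default November–January) means are labelled by the year of the
November opening the season; a season that does not cross the year boundary
is labelled by its own calendar year. A winter is valued only when a
majority of its season months are observed (so a record starting in January
cannot fabricate its preceding winter); winters missing a minority of
months are averaged over the available ones and flagged incomplete. A
2006–2018 monthly record therefore yields exactly 13 NDJ winters, the last
one incomplete, and correlation maps against 13 winters carry
`df = 13 − 2 = 11`.

## Anomalies

Anomalies remove the monthly climatology and a linear trend per grid cell.
Both are removed in **one joint least-squares projection** onto the span of
the twelve calendar-month indicator functions plus linear time, rather than
sequentially. Removing the climatology first aliases part of any trend into
a 12-month sawtooth that a subsequently fitted single line cannot absorb;
the joint projection has the properties an anomaly operator should have:

* pure seasonal-cycle and pure linear-trend inputs map to exactly zero
  anomalies (to float precision),
* idempotence (a projection applied twice equals once),
* linearity in the input field,
* exact reconstruction: anomaly + climatology + trend restores the input to
  better than 1e−10 of the field scale.

The fit is masked-aware per cell; cells with fewer than 14 unmasked months
fall back to plain per-month centring and are flagged. Trend slopes are
retained (units: field units per month; ×120 for per-decade).

## Correlation, events, composites

The winter CPUE series and the per-winter anomaly fields are correlated
with the uncentred Pearson form `R = Σx'y'/(√Σx'²√Σy'²)`; both inputs are
already detrended anomalies (the seasonal CPUE series is detrended across
winters by `detrend_series`), so no further centring is applied.
Significance is a two-sided Student-*t* test of `t = R√(df/(1−R²))`;
two-sided is the conservative choice where one-sidedness is not dictated by
a directional hypothesis. No multiple-testing correction is applied across
grid cells; field-significance testing would be an extension.

Events are winters whose box-mean subsurface-temperature anomaly strictly
exceeds ±`threshold` × the sample SD (ddof 1) of the full index series
(default threshold 1.0). Composites average member anomaly fields over
event winters; significance is a two-sided one-sample *t* of the member
mean against zero with `df = n_events − 1` — standard composite-analysis
practice. An event whose lagged window precedes the record is dropped from
that lag with `n_events` adjusted; a single-member composite is reported
with its *t* undefined.

Lagged windows are resolved on the calendar, anchored at December of the
event winter: the NDJ window at lag 3 is August–October of the same year,
at lag 12 the previous winter's NDJ; monthly lags shift December itself.

## Phase-speed estimation

Hovmöller diagrams stack monthly-lag composites reduced onto a transect
(nearest grid line, no interpolation — interpolation would smooth exactly
the feature being tracked). The estimator then:

1. lightly smooths each row along the coordinate (Gaussian, σ = 1°;
   symmetric, so a packet extremum is not displaced),
2. anchors the track at the strongest extremum in the search window over
   all lags — anchoring at the earliest lag instead would let a noise peak
   at a signal-free lag poison the whole track,
3. walks outward in both lag directions, re-centring a ±9° continuity
   window on the previous position (wide enough for ~20 cm/s at subtropical
   latitudes); maxima pinned to a window edge are rejected as unresolved,
   values below a noise floor (25% of the diagram's peak) count as gaps,
   and more than 2 consecutive gaps ends the walk,
4. refines each position sub-grid by a 3-point parabola, converts degrees
   to km at the transect's reference latitude (111.32·cos φ km/° for zonal
   sections), and fits position against lag time by least squares
   (1 month = 365.25/12 days).

Speeds are signed positive in the propagation direction being diagnosed
(westward for zonal sections, northward for meridional). On noise-free
uniformly translating packets the estimate is exact to well under 1% for
speeds of 2–20 cm/s.

The theoretical comparison value is the long-wave first-baroclinic limit
`c = β L_d²` with `β = 2Ω cos φ / a` (Ω = 7.292×10⁻⁵ s⁻¹,
a = 6.371×10⁶ m). The deformation radius can be computed from a density
profile in the WKB approximation `L_d = (1/(π|f|)) ∫N dz` (trapezoidal in
the sense of piecewise-constant layer N; exactly `N·H/(π|f|)` for constant
N). The default comparison uses `L_d` = 50 km at 30°N, giving ≈4.96 cm/s —
a representative open-ocean subtropical value; the scenario's own 700 m
profile gives a much smaller radius because it truncates the deep
stratification, and is reported as a diagnostic only.

Mixed-layer depth uses the Δσ = 0.125 kg m⁻³ density-offset criterion with
linear interpolation between levels (a common oceanographic default).
Thermocline depth is the maximum density gradient on layer midpoints below
the mixed layer, ties broken to the shallowest qualifying depth; on a 10 m
level grid a 250 m tanh pycnocline is recovered at 245 m (midpoint
quantization, within half a level spacing).

## Wind stress curl

Curl is computed on the regular lat/lon grid as
`(1/(a cos φ)) ∂τy/∂λ − (1/a) ∂τx/∂φ` — the local-metric form
`∂τy/∂x − ∂τx/∂y` — with centred differences inside and one-sided
differences at the edges. The spherical metric term `τx tan φ / a` is
deliberately dropped, as is common for stress-curl maps: it is below
10⁻⁸ N m⁻³ at subtropical latitudes, and its omission makes the curl of a
constant stress identically zero, a property the test suite relies on.

## The synthetic scenario generator

The generator produces every pipeline input with known truth. Defaults
describe the study conditions; they are set once and are not tuning knobs.

| component | default | rationale |
|---|---|---|
| grid | 26–34°N, 128–170°E at 0.5°, monthly 1993–2018 (312 months) | resolves 1.5° packets while keeping desk-scale runtimes; the analysis window of an eddy-resolving reanalysis era |
| SSH background | seasonal amp 6 cm, trend 1 cm/decade, AR(1) noise SD 3 cm, r₁ = 0.5 | typical interannual SSH variability away from strong currents |
| packets | amplitude 12 cm, σ = 1.5°, zonal 10 cm/s along 30°N, northward 5 cm/s after turning at the coastal box longitude, genesis 155°E | mesoscale anticyclonic anomalies; the northward leg reaches the box ~2 months after the turn |
| event winters | 7 of 26 (1994, 1997, 2001, 2004, 2007, 2011, 2015) | seven warm winters, three inside the CPUE period |
| T150 coupling | γ = 0.1 °C per cm SSH + AR(1) noise SD 0.3 °C | vertically coherent SSH/subsurface response via thermocline heave |
| heave | α = 2 m per cm SSH against a tanh profile (pycnocline 250 m, width 100 m, 0–700 m at 10 m) | deepened isotherms under high SSH |
| CPUE | monthly climatology 20–80 kg/person-day peaking in winter; winter-mean noise SD 6; coupling solved for population ρ = 0.45 | winter-dominated fishery with a moderate, realistic ocean signal |
| catch records | 20 records/month, effort 1–5 person-days, lognormal catch dispersion, rescaled so records pool back to the monthly CPUE exactly | conservation by construction |

Packets are **kinematic** — prescribed trajectories, not dynamics — so the
truth record (per-lag centre positions, implanted speed, event winters,
coupling coefficient) scores every recovery test without re-deriving
generator internals. Packet kinematics convert cm/s to degrees with the
same 111.32·cos φ km/° and month length the estimator uses.

The CPUE coupling coefficient `b` is solved from the target correlation via
the variance budget `ρ = b σ_T / √(b²σ_T² + σ_ε²)`, where σ_T combines (i)
the deterministic packet contribution to the winter box-mean T150 (computed
exactly from the kinematics) and (ii) closed-form winter-mean variances of
the AR(1) noise terms (3-month mean of an AR(1) has variance
σ²(3+4r+2r²)/9; box averaging contributes the cos-lat weight factor
Σw²/(Σw)²). `expected_box_correlation` inverts the same formula, so the
tuning is self-consistent to machine precision. A sample correlation at
n = 13 is biased toward zero by ≈ρ(1−ρ²)/(2(n−1));
`expected_sample_correlation` applies this first-order correction and is
the right comparison for Monte-Carlo means of estimated correlations
(population 0.45 → expected sample mean ≈ 0.435; 200-scenario pipeline
means land within a few hundredths of it).

SLP highs and anticyclonic wind-stress anomalies (from a negative Gaussian
streamfunction) are placed near the genesis longitude in the NDJ season one
year before each event winter. They are statistically plausible patterns
for exercising the compositing code; **no dynamical consistency** between
the wind forcing and the implanted waves is claimed.

### What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
separable climatology/trend/noise, a coherent propagating signal, a linear
CPUE–temperature link with independent noise. Real fisheries and ocean data
violate all of these in degree — effort reporting changes, non-Gaussian and
spatially correlated noise, waves that disperse and interact with the mean
flow, nonlinear and lagged ecological responses. Passing recovery tests
shows the estimators are correct and calibrated under the stated
conditions, not that real catch records contain such signals.

## Numerical choices and degenerate inputs

* Longitudes are canonicalized to [0, 360) internally; writers restore (or
  override) the input dialect. The study domain never crosses the dateline.
* Box averages weight by cos(lat) by default (correct on a regular grid;
  negligible for sub-degree boxes).
* Strict inequality at the event threshold; sample SD uses ddof 1.
* |R| is clipped to 1 before the *t* transform; |R| = 1 is significant by
  convention.
* Zero-variance indices yield no events, with a warning.
* A column never meeting the mixed-layer criterion reports full depth,
  flagged; fewer than three gradient levels below the mixed layer is an
  error rather than a guess.
* All randomness flows from one seed through independent spawned streams
  per field, so scenarios are bit-reproducible.

## Problem sizes

Default test and acceptance runs use the 0.5° × 26-year scenario
(~1 s per realization): 20 realizations for event-recall and noisy
phase-speed medians, 200 for the correlation-recovery mean. These sizes
put Monte-Carlo standard errors well inside the tolerances being checked
(e.g. SE ≈ 0.016 on the 200-seed mean correlation against a ±0.05 band).

## Known limitations

* The vertical-mode eigenproblem is not solved; the WKB radius suffices for
  the single theory value used. Mean-flow modification of phase speed is
  discussed, not computed.
* No effective-df correction for serial autocorrelation in the correlation
  maps (winter-to-winter autocorrelation of the index is weak by
  construction here, and commonly weak in the motivating data).
* No GLM-style CPUE standardization (species, gear, vessel effects).
* Curvilinear grids and sigma-coordinate vertical axes are out of scope;
  inputs are regular lat/lon z-level fields.
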