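# wavecatch

Fisheries–ocean teleconnection analysis: from daily catch records and gridded
monthly ocean/atmosphere fields to catch-per-unit-effort (CPUE) series,
detrended anomalies, correlation maps with Student-*t* significance, ±1 SD
event composites, Hovmöller diagrams, and first-baroclinic Rossby-wave
phase-speed diagnostics.

## The scientific problem

Coastal fish stocks along western boundary currents vary from winter to
winter with the warm water those currents deliver. The chain this package
diagnoses runs, in order:

1. **CPUE** — monthly fish abundance proxied by pooled catch per unit effort,
   `CPUE = Σ catch / Σ effort` (kg per person-day), with a strong winter
   (November–January, "NDJ") season.
2. **Anomalies** — gridded sea-surface height (SSH), subsurface temperature
   at 150 m (T150), SST, SLP and wind stress reduced to monthly anomalies by
   removing the monthly climatology and a least-squares linear trend per grid
   cell.
3. **Correlation maps** — the winter CPUE series `x'` against each cell's
   winter anomaly `y'` via the uncentred Pearson form
   `R = Σx'y' / (√Σx'² √Σy'²)`, with `df = n − 2` (13 winters → df = 11) and
   two-sided Student-*t* significance.
4. **Events and composites** — winters whose box-mean T150 anomaly exceeds
   ±1 sample SD, and lagged composites of the anomaly fields over those
   winters (one-sample *t* against zero, df = n_events − 1).
5. **Propagation** — Hovmöller sections of the monthly composites along a
   latitude line; an anomaly extremum tracked across lags and fitted by
   least squares gives a westward phase speed, compared with the long
   first-baroclinic Rossby-wave limit `c = β·L_d²`
   (`β = 2Ω cos φ / a`; `L_d` the baroclinic deformation radius, here from
   the WKB form `L_d = (1/π|f|) ∫N dz`).

Real catch ledgers and eddy-resolving reanalyses are proprietary or
terabyte-scale, so the package ships a **synthetic scenario generator**
(`wavecatch.synthetic`) that emulates the statistical structure of such data
at desk scale — seasonal cycle + trend + AR(1) red noise per cell, kinematic
westward-propagating Gaussian SSH packets that turn north into a coastal
box, thermocline heave coupling SSH to subsurface temperature, and a CPUE
series coupled to the box-mean T150 anomaly at a configurable population
correlation — with closed-form truth for every implanted signal, so each
pipeline stage is testable end to end.

## Worked example

One command chains the whole pipeline on the default scenario
(0.5° grid, 26 years of monthly fields, 13 years of daily catch records,
7 implanted warm winters, 10 cm/s packets):

```sh
wavecatch demo --seed 1 --out demo_out
```

or in Python:

```python
from wavecatch import pipeline, synthetic
summary = pipeline.demo(synthetic.ScenarioConfig(seed=1), outdir="demo_out")
```

which prints (abridged):

```json
{
  "n_winters_cpue": 13,
  "df": 11,
  "box_correlation": 0.2569,
  "expected_box_correlation": 0.45,
  "event_recall": 0.857,
  "detected_positive_winters": [1994, 1997, 2001, 2007, 2011, 2015],
  "estimated_speed_cm_s": 10.08,
  "theoretical_speed_cm_s": 4.956,
  "speed_ratio_estimated_over_theory": 2.03
}
```

Reading the numbers: 13 CPUE winters give correlation maps with 11 degrees
of freedom. Event detection at the ±1 SD rule recovered 6 of the 7
implanted warm winters (`event_recall` 6/7 ≈ 0.857). Extremum tracking on
the Hovmöller diagram recovered the implanted 10 cm/s westward speed to
within 1%, about twice the theoretical `β·L_d²` value of ≈5 cm/s at 30°N
with `L_d` = 50 km — the expected signature of waves riding a mean current.
The single-realization box correlation (0.26 here) scatters widely around
the implanted population value 0.45, as any 13-sample correlation must
(sampling SD ≈ 0.23); the calibrated check below averages 200 realizations.

Each stage is also a standalone subcommand operating on files
(`simulate`, `cpue`, `anomalies`, `corrmap`, `events`, `composite`,
`hovmoller`, `speed`); run `wavecatch --help`.

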