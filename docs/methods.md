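# Methods

`medpql` predicts how long a Mediterranean fruit fly (*Ceratitis capitata*,
Medfly) quarantine must extend past the last fly detection, for a given
start date and an hourly temperature record, under two models: regulatory
degree-day accumulation and a stochastic agent-based elimination simulator.
This note records the models, their assumptions, the tunable parameters, and
the design choices made where the design was genuinely open.

## Degree-day predicted quarantine length (DD PQL)

Daily degree-days above a base temperature `b` are computed by the
single-sine method: the day's temperature is assumed to trace a sinusoid
between `tmin` and `tmax`, and the area above `b` has the closed form

```
m = (tmin + tmax)/2        a = (tmax - tmin)/2
DD = 0                                     tmax <= b
   = m - b                                 tmin >= b
   = [(m - b)(pi/2 - theta) + a cos(theta)] / pi,   theta = arcsin((b - m)/a)
```

With gap-free hourly data available, simple hourly summation
`sum(max(T_h - b, 0))/24` is provided as a comparator; the two agree to
< 0.05 DDc on days whose temperatures actually follow the sinusoid.

Defaults follow the regulatory standard for Medfly: `b = 12.39` °C
(54.3 °F), 345.56 DDc (622 DDf) per generation, 3 generations, so a
quarantine ends once 1036.68 DDc have accumulated. The DD PQL for a start
date is the smallest whole number of days reaching that sum.

Numerical choices:

* PQL granularity is whole calendar days; the start date's own degree-days
  count (day 1 = start date). No within-day fractional interpolation.
* The single-sine form has no upper developmental cutoff by default (the
  regulatory standard specifies only a base); an optional horizontal
  `upper_cutoff` hook exists.
* A series that ends before the threshold yields a *censored* record that
  carries the partial accumulation, so callers can distinguish "nearly
  done" from "cold-dead".
* The closed form is verified against 10,000-point numerical integration to
  1e-6 DDc over 1,000 random `(tmin, tmax, base)` triples.

## Agent-based predicted quarantine length (ABS PQL)

A non-spatial, stage-structured, individual-based model of an outbreak
under eradication pressure. Stages: egg, larva, pupa, immature adult,
mature adult. Each day, against 24 hourly temperatures, events run in a
fixed order (reordering changes trajectories, so the order is part of the
model):

1. **Development.** Stage `s` accumulates `max(T_h - b_s, 0)/24` per hour
   and advances when the accumulation reaches `DD_s`; excess carries over.
   Sex is assigned (F/M, p = 0.5) at adult emergence.
2. **Acute temperature mortality.** Death with probability `p_cold` per
   hour below `cold_lethal_c`, `p_heat` per hour above `heat_lethal_c`.
3. **Daily mortality.** Baseline `mu_s` combined with control-effort
   mortality as independent hazards:
   `p_death = 1 - (1 - mu_s)(1 - mask_s * control)`. The stage mask
   (default 0.2 for egg/larva/pupa, 1.0 for adults) reflects that sprays
   and SIT-support measures reach exposed adults far more effectively than
   larvae inside fruit or pupae in soil; a uniform mask is configurable.
4. **Mating.** Each unmated mature female mates once for life: sterile with
   probability `p_sit_daily` (inundative sterile-male releases), otherwise
   fertile if at least one living mature male exists.
5. **Oviposition.** Each fertile female lays `Poisson(fecundity * scale)`
   eggs, where `scale = min(max(Tbar - b_egg, 0)/(25 - b_egg), 1)` and
   `Tbar` is the day's mean temperature. The ramp saturates at the 25 °C
   reference: Medfly fecundity plateaus near its thermal optimum rather
   than growing without bound.

A simulation runs until the last living agent of any sex dies; the
elimination day is 1-based from the start date. Because most biological
parameters are only known to within ranges, each *run* sweeps them by Latin
hypercube sampling (one simulation per sampled vector; every parameter
independently stratified into `n` equal-width bins). The ABS PQL of a run
is the day by which 95% of its simulations have reached elimination — the
`ceil(0.95 n)`-th order statistic of elimination days — and is censored if
fewer than that many simulations finish inside the horizon. Runs start
every 7 days by default; the PQL knots are linearly upsampled to daily
values, with censored knots breaking (never bridged by) the interpolation.

Reproducibility: per-run LHS designs and per-simulation RNG substreams are
derived from `(master seed, run index, sim index)` counters, so a runset is
bit-for-bit reproducible and independent of execution order.

### Default parameter ranges

The outbreak-and-intervention ranges describe a typical response campaign:
33–100 initial adult females (plus equal males, all mature, the same age
profile in every simulation), SIT sterilisation probability 0.5–1.0 per
day, control-induced mortality 0.05–0.15 per day. Stage-level biology is
configured, not hard-coded (`data/default_config.yaml`):

| parameter | range | units / note |
|---|---|---|
| DD_egg, DD_larva, DD_pupa, DD_imm | [20,30], [72,92], [128,148], [90.6,110.6] | DDc; midpoints sum to 345.56 so the two models stay commensurable |
| b_s (all stages) | [11.39, 13.39] | °C, centred on the regulatory base |
| mu_egg, mu_larva | [0.015, 0.05] | baseline deaths/day |
| mu_pupa | [0.01, 0.04] | pupae are the most protected stage |
| mu_imm, mu_mat | [0.02, 0.06], [0.03, 0.10] | deaths/day |
| fecundity | [1.0, 2.2] | eggs/female/day at 25 °C, under intervention |
| cold_lethal_c, p_cold | [-6, -1] °C, [0.05, 0.2]/h | acute kill at frost, not at every cool night |
| heat_lethal_c, p_heat | [36, 42] °C, [0.02, 0.1]/h | acute heat stress |

These stage-level values are implementer-calibrated placeholders chosen
once, by two a-priori criteria: (i) the deterministic net reproduction
number R0 (daughters per female: fertile-mating probability x eggs/day x
adult life expectancy x egg-to-adult survival x 1/2) stays below 1 for all
but ~1% of sampled vectors even at 27 °C, so elimination is the typical
outcome — the regime the quarantine question presumes; and (ii) resulting
ABS PQLs fall in a realistic 50–250 day band with winter dips driven by
rare brief cold snaps rather than by routine cold nights. The ensemble
size defaults to 250 per run at desk scale; 2500 (the full-fidelity size)
is retained in the config.

## Synthetic climate generator

The generator stands in for multi-decade station records. It produces, per
hour: an annual sinusoid (`annual_mean` ± `annual_amplitude`, warmest on
day-of-year `annual_phase`, default mid-July), a diurnal sinusoid peaking
at `diurnal_phase` (default 15 h), stationary AR(1) noise (marginal sd
`noise_sigma` = 2 °C, hour-to-hour correlation `noise_rho` = 0.95, i.e. a
weather decorrelation time of about a day), and Poisson-count cold snaps
(default 3/year, 6 h, 12 °C below the seasonal curve) emulating the rare
brief lethal-cold events that matter for the agent model. Optional defect
injection (gross spikes of 25–40 °C, record gaps) exercises the cleaning
stage, with every defect written to an injection log so cleaning can be
validated against ground truth.

What it deliberately does not emulate: humidity/wind, daylight-saving or
time-zone bookkeeping (timestamps are local standard time), long-term
trends or inter-annual regimes (El Niño years), asymmetric heat waves, and
spatially correlated weather between sites. Tests passing on this
generator therefore demonstrate the *machinery* (cleaning, accumulation,
simulation, aggregation) and the qualitative seasonal/cold-snap structure,
not station-accurate quarantine lengths. One concrete consequence of the
missing inter-annual variability: degree-day PQLs become almost a pure
function of day of year (normal-R² near 100%), so in the paired comparison
the degree-day deviations from the mean normal are *smaller* than the
agent-model deviations (which carry finite-ensemble noise) — with real
multi-decade weather the degree-day model is the more erratic of the two.

## Cleaning

Raw observation series are cleaned in the order: outlier removal →
resampling to every hour on the hour → gap filling. Outliers are records
deviating more than `threshold_c` (default 15 °C) from the centred rolling
median over ±`window_hours` (default 24 h). Grid hours bracketed by
observations ≤ 3 h apart are linearly interpolated in time; hours inside
larger gaps are filled day-over-day (same hour of day, linear across the
nearest bracketing days that have an observed or small-gap value at that
hour). A large gap touching a series boundary is an error, never an
extrapolation. Conflicting duplicate timestamps resolve to their mean.
Partial first/last calendar days are excluded from daily extremes.

Known limitation: the rolling-median rule cannot distinguish a *real* cold
excursion deeper than `threshold_c - diurnal_amplitude` from a sensor
spike — a night-time cold snap of depth ≥ ~10 °C sits that far below the
49-hour rolling median. The cleaning-is-identity property therefore holds
for snap-free input; on snapped input the cleaner may clip the deepest
snap hours (they are re-filled by interpolation from the adjacent, still
cold, hours).

## Statistics

*Normals.* All values for the same calendar (month, day) irrespective of
year are aggregated — deliberately without running-mean smoothing — into
n, mean, min, max, σ, quartiles. σ is the population (divisor n) standard
deviation, consistent with min/max being population summaries; sample σ is
a flag away. Quartiles use linear interpolation between order statistics.
Feb-29 is kept as its own key with smaller n.

*Variance capture.* `normal_r2 = 1 - Σ(y - ŷ_doy)² / Σ(y - ȳ)²` (reported
as a percentage), where `ŷ_doy` is the mean normal for the value's calendar
day — the fraction of PQL variance explained by the seasonal cycle alone.

*Latitude.* OLS of per-site median PQL on latitude; F and p from the
regression's overall test (statsmodels).

*Historical matching.* Outbreak locations map to the nearest of the
packaged 11 reference stations by haversine distance; ties break to the
lower latitude, then callsign order. The paired DD-vs-ABS contrast uses a
paired t-test on the differences and a two-sided variance-ratio F-test on
the deviations of each method from its own mean normal (larger variance
mirrored into the numerator; one-sided available by flag since the
direction can be stated a priori).

## Known limitations

* **Daily mortality is temperature-independent.** With the per-day hazard
  structure used here, cold slows development but does not change baseline
  death rates. Consequently cold-climate immature cohorts persist no longer
  than warm-climate subcritical reproduction chains, and the agent model
  does not reproduce a positive latitude gradient in *median* ABS PQL the
  way a temperature-dependent-mortality model can; the degree-day latitude
  gradient is strong and robust. The ABS latitude slope should not be
  interpreted quantitatively from this package.
* No density dependence, spatial structure, explicit sterile-male cohort
  dynamics, or genetics; elimination is guaranteed only because the
  parameter ranges keep the swept population subcritical.
* The 95% ensemble threshold is a statement about parameter-space coverage,
  not about the elimination probability of any single outbreak.
* Desk-scale problem sizes are the package's defaults: the test suite runs
  a 20-year synthetic site with 100-simulation runs every 14 days, and the
  acceptance script a 10-year site at the same ensemble size; the full
  reference design (2500 simulations per run, every 7 days, 43–66 year
  records, 11 sites — about 86 million simulations) is expressed in the
  config but not executed by default.
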