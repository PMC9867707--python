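# Methods

`fullcycle` turns year-round GPS + tri-axial acceleration biologging records
of a migratory gull into daily energy expenditure and annual-cycle
statistics. This note documents the models, the numerical choices, and what
the synthetic data generator does and does not emulate.

## Activity energetics

Each GPS fix is followed by a 1-s burst of tri-axial acceleration (20 Hz on
the reference tags). The static (gravitational) component is removed by
subtracting the per-axis mean over the burst; dynamic body acceleration is
the burst mean of the per-sample vector norm,

    DBA = mean_t sqrt(x_t² + y_t² + z_t²)   [g],

the VeDBA convention. Averaging per-sample norms (rather than taking the
norm of per-axis sums) makes DBA independent of burst length and invariant
under sensor-frame rotations; both properties are tested.

Behavior labels from an upstream classifier are reduced to four modes.
Activity metabolic rate per fix is

| behavior                  | MR (W)              |
|---------------------------|---------------------|
| stationary (not floating) | 4.80 + 49.80 · DBA  |
| flapping flight           | 32                  |
| soaring flight            | 7.9                 |
| walking                   | 8.5                 |
| floating                  | 6.6                 |

The calibration applies only to non-floating stationary behavior because
behavior-specific calibrations could not be resolved for the locomotory
modes; those use fixed average costs. DBA is in g; the slope is W per g.

## Thermoregulation

Resting birds below their lower critical temperature must produce heat. The
model works on an operative temperature and a wind-scaled conductance:

    T_e  = T_a + r · R_g
    K(u) = k0 · (1 + c · sqrt(u))
    MR_thermo = basal                          if T_e ≥ T_lc
              = basal + K(u) · (T_lc − T_e)    otherwise

with T_a the 2-m air temperature (°C), R_g surface solar radiation (W m⁻²),
u the 10-m wind speed (m s⁻¹). This preserves the monotone structure of
heat-exchange models for birds — cost falls with temperature and solar
gain, rises with wind — while keeping every constant in `ThermoConfig`
(YAML-loadable). Defaults: `basal = 4.59 W` (the captive resting rate,
396.4 kJ day⁻¹, expressed in W), `T_lc = 10 °C`, `r = 0.01 °C per W m⁻²`,
`c = 0.2 per sqrt(m s⁻¹)`, and `k0 = 0.15 W °C⁻¹`, chosen so that a
mid-winter UK residence raises stationary metabolic rate by roughly
10–25 kJ day⁻¹ — enough to flatten the annual profile of short-distance
migrants without dominating it. Species-specific constants from respirometry
should replace these defaults when available; only the monotone structure is
relied on by the analysis. No heat-stress costs at high temperature, and no
water-conductance surcharge while floating.

**Max-rule.** Thermoregulatory heat is assumed to be substituted by activity
heat, so each fix costs `max(MR_activity, MR_thermo)`; ties return the
common value. Daily energy expenditure is the day's mean per-fix MR times
86.4 (kJ day⁻¹ per W). Time budgets allocate 24 h by fix counts; energy
fractions allocate summed MR.

## Annual-cycle segmentation

* **Displacement**: haversine distance (sphere radius 6371.0088 km) between
  the fixes closest to consecutive UTC midnights (tolerance ±6 h, else the
  day is missing). Days moving **strictly more than 70 km** are relocation
  days; the boundary value is stationary (configurable).
* **Breeding** is anchored on colony association: the last detection within
  10 km of the colony before the long nonbreeding absence, and the first
  detection after it.
* **Winter area**: Gaussian KDE of the nonbreeding *residence* positions —
  fixes on stationary days between colony departure and return; transit
  fixes strung along travel legs would bridge otherwise-distinct core areas
  at the 95% level — on a Lambert azimuthal equal-area projection centered
  on their mean, evaluated on a 200×200 grid, thresholded at the density
  level enclosing 95% of the mass. The kernel bandwidth is fixed at 25 km
  (isotropic). Scott's rule is available but documented as unsuitable for
  migratory tracks: with residence clusters thousands of km apart it
  inflates the bandwidth until stopover and winter clusters merge into one
  contour. 25 km resolves clusters ≳150 km apart and yields core areas of
  order 130 km across, matching the study system's scale. Components
  holding <1% of the KDE mass are discarded as grid artifacts; of the
  remainder, the one with the southernmost mass-weighted centroid is the
  wintering area.
* **Winter period**: first to last stationary day whose mean daily position
  falls inside that core area; the migration stages are what lies between
  breeding and winter. Relocation days inside migration stages are migration
  days, stationary ones stopover days. Missing days flanked by stationary
  days inherit stationary.
* **Strategy** from the winter centroid via lat/lon boxes (Africa split at
  25°N; Iberia checked before North Africa so the Gibraltar overlap resolves
  to Spain); polygons are user-overridable.

## Subsampling, coverage and gap filling

Days are subsampled to a common interval: the smallest value in [20, 60] min
that is at least the day's largest between-fix gap; the earliest fix per bin
survives. Bird-years need data on ≥75% of days (evaluated **before** gap
filling — a filled year would trivially pass, which would defeat the
filter). Gaps are detected as between-fix intervals above 3× the nominal
sampling interval. A gap whose bounding fixes lie >70 km apart means the
bird relocated unobserved; such bird-years are discarded
(`RelocationDuringGap`). Otherwise each missing slot on the sampling grid
draws a donor fix uniformly (without replacement per window, falling back to
with-replacement) from the surrounding stationary period within ±1 h
time-of-day, widening stepwise to ±3 h with warnings. Filled fixes carry the
donor's behavior, DBA and location but the slot's own timestamp, so
thermoregulation is evaluated against the weather of the missing moment.
Simulated fixes are flagged, included in DEE/AEE and stationary-MR
statistics, and excluded from time-allocation exports.

## Summary statistics

* **AEE**: mean DEE over the bird-year (366 days in leap years).
* **Sum of deviance**: Σ_t |moving-mean_w(DEE)_t − AEE| for w ∈ {1, 7, 30};
  centered windows; for w > 1 only full windows contribute (truncated edge
  windows would inflate the sum; the alternative is available as
  `edges="truncated"`). Smoothing can only contract the sum — tested by
  brute force.
* **Extreme weeks**: greedy selection on the 7-day moving mean, most extreme
  first, each pick blocking its seven days; highest weeks ranked by largest
  window mean, lowest by smallest; ties break to the earliest center date
  (determinism). Greedy equals sequential exhaustive search by construction
  of the definition; tested against an independent brute-force oracle.
* **Migration table**: per strategy × season, mean ± SD across bird-years of
  period length (stopovers included), migration-day counts, and DEE/flight
  hours on migration days.
* Mixed-model fitting (LMM/GAMM/ARMA) is delegated to external statistics
  software; `export_model_tables` writes tidy per-bird-year and per-bird-day
  tables for it.

## The synthetic generator

`synthetic_tracks` exists so every downstream stage is testable without
field data. Four strategy templates (colony 53.0°N 4.7°E; winter centroids
51.0°N −0.5°E, 39.5°N −8.5°W, 31.5°N −9.5°W, 14.7°N −17.0°W) encode
realistic schedules: autumn migratory periods of 33–123 days with long
stopovers, short spring returns (16–21 days), 5–18 travel legs per season
with leg displacement well above the 70-km threshold, and flight bouts of
6–17 h (truncated normal, mean 9) on travel days. Stage budgets put
14–16% of breeding fixes in flapping flight and 74–83% of winter fixes
stationary (up to ~19.9 h day⁻¹ for the longest-distance template).
Day-to-day (lognormal σ = 0.15) and bird-to-bird (σ = 0.20) activity
multipliers reproduce the high individual variation real cohorts show.
Budgets were set from the published time-budget and energy scales of the
study system, then balanced analytically (via `expected_aee`, the
closed-form activity-only expectation) so that strategies differ in the
*distribution* of expenditure over the year much more than in its annual
mean — the study system's signature pattern.

Weather is a deterministic seasonal+diurnal sinusoid field with Gaussian
noise: mean temperature `28 − 0.33·lat + 0.14·lat·cos(2π(doy−202)/365)`
plus a ±3 °C diurnal cycle, solar radiation from the astronomical elevation
(exactly zero at night) times a cloudiness factor, Rayleigh-like wind. The
field gives sub-10 °C winters at 52°N and winters that never drop below
10 °C at 15°N. Draws are keyed on (seed, location, day, hour), so gap-fill
weather lookups are reproducible.

Positions follow stage anchors with an AR(1) wander (σ_step = 0.01°,
ρ = 0.99 when resident) — winter areas spread over tens of km while
day-to-day displacement stays a few km — plus 0.003° per-fix jitter. The
bird slips ~12 km outside the colony radius before its first travel day and
roosts ~12 km short on its last, so the day-level colony-detection
boundaries are exact.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: realistic flight paths (wind drift, thermalling),
behavior autocorrelation within bouts outside migration, habitat structure,
weather autocorrelation and fronts, tag failure other than clean gaps,
classifier error in the behavior labels, and any physiological variation
(molt, mass change) in resting costs.

`generate_validation_days` builds a separate high-resolution (2.5-min)
validation set for the interval-sensitivity analysis: single-location days
whose flight bouts vary uniformly between 0 and 14 h, mirroring a real
breeding-season validation set where flight time drives the day-to-day DEE
spread. Regressing subsampled DEE on native DEE on these days yields slopes
within a few percent of 1 (no systematic bias from coarser sampling), with
median absolute errors of ~4% at 20 min and ~8% at 60 min.

## Problem sizes and runtime choices

Cohort-level checks use 20 bird-years per strategy at the 20-min default
interval (~26k fixes per year); the interval-sensitivity analysis uses 200
validation days; oracle-equivalence checks use 1000 random pairs/series.
`winter_core_area` thins its input to ≤800 positions (uniform stride) before
evaluating the KDE grid; the estimate is insensitive to this because
residence clusters contain hundreds of near-duplicate positions. The
Monte-Carlo unbiasedness check for gap filling uses 40 replicates, each a
fresh bird-year with a fixed 26-day winter mask, comparing the filled
period mean against the fully observed one; the bound is two standard
errors of that sample.

## Known limitations

* The thermoregulation constants are structural defaults, not respirometry
  fits; absolute winter thermoregulatory costs should not be interpreted,
  only their monotone behavior and order of magnitude.
* Stage labels are day-granular; a travel leg falling on the colony-
  detection boundary day can be attributed to breeding, so recovered
  migration-day counts can be one short of the schedule.
* The KDE winter area assumes residence clusters are compact relative to
  their separation; nomadic winters would need a different estimator.
* `coverage` counts a day as covered if it has a single fix; it does not
  weight within-day completeness.
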