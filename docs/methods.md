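# Methods

This note documents the models, decision rules, numerical choices and
known limitations of the pipeline, in the order the data flows through
it.

## Track cleaning

Three screens run in sequence, each leaving a per-fix `qc_flag` so that
retained + flagged always equals the input count:

1. **post-capture window** — fixes within 7 days of the capture date are
   dropped (handling effects);
2. **satellite count** — fixes acquired with ≤ 2 satellites are dropped;
   if the input has no satellite column the screen is skipped with a
   logged warning;
3. **speed** — a fix whose straight-line speed from the previous
   *retained* fix exceeds 20 km/h is dropped. The filter runs in a
   single forward pass, so a removed blunder is never used as the speed
   reference for the fixes after it and one bad fix cannot cascade.

Duplicate timestamps keep the first record. A track with fewer than 100
survivors is marked unusable rather than raising, so one bad collar
does not abort a cohort run. Coverage is adequate when the series
starts ≥ 30 days before spring departure and ends ≥ 90 days after the
fall return (residents: a full year).

Geographic coordinates are projected to a single metric CRS with a
built-in WGS84 transverse-Mercator (UTM) implementation (sixth-order
series). Its correctness is pinned in the test suite by meridian-arc
quadrature, conformality of the numerically differentiated forward map,
the 0.9996 central-meridian scale, and sub-centimetre round-trips. The
DEM is a single-band ESRI ASCII grid sampled by nearest cell (no
interpolation — the 20 m product's granularity is the native
resolution of the answer).

## Migration detection from net squared displacement

Field studies usually date migrations by visual inspection of NSD
plots. The detector here is a deterministic surrogate with every
constant exposed in `DetectorConfig`:

* daily series: per-day median of per-fix NSD, then a centred 3-day
  rolling median;
* winter radius `r_w`: 95th percentile of √NSD over the 30 days after
  the reference date (15 March, pushed later if capture + 7 d or the
  series start falls later);
* candidate days: smoothed NSD above `plateau_frac = 0.5` × the 95th
  percentile of the smoothed series; runs shorter than 3 days are
  ignored as blips;
* migrant verdict: longest run ≥ 30 days **and** its median displacement
  > 2 × r_w. Both conditions matter — a resident's jitter produces long
  runs above half of a small threshold, but never at twice its winter
  radius;
* the plateau period spans the **first to the last** candidate run, not
  just the longest one. A vacillating migrant's returns split its
  summer into several runs; anchoring dates to the longest run alone
  would misdate spring arrival by weeks;
* date refinement: spring arrival is the first day at ≥ 85%
  (`arrival_frac`) of the plateau's median NSD, fall departure the last
  such day; spring departure is the last prior day at ≤ r_w², and the
  fall return the first subsequent day at ≤ r_w² whose following
  30-day window has median smoothed NSD ≤ r_w². The median-window form
  is deliberate: winter jitter is autocorrelated, and a literal "30
  days strictly below" is essentially never satisfied at a
  95th-percentile radius;
* fix-level transit bounds (last in-winter fix → first at-plateau fix)
  are attached to the event and used for route distances, so
  pre-departure residence wander is not counted as travel.

The detector is invariant to translation and rotation of the
coordinates (it sees only distances), and on near-noise-free tracks its
dates move ≤ 1 day when the fix rate doubles.

Vacillations are counted inside the summer window as maximal intervals
of ≥ 6 consecutive fixes inside the winter 95% polygon.

**Resident seasons.** Residents have no dated migrations, so their
seasons come from the migrant cohort: summer = [66th percentile of
spring-end dates, 33rd percentile of fall-start dates], winter
analogously, computed on day-of-year ordinals with linear interpolation
and rounded half-up. Fall-end dates spilling into January are mapped
past day 365 first so a late outlier cannot wrap the window. With fewer
than 3 migrant events the pipeline falls back to a configured template
(defaults: summer 26 Jun–18 Aug, winter 5 Oct–12 Jun).

## Brownian bridge UDs

Between fixes z_a, z_b with gap T the bridge position at fraction α is
N((1−α)z_a + αz_b, Tα(1−α)σ₁² + ((1−α)²+α²)σ₂² · I). The UD is the
equal-weight mean of all bridges with gaps ≤ 24 h (longer gaps are
skipped and reduce the denominator).

Numerics:

* α is integrated by a midpoint rule, `n_alpha = 10` steps per bridge by
  default (configurable; correctness tests run at 1000 against a dense
  brute-force quadrature, agreeing to < 1e-6 per cell);
* each α-slice's per-cell mass is **exact**: separable products of
  Gaussian CDF differences over the cell edges, truncated at 6 SD
  (truncation loss ~4e-9), so mass is conserved to well under 1e-6;
* the grid is 50 m, origin snapped to a multiple of the cell size. All
  surfaces of one study therefore share a global lattice, and overlap
  percentages, stopover screening and band-corridor averaging are exact
  cell-set arithmetic; padding is generous enough that doubling it
  changes isopleth areas by < 0.5%;
* σ₁ is fitted per analysed segment (each season, each corridor) by
  maximising the leave-one-out likelihood — odd-indexed fixes scored
  under the bridge of their even-indexed neighbours — over log σ₁ on a
  bounded bracket, with σ₂ fixed at 30 m. Coincident-fix degeneracy
  returns the lower search bound and a warning. Calibration: median
  relative error ≈ 4% on 1000-fix Brownian tracks;
* isopleths rank cells by density with row-major index tie-break and
  take the smallest prefix reaching the target mass (a 1e-12 relative
  slack prevents float accumulation from overshooting an exact
  boundary by one cell). Areas are 0.25 ha per 50 m cell.

## Ranges, bands, fidelity

Seasonal ranges are 95% isopleths over the season windows (≥ 30 days of
data required). The migrant rule uses the summer range's percentage of
the winter range, strict `< 20%`. Thresholds phrased as "overlap >
X%" are applied to the percentage of the *smaller* range; >70% plus a
co-movement score (> 50% of time-matched fix pairs within 500 m within
1 h) defines band edges, and bands are the connected components of that
graph. Winter fidelity requires > 50% overlap for every
consecutive-year pair.

## Corridors and stopovers

Corridor UDs use the fixes of the fix-level transit window padded by
24 h on each side, anchoring the bridges into both seasonal ranges.
Route distance is the cumulative Euclidean step length over the transit
fixes; the per-female reported value is the spring distance, falling
back to fall when spring is missing (configurable: fall/max/mean).
Observation noise and path wiggle inflate a cumulative step length by
roughly E√(d² + 2σ²)/d per step — ~2% on a fast 30 km leg at 2 h fixes
— which is measured, not corrected.

Stopovers: top-10% isopleth of the corridor UD → 8-connected cell
components → drop components touching either seasonal 95% range (this
also removes the dense padding clusters at the corridor ends) → drop
components with < 12 h of occupancy (inter-fix intervals attributed by
the spatial midpoint of each step) → merge components whose cell-edge
distance is < 300 m (union-find over the proximity relation, hence
order-independent and a fixed point in one pass). Band corridors are
cell-wise means of member UDs on the union grid, renormalised.

## Altitudinal classification

Daily mean elevations, smoothed by a centred 14-day (±7 d) moving mean;
gaps longer than the window leave the moving mean undefined. Seasonal
medians are over per-fix elevations inside the season windows. The
taxonomy (checked in this order):

1. **traditional**: |winter median − summer median| > 250 m (sign
   convention: Δ = winter − summer, negative when summer is higher);
2. **abbreviated**: winter and summer medians both > 150 m above the
   spring moving-mean minimum, and both > 100 m above the fall minimum;
3. **altitudinal resident**: moving mean inside a 150 m envelope all
   year; otherwise "mixed" with a flag (treated as resident in the
   final label, logged).

Phase minima are searched around the transition into/out of summer:
±14 d for migrants (whose transitions are dated), and a 75-day lead
before summer for residents — their spring descent happens weeks before
the template summer starts (mid-April to mid-May descents against a
late-June summer window), so a ±14 d window would systematically miss
the descent the rule is meant to detect.

Verdicts are invariant to adding a constant to all elevations, and
raising the 250 m cut can only move animals out of "traditional".

## Strategy label

Decision order for geographic migrants: ≥ 2 vacillation returns → VAC;
route > 20 km → LDM; else SDM (a tie at exactly 20 km is SDM — the
cut-off is read as strictly "greater than" for long-distance, and
logged). Geographic residents take their altitudinal pattern
(TRAD_ALT / ABR_ALT / RESIDENT). The geographic label takes precedence
over any concurrent altitudinal pattern. The distance is stored on
vacillating migrants too, so a long/short sub-classification of VAC
remains recoverable.

## The simulator: what it emulates, and what it does not

`synthetic_data` generates collar data as an anchor path (residence
centroids, constant-speed waypoint legs, stopover and vacillation
dwells) plus AR(1) positional jitter with segment-specific stationary
SD (500 m on seasonal ranges, ~100 m in transit, 80 m at stopovers) and
30 m Gaussian observation noise, all deterministic given the seed.
Schedules default to the studied population's medians: 2 h fixes from
1 Mar to 31 Dec, spring 12–19 Jun, fall 1–13 Sep (~100-day winters,
~70-day summers). Archetype geometry: 30 km (LDM), 10 km (SDM), 12 km
with three 24 h returns (VAC), 1.6 km across a 25% ramp (TRAD_ALT,
~400 m seasonal elevation shift while geographically resident), 1 km
along a ridge crest with 18-day valley excursions in April and
September–October (ABR_ALT), and 0 (RESIDENT). Bands share one
realised path (sheep bands move as a gregarious unit) with ~100 m
individual jitter. Elevations always flow through the DEM-sampling
path — the generator never assigns them directly — so elevation tests
exercise the raster machinery end to end.

Not emulated: resource selection, memory, snow, variable fix success
beyond uniform dropout, collar drift, or fat-tailed location error.
Recovery rates on this generator therefore demonstrate the pipeline's
internal consistency and the detectability of the archetypes under
realistic noise magnitudes, not performance on any particular field
data set.

Validation sizes (chosen to exercise each claim with sampling room to
spare): 60-track recovery suite (10 per archetype) for labels and
dates; 20 seeds × 1000 fixes for σ₁; 16 simulated females in 9 bands of
sizes (1,1,2,3,1,2,2,2,2) for the band partition.

## Known limitations

* Absolute UD areas depend on α-resolution, grid padding and the σ₁
  fit; published hectare values from other software are reproducible in
  distribution, not bit-exactly.
* The NSD detector assumes one migration cycle per year; double
  migrations or nomadism fall out as "resident" or truncated events.
* Band assignment needs temporally overlapping collars; the co-movement
  score is undefined (0) for disjoint deployments.
* The percentile season template inherits the migrant cohort's
  composition; with < 3 migrants the configured fallback dates apply.
* GeoTIFF rasters are not read; convert to ESRI ASCII grid first.
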