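# Methods

## Trajectory model

`mothtraj` advects passive air parcels through a gridded horizontal wind
field. The model is deliberately minimal: insects are treated as passive
tracers at a fixed release height, with no flight behaviour, no boundary
layer physics, no terrain, and no dispersion. This is the kinematic
trajectory abstraction used throughout the wind-borne-migration
literature; everything the package infers (frequency maps, hit ratios,
candidate pairs) is conditional on that abstraction.

Winds live on a regular latitude–longitude–time lattice
(`WindField`). Sampling is bilinear in space and linear in time, which
reproduces stored values exactly at grid nodes and stored times.
Integration uses the two-stage predictor–corrector (Heun's method)

    P' = P + V(P, t) Δt
    P(t+Δt) = P + ½ [V(P, t) + V(P', t+Δt)] Δt

with an internal step of 6 minutes (`internal_dt = 0.1 h`) and hourly
recorded output. Backward trajectories integrate with Δt < 0, sampling
the wind valid at the correspondingly earlier times; the time-reversal
tests confirm the forward and backward paths close on each other with an
error that shrinks with Δt.

Metres convert to degrees through a local equirectangular metric:
1° latitude = 111,320 m and 1° longitude = 111,320·cos(lat) m. This is a
regional mid-latitude approximation — wind-field constructors reject
domains touching the poles, and longitudes wrap at ±180°. Parcels that
leave the horizontal domain, outrun the field's time coverage, or exceed
the model top are **truncated** and flagged, never extrapolated:
extrapolated winds would be fiction, and the flag keeps the loss visible
downstream.

Vertical handling has two modes. When the field carries a vertical
velocity and `vert_motion` is set, height is advected with w (clamped at
the ground, truncated at `model_height`); otherwise parcels stay at their
release height. The horizontal wind is a single-level field either way —
the synthetic regimes are barotropic by construction — so height never
enters the horizontal interpolation.

### Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| `height` | 1000 | m AGL | release level of the nocturnal transport layer the campaign design assumes |
| `duration` | 72 | h | physiological flight-endurance horizon for the target moths |
| `daily_hours` | 0–23 | h UTC | hourly releases on each simulated day |
| `model_height` | 20,000 | m | vertical cap; parcels above it truncate |
| `output_interval` | 1 | h | recorded-position cadence |
| `internal_dt` | 0.1 | h | integrator sub-step; small enough that halving it moves 24-h endpoints by <10⁻³ deg on smooth fields |
| raster resolution | 0.1 | deg | frequency-analysis cell size |

## Occurrence semantics

Trap counts arrive either daily or interval-censored (counts attributed
to an inspection interval). Comparison grids are keyed on fixed sampling
periods — 7-day bins from the campaign start with a truncated final bin,
labelled `mm/dd-mm/dd`. Date membership is inclusive on both ends and
periods must not overlap. Interval-censored counts are attributed wholly
to the period containing the inspection date; uniform spreading across
the gap would be the alternative, but whole-attribution is the simplest
defensible rule and is what the filtering step needs. The Step-2 filter
keeps exactly the trajectories whose (site, release period) has a
positive count; it is idempotent, and releases falling outside every
period are dropped and logged.

## Frequency raster

"Passing through" is operationalized as hourly-point membership: a cell's
`nhits` is the number of **distinct trajectories** with at least one
recorded point in the cell, never a point count — three points of one
trajectory in one cell contribute 1. Cell membership is half-open,
[edge, edge + resolution) on both axes, and grid edges snap outward to
multiples of the resolution from a global (−90, −180) anchor so cell
boundaries are identical across runs. A `densify` option interpolates
extra points per hourly segment for users who want near-segment
semantics; with hourly output and the default wind speeds a parcel moves
well under one 0.1° cell per hour, so the default point semantics loses
little. On disk the raster is an ESRI ASCII grid (integer counts,
geographic WGS84), chosen because it round-trips exactly and diffs in
tests.

## Zonal summary

A raster cell belongs to a district iff its **center** lies strictly
inside the polygon. Cell-center membership (rather than area-weighted
overlap) matches common raster-masking semantics and is exactly testable
against a brute-force oracle; strict interiors mean a center on a shared
boundary counts for neither district, which keeps disjoint tilings
partition-consistent. Zero-count member cells are included in the
denominator of `nhits_mean`. Districts with no member cells report a
*missing* mean, not zero — choropleths render both neutral grey, but the
attribute table keeps the distinction. `find_max_regions` returns every
district tied at the maximal defined mean and flags none when all means
are zero. Choropleth colors are min–max normalized per map, so maps are
comparable in pattern but not in absolute scale.

## Comparison and matching

Each (trap, period) cell gets a two-letter label, model first:
O = some retained trajectory released in that period has a recorded
point inside the trap's target polygon, X otherwise; the second letter is
O iff the trap's count is positive. The target polygon defaults to the
administrative district containing the trap; a circular buffer
(`trap_buffer_km`) is the region-free alternative. A period's model-O
uses trajectories *released* in the period — release time is the only
timestamp the weekly grids key on.

Hit ratio = 100·n(O-O)/[n(O-O)+n(O-X)] per location (column) or period
(row). X-O and X-X cells never enter either side: with a handful of traps
per country they reflect ground-truth sparseness, not model error. An
empty denominator is reported as 0% with `defined=False` rather than
omitted, so tables stay rectangular.

Candidate (origin, destination, period) pairs require four simultaneous
pieces of evidence: backward-grid O-O at the origin, forward-grid O-O at
the destination, a backward trajectory released at that destination
crossing the origin's polygon in the period, and a forward trajectory
released at that origin crossing the destination's polygon in the same
period. Both directions must share identical period bins; driving both
from one `RunConfig` enforces this. Pairs are deduplicated and sorted by
(period, origin, destination).

## Synthetic scenarios

`synth` generates every input. Wind regimes: `uniform` (closed-form
straight trajectories), `solid_rotation` (circular streamlines, a
radius-conservation oracle), and `westerly_jet`
(u = U0 + A·sin(2πlat/L), v = V0·sin(2πlon/M) — a sheared westerly with
a standing meander, the reference regime). Districts are rectangular
tilings. The planted-migration scenario puts one emitting origin and two
decoy origins (different latitudes, same longitude) in the upwind
country and five jittered destination traps downwind; all origins draw
Poisson(`emission_rate` = 20) weekly counts, but only the true origin's
forward plume reaches the destinations.

Two generator choices are deliberate:

- **Delivery by radius, not by polygon.** A destination receives moths
  when it lies within `connect_radius_km` (100 km) of an integrated
  forward-trajectory point. Using a distance rule in the generator keeps
  the planted truth independent of the pipeline's own polygon-membership
  conventions, so recovery tests do not test the code against itself.
  Captured counts are 1 + Poisson(capture_rate·emission_rate) with
  probability `capture_rate` = 0.8, else 0 — a thinned, guaranteed-
  positive capture model standing in for real trap series, which are
  overdispersed and seasonal in ways this generator does not imitate.
- **Strip districts upwind.** Origin-country districts default to six
  2°-tall latitudinal strips. Under a predominantly zonal flow a backward
  corridor crosses *every* longitude at one latitude band, so a 2-D
  district grid would tie (up to sampling noise) along the corridor and
  the maximal-mean district would be arbitrary; latitude strips make the
  argmax well defined while still forcing the analysis to discriminate
  among six candidate bands, including both decoy bands.

Passing recovery tests therefore show that the pipeline's counting,
filtering, summarizing and matching logic is correct under
advection-dominated transport with a genuinely connected source; they do
not show that real moths follow passive trajectories, that real count
noise is Poisson, or that real districts behave like strips.

## Problem sizes and determinism

The recovery test runs 10 seeded scenarios of 960 backward plus 576
forward 72-h trajectories each (one release day per period, hourly
releases), integrating all parcels of a campaign as one vectorized batch;
a scenario completes in a few seconds. All generators are pure functions
of their spec and seed; pipeline artifacts (CSV, ASCII raster, GeoJSON)
are byte-identical across reruns with the same seed.

## Known limitations

- Single-level winds: no vertical shear sampling even in w-advection
  mode; real HYSPLIT runs interpolate between pressure levels.
- Point-based crossing/rasterization semantics (bounded by `densify`,
  but segment–cell intersection is not implemented).
- Equirectangular metric degrades at high latitudes; polar domains are
  rejected rather than handled.
- Interval-censored counts are attributed to the inspection date's
  period; no uniform-spreading option.
- No statistical uncertainty on hit ratios or `nhits_mean`; the outputs
  are descriptive, as in the validation workflow they feed.
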