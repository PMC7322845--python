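# Methods

This note documents the models, parameter choices and numerical conventions
behind `plasmascape`, and what the synthetic-data tests do and do not show
about real tracking data.

## Spatial sample unit

The analysis treats each individual as a single spatial observation: a
time-integrated weighted mean foraging location paired with its plasma
δ13C/δ15N values. The justification is isotopic: blood plasma turns over
with a half-life of days, so a sample integrates roughly the preceding week
of diet (`window_days = 7`, tunable). Foraging-labelled fixes from trips
ending inside that window are binned onto a grid; each fix contributes its
nominal sampling interval (1 h flying, 2 min diving after resampling) to its
half-open cell; cell weights are normalised and the weighted mean of cell
centres is the location. Trips straddling the window start are trimmed to
the window rather than excluded — the milder reading of an ambiguous
inclusion rule. Cell centres, not corners, carry the coordinates, and grid
origins snap to multiples of the cell size globally so surfaces built in
separate runs align cell-for-cell.

The grid cell size follows a travel-scale rule: the mean along-track
distance covered in 2 h, converted at 111.19 km/° (Earth radius 6371 km,
the single distance convention used throughout) and rounded *up* to the
next 0.05°. Fast wide-ranging flyers get coarse grids (~0.5°), penguins
fine ones (~0.05–0.1°).

## Track cleaning

Stages run in a fixed order — segment, speed-filter, resample, buffer —
because the order matters: resampling before filtering smears planted
outliers into their neighbours (a regression test documents this).

- **Segmentation.** "On land" is distance-to-colony ≤ `land_radius_km`
  (default 0.5 km) rather than a coastline polygon; a trip is a maximal
  run of at-sea fixes. Trips with no return to land (logger failure) are
  retained and flagged incomplete.
- **Speed filter.** Forward-pass remove-and-recheck anchored at the first
  fix, iterated to fixation: any fix implying a segment speed above
  135 km h⁻¹ (flying) or 10 km h⁻¹ (diving) from the previously retained
  fix is dropped. Idempotent at fixation.
- **Resampling.** Flying tracks are interpolated linearly in raw lon/lat at
  hourly intervals — below 60° latitude at hourly spacing the departure
  from the great circle is under 0.1 km for 30 km steps. Penguin tracks,
  whose GPS fixes are irregular because the receiver is underwater, use a
  continuous-time correlated random walk: an integrated Ornstein–Uhlenbeck
  velocity process per axis (`dv = −βv dt + σ dW`), an exact linear-Gaussian
  state space over irregular gaps. β and σ are estimated by maximising the
  Kalman innovation likelihood (Nelder–Mead over log-parameters from a
  coarse 3×3 grid start; observation SD fixed at 50 m); positions at the
  2-min grid come from an RTS smoother run over the union of observation
  and output times. For trips longer than 200 fixes the likelihood is
  evaluated on 200 evenly thinned fixes (the smoother always uses all) —
  the parameter estimate changes negligibly and the fit stays O(n).
  Non-convergence falls back to linear interpolation with a logged warning.
- **Colony buffer.** Fixes within 15 km (flying) or 2 km (diving) of the
  colony are removed to avoid commuting bias; individuals left with no
  fixes are excluded, mirroring birds that forage only at the colony.

## Behavioral classification

Flying birds: a four-component Gaussian mixture in standardised
(speed, |turning angle|) space — standardised because km/h and radians are
not commensurate — initialised at the four quadrant centres of the
per-variable medians and bound to quadrants after fitting by ordering the
component means (two lowest speed means = low-speed pair; turn mean splits
each pair). |turn| rather than signed turn makes the labelling mirror-
invariant. The low-speed/high-turn state ("actively sitting") is foraging.
Degenerate EM solutions are retried up to 5 times with seeded jitter, then
the classifier falls back to a median-threshold rule; fewer than 20 steps
also triggers the fallback. EM is pooled per species, not per individual,
for stability at small per-bird step counts.

Penguins: a step is foraging iff its speed is strictly below the species-
pooled mean speed. Pooling is at species level ("a species average"), and
the strict inequality means constant-speed data produce no foraging labels.

## Lipid normalization

Plasma lipids are 13C-depleted; C:N mass ratio > 3.5 flags lipid-rich
tissue. Per species, paired raw/delipidated aliquots give
Δδ13C = δ13C_del − δ13C and ΔC:N = C:N_del − C:N; OLS of Δδ13C on ΔC:N
yields slope m and intercept c (m is typically negative under this
orientation). Raw-only samples are corrected at
ΔC:N\* = mean(C:N_del) − C:N_raw — lipid-rich samples get negative ΔC:N\*,
hence a positive correction — via the **direct form**
δ13C_cor = δ13C + m·ΔC:N\* + c (default). Published formulations of this
normalization differ in algebra, so an **inverse form**
δ13C_cor = δ13C + (ΔC:N\* + c)/m is selectable by configuration; the two
genuinely disagree except at special m, and a test documents that. Models
are strictly per-species (no pooled fallback): normalizations developed for
one species or tissue do not transfer. δ15N is always taken from raw plasma
and never altered.

## Isoscape estimation

- **Correlations.** Pearson R with a two-sided t-test, plus the OLS line on
  the same pairs; predictors are mean foraging latitude and longitude for
  flying species and haversine distance to the colony/coast for penguins,
  whose latitudinal range (~0.5°) is too small for a latitude gradient.
- **Variograms.** Empirical semivariance in 12 equal-width lag bins up to
  2/3 of the maximum pairwise distance; spherical, exponential and Gaussian
  candidates fitted by least squares weighted by pair counts; lowest
  weighted SSE wins. Bounds follow automatic-fitting practice: the range
  cannot exceed twice the sampled lag span and sills are capped at a
  multiple of the data variance — unbounded fits on strongly trended data
  otherwise run away. Fewer than 3 non-empty bins falls back to a pure-
  nugget model (logged).
- **Kriging.** Ordinary kriging in isotropic geographic degrees (study
  extents are modest in longitude-compression terms; pre-projected
  coordinates can be supplied where that approximation bites). The nugget
  is treated as micro-scale variance, so the covariance at zero distance is
  the full sill and predictions honour the data exactly at sample points.
  Exact duplicate coordinates are averaged beforehand (singularity guard);
  a singular system gets one jittered retry, then a hard error. All
  prediction points share one LU factorisation. Predictions are clipped to
  the observed value range widened by three sill standard deviations —
  smooth (Gaussian) models otherwise overshoot far from data; the clip is
  the surface's stated sanity band, not a statistical correction.
- **Masks.** Convex hull of the mean foraging locations dilated by one cell
  (0.5° flying / 0.05° diving); collinear locations degrade to a buffered
  segment with a log note.
- **Differences.** Species surfaces subtract cell-for-cell on the
  intersection of their masks (alignment guaranteed by global grid
  snapping); disjoint masks are an error, mirroring species pairs whose
  ranges barely overlap.
- **Guild bootstrap.** Each of B replicates draws k individuals per species
  *without replacement* — the stated purpose is equalising per-species
  sample sizes, which subsampling does directly; with-replacement is
  available by flag. The variogram is refitted per replicate and each
  replicate is kriged on the fixed guild grid; the guild surface is the
  cell-wise mean. B = 1000 by default; the recovery tests use B = 200,
  k = 9 with 25 individuals per species, a size chosen so the full check
  runs in well under five minutes on one CPU.

## Fronts and zones

Fronts are marching-squares contours of the SSH field at 0.92 m
(sub-tropical), 0.03 m (sub-Antarctic) and −0.48 m (Antarctic polar); with
multiple disjoint contours the longest is kept (logged). Zones partition
the domain north-to-south (STZ/SAZ/PFZ/AZ) by comparing a point's latitude
with each front's latitude at that longitude; points exactly on a front go
to the zone north of it. "Within one degree along a front" is read as a
±1° latitude band following the front (not a great-circle corridor).
Front plasma values are back-calculated by evaluating the species latitude
regressions at the nominal front latitudes 51°S (polar) and 42°S
(sub-tropical); reported values are rounded half-away-from-zero to one
decimal, the convention that reproduces the published per-species table
from its printed coefficients. Two species' published front values do not
recompute from their printed (rounded) coefficients; they are documented
as such and excluded from exact-reproduction checks rather than guessed.
Cross-species aggregates are the arithmetic mean and n−1 SD of the
per-species values.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, with
conditions fixed once:

| parameter | flying | diving |
|---|---|---|
| fix interval | 1 h | 2 min |
| mean speed (transit) | 35 km h⁻¹ | 4 km h⁻¹ |
| speed SD | 10 | 1.5 |
| trip duration | 120 h | 48 h |
| heading-change SD (transit / forage) | 0.15 / 1.5 rad | 0.25 / 1.5 rad |
| forage speed factor | 0.25 | 0.25 |

Tracks are first-order correlated random walks on the sphere
(wrapped-normal heading increments, truncated-normal speeds) with a
two-state Markov chain (transit/forage) and a homing phase that returns the
bird to the colony within the trip budget; each individual gets a
persistent random initial heading so a colony's birds radiate over tens of
degrees. Baseline fields use the plasma-level combined gradients minus the
default trophic offsets: δ13C slope 0.21 ‰/°, intercept −12.25 ‰ (offset
1.0 ‰); δ15N slope 0.12 ‰/°, intercept 14.79 ‰ (offset 3.5 ‰ — both
offsets inside the canonical per-trophic-level ranges). Optional front
steps and exponential inshore enrichment can be added. Plasma values are
time-weighted field means over the within-window foraging fixes plus offset
plus Gaussian noise (SD 0.3 ‰ per isotope); the weighted location and
baseline value are stored as ground truth. Lipid contamination is the exact
inverse of the chosen correction form (default model m = −0.6, c = 0.1,
mean delipidated C:N 3.2), so contaminate→correct is the identity to
numerical precision. SSH fields are monotone-in-latitude PCHIP profiles
through the planted (front latitude, level) anchors.

**What passing tests do not show.** The generator has no ocean circulation,
advection, eddies, tides or dive behavior; its baseline is stationary in
time; its behavioral states are cleanly separated Gaussian clusters; its
plasma noise is i.i.d. Real data violate all of these, so recovery results
bound what the *pipeline* can do under its own assumptions, not what field
data will deliver.

## Known limitations and numerical notes

- Ordinary kriging shrinks toward the local replicate mean at the edges of
  the hull where few individuals reach; a whole-surface regression of the
  bootstrap guild surface on latitude is therefore mildly attenuated
  (~5–15% on the standard synthetic study), while the interior of the
  surface tracks the generating gradient closely.
- Kriging distance is isotropic in degrees; at 47°S a degree of longitude
  is ~68% of a degree of latitude, so ranges are effectively anisotropic in
  km. Documented approximation, acceptable at the study's extents.
- Antimeridian-spanning grids are rejected rather than handled.
- The speed-filter variant (forward pass, first fix anchored, iterate to
  fixation) is one of several in use; the choice is documented rather than
  inferred.
- EMbC here omits the published smoothing post-pass and uses |turn| with
  quadrant binding; on penguin-like data the four-state clustering is not
  expected to work well, which is why the speed rule exists.
- Reported roundings use decimal half-away-from-zero (after removing float
  fuzz at 1e-9) — banker's rounding would not reproduce the published
  tables.
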