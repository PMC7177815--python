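# Methods

This note documents the models, numerical choices, and limitations of
the package in one place. The README gives the one-screen summary; here
we record *why* things are the way they are.

## The discrimination problem

A depressed rice canopy is ambiguous: heavy-metal contamination,
pest/disease outbreaks, and nutrient deficits all reduce LAI. The
package separates them by three orthogonal observables, each computed
per pixel from two consecutive seasons of LAI series (20 samples at
5-day steps, DOY 160–255):

| observable | heavy metal | pest/disease | nutrition | healthy |
|---|---|---|---|---|
| stress level `S` (DTW to healthy reference) | high | moderate | high | ~0 |
| temporal stability `TS` (1 − normalized inter-annual DTW) | high | low | low | high |
| local Moran's I of `TS` | positive (clusters) | negative/0 (scattered) | mixed | positive |

Only heavy-metal pixels score high on all three, which is why the
composite index is their geometric mean: `SIST = (S·TS·I)^(1/3)`. The
cube-root form keeps the index in [0, 1] and makes a zero in any factor
veto the pixel.

## Radiation forcing

Daily sunshine hours `n` are converted to surface shortwave radiation
`Rs` (MJ m⁻² d⁻¹) through the standard astronomical chain:
Earth–Sun distance factor `Dr = 1 + 0.033·cos(0.0172·DOY)`, declination
`δ = 0.4209·sin(0.0172·DOY − 1.39)`, sunset hour angle
`ωs = arccos(−tanφ·tanδ)`, extraterrestrial radiation
`Ra = 37.6·Dr·(ωs·sinφ·sinδ + cosφ·cosδ·sinωs)`, day length
`N = (24/π)·ωs`, and the Angström–Prescott relation
`Rs = (a_s + b_s·n/N)·Ra` with `a_s = 0.18`, `b_s = 0.55` (temperate
defaults, overridable). Constants are used exactly as written above —
including the 0.4209 declination amplitude — rather than substituted
with other conventions, so results are reproducible against the same
formula set. The arccos argument is clamped to [−1, 1] so latitudes
beyond the polar circles degrade to 0/24-hour day lengths instead of
raising a domain error; the subtropical study setting (≈27.7° N) never
triggers the clamp.

## The reduced crop model

A full physiological crop simulator is out of scope; the package uses a
deliberately compact daily LAI model behind a pluggable interface:

    CVF_t   = rue · Rs_t · (1 − exp(−k_ext · LAI_t))      (gross assimilation)
    CVFf_t  = f · CVF_t                                    (stress coupling)
    LAI_t+1 = max(LAI_t + leaf_conversion · CVFf_t − sen_t · LAI_t, 0)

with `sen_t = senescence_rate` once cumulative thermal time above
`t_base` exceeds `tt_senescence`, else 0. The stress factor `f ∈ [0, 1]`
(1 = healthy, 0 = fully stressed) multiplies assimilation exactly as it
would in a full model, so substituting a richer simulator changes
nothing downstream.

Defaults are configuration, not science: `lai_init = 0.3`,
`rue = 0.55`, `k_ext = 0.6`, `leaf_conversion = 0.020`, `t_base = 8 °C`,
`tt_senescence = 900 °C·d`, `senescence_rate = 0.045 d⁻¹`. They were
tuned once so the unstressed curve under subtropical summer forcing
rises from 0.3, peaks near LAI 6.3 around DOY 205, and declines toward
harvest (peak 4.8 at DOY 210 under constant Rs = 15 MJ m⁻² d⁻¹), and
then frozen. The model is deterministic and pointwise monotone in `f`.

`f` is a single season-constant scalar per pixel when calibrated
(no time structure is identifiable from a handful of satellite
acquisitions); the simulator itself accepts per-day and per-pixel `f`
arrays, which the scene generator uses for windowed (abrupt) stress.

## Calibration

The cost is the mean squared difference between observed LAI (NDVI
mapped by `LAI = 0.361·exp(3.69·NDVI)`, a relation assumed constant
across the two years) and the simulated series, each observation
matched to the nearest simulated DOY within ±2 days (satellite
acquisition dates rarely coincide with the 5-day grid; a larger gap is
an error, not an extrapolation). MSE is kept as-is, not RMSE.

The optimizer is global-best PSO: 20 particles, 100 iterations,
inertia 0.72, cognitive = social = 1.49, hard bounds [0, 1], seeded.
For this 1-D problem PSO is verifiable against a dense grid search
(`grid_search_stress_factor`, batched so all 1001 candidates simulate
in one pass), and the tests hold it to that oracle. Non-convergence
returns the best-so-far with a flag rather than raising.

## DTW

Classic O(mn) dynamic programming with steps {(1,0),(1,1),(0,1)},
boundary (1,1)→(m,n), and a Sakoe–Chiba band `|j − (n/m)·i| ≤ r`
(1-based). Choices:

- **Local cost** `δ = |a_i − b_j|` by default (keeps distances in LAI
  units); squared difference available.
- **No path-length normalization** — downstream min–max normalization
  absorbs scale.
- **Band radius default r = 3 samples** (15 days): wide enough for
  realistic transplanting shifts, narrow enough to forbid pathological
  warps. A band that excludes every complete path is an error, never a
  silent fallback.
- Ties in backtracking prefer the diagonal, so identical series report
  the diagonal path.

The raster pipeline uses a batch variant vectorized over pixels
(~10⁴ 20×20 alignments per second per stage); tests pin it to the
scalar implementation, to exhaustive path enumeration at small sizes,
and to an independent memoized recursion at length 20.

## Stress surfaces

The healthy reference is one `f = 1` simulation per year (global per
scene, not per pixel). Normalization extrema are taken over the rice
pixels of the processed scene and recorded in the output manifest so
runs can be compared. Each year is normalized separately and then
averaged (normalization precedes the two-year mean); the alternative
order is a one-line change and the extrema needed for it are recorded.
Degenerate ranges (all values equal) map stress to 0 — no evidence of
*differential* stress — and temporal stability to 1 — maximal
stability; both conservative.

## Local Moran's I

The Anselin local form `I_i = (x_i − x̄)/m2 · Σ_j w_ij (x_j − x̄)` with
`x̄` and `m2 = Σ(x_k − x̄)²/n` over all rice pixels (denominator `n`,
matching the population-variance form of the global statistic), queen
3×3 neighborhoods restricted to rice pixels, truncated at scene edges
(no synthetic neighbors). Row-standardized weights are the default so
edge and interior pixels are comparable; with them, the mean of the
local values equals the global Moran's I on fully-defined grids, which
the tests check to 1e−9. The intended input is the temporal-stability surface (`TD` works too
but inverts the cluster semantics — the statistic itself is agnostic
to which raster it receives). Significance testing is deliberately absent: the index uses
the normalized magnitude, not a hypothesis test. One geometric fact
worth recording: on an exact checkerboard the queen-neighborhood
deviations cancel and local I is exactly 0, not negative — dispersion
tests need stripes or spikes.

Cluster labels follow the usual quadrant rule (positive I splits into
high-high/low-low by the sign of `x_i − x̄`; negative I into
high-low/low-high); high-high `TS` clusters with high stress are the
heavy-metal signature, low-low `TS` clusters the healthy one.

## Composite index and summaries

`SIST = (S_norm · TS · I_norm)^(1/3)`, nodata wherever any component is
nodata (isolated rice pixels therefore have no SIST). The zonal
summary's exceedance threshold (default 0.5) is reporting
configuration with no empirical basis. The Pearson-correlation utility
validates against severity references; on real deployments that would
be soil Cd concentrations, in this package it is exercised against the
synthetic generator's latent contamination level.

## Land-cover post-processing

Rice objects smaller than 4 pixels under 4-connectivity are removed and
filled with the mode of the non-target classes in the object's
8-neighborhood; ties and fully-enclosed objects fall back to the class
of the nearest non-target pixel (Euclidean). The rule is deterministic,
local, and idempotent. Accuracy statistics are always derived from the
confusion-matrix cells; the bundled example matrix ships as counts only
and every statistic is recomputed from them.

## The synthetic scene generator

The generator defines the study conditions; its defaults are not tuning
knobs. On a 100×100 grid with 90 % rice cover: three rectangular
heavy-metal blocks (10–16 % of the short grid side each) with per-pixel
latent level ~ U(0.3, 0.8) and `f = 1 − 0.6·level` in both years; two
nutrition zones with severity ~ U(0.2, 0.6) redrawn independently each
year through the same effect coefficient (`f = 1 − 0.6·severity`), so
the two chronic stressors are comparable within a season and differ
only in inter-annual stability — the distinction the method actually
claims to detect; 2 % of healthy pixels get abrupt stress (`f = 0.4`
inside DOY 190–210 of the first year only); the second year's phenology
is shifted one 5-day step; additive Gaussian observation noise
(sd 0.15 LAI) is floored at 0. Weather is a smooth seasonal cycle with
daily noise, year-dependent but seeded.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: cloud gaps and irregular
acquisition dates, NDVI→LAI model error, mixed pixels at field
boundaries, co-occurring stressors on one pixel, spatially correlated
noise, and real contamination gradients. The end-to-end numbers
(AUC ≈ 0.99, r ≈ 0.8 between SIST and latent contamination) are
synthetic-truth separation properties, not field-validation results.

## Problem sizes and determinism

Default analyses run on 100×100 scenes (≈9 000 rice pixels), which the
batched DTW completes in about a second; the unit suite uses 6×6 to
40×40 grids. Every stochastic component (scene layout, severities,
noise, PSO) draws from one seed through `numpy.random.SeedSequence`
spawning, so identical configurations are bit-reproducible and the
acceptance script is a pure function of its `--seed`.

## Known limitations

- Two years of data cannot separate heavy-metal stress from any other
  stressor that happens to repeat identically in both years; longer
  records would sharpen `TS`.
- A pixel under both heavy-metal and abrupt stress is not classifiable
  by this construction (the abrupt signal destroys `TS`).
- Min–max normalization ties all surfaces to the processed scene's
  extrema: a scene with no healthy pixels, or a single extreme outlier,
  shifts every normalized value. Extrema are exported precisely so such
  runs can be diagnosed.
- The reduced crop model has no water/nutrient balance and one free
  parameter; it is adequate for shape-level stress coupling, not for
  yield prediction.
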