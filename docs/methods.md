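# Methods

## The estimation problem

Daily ground-level PM2.5 at a location s and day t is modelled as the sum of
a fire-smoke component and a background from all other sources,
`PM(s,t) = PM_F(s,t) + PM_B(s,t)`. Monitors observe only the total; a
chemical transport model (CTM) run twice — with and without fire emissions —
observes the split, but with substantial bias. The pipeline fuses the two:
cell-days are partitioned into a *smoke-impacted* region (inside a
satellite-analyst smoke polygon, or CTM smoke ratio strictly above 0.03) and
a *no-smoke* region, and two random-forest regressors are trained
independently on observed totals — one per region. In the no-smoke region
smoke is assumed negligible, so the observed total identifies the
background; that forest then predicts background *inside* the smoke region,
and the smoke component is the clipped difference of the two forests'
predictions. Negative differences are clipped to zero: the additive
decomposition makes a negative fire contribution physically meaningless, and
the difference of two independently trained regressors would otherwise go
slightly negative wherever smoke is near zero.

Assumptions worth stating explicitly:

- the no-smoke labelling is trusted: observed totals there are treated as
  pure background. Mislabelled smoke (omitted plumes, ratio below threshold)
  biases the background model upward and the smoke estimate downward;
- both forests share the pool of additional predictors Z (gap-filled AOD,
  meteorology, cloud fraction, population, climate-region indicators); the
  plume descriptors (duration, density) enter only the smoke model;
- no time indicator is used, so the model transports information across the
  whole record rather than interpolating within years.

## Partition threshold

The smoke ratio is `max(full − nofire, 0) / full`, defined as 0 when the CTM
total is at or below 0.1 µg/m³ (a floor that avoids unstable ratios near
zero; the subtraction is clipped because the no-fire run exceeding the full
run is a numerical artefact, not a sink). The operating threshold 0.03 can
be re-derived with `scan_threshold_balance`, which counts the two models'
training rows over a 0.01–0.10 grid and scores each threshold by
min/max row count ("most balanced" is not otherwise formalized; min/max is
isolated in one function so another criterion is a one-line change). All
comparisons at thresholds are strict (`>`), and attainment uses `≥` the
standard; boundary tests pin these conventions.

## Low-cost sensor calibration

Hourly records pass QC as daily values when at least 16 of 24 hours are
valid, the two optical channels' daily means differ by at most 30% of their
mean (computed on daily means; an hourly variant would reject more days —
the choice is documented, not resolved), and daily PM2.5 ≤ 1000 µg/m³,
temperature within [−20, 140] °F, humidity within [0, 100]%.

Calibration regresses reference PM2.5 on (low-cost PM2.5, RH, temperature)
by geographically weighted regression with a Gaussian kernel
`exp(−d²/2b²)`. Anchors are the matched low-cost sites (pairs within 5 km of
a reference monitor, inclusive); the bandwidth b is selected per region from
{5, 10, 20, 40, 80} km by leave-one-site-out CV RMSE; singular local designs
widen their kernel geometrically and log it. The domain splits into four
quadrant regions. Within 20 km of an internal boundary, predictions from the
adjacent regions are blended with a weight that ramps linearly from 0 at the
buffer edge to 0.5 on the boundary — on the seam itself this is exactly the
plain mean of the two regional fits, and unlike an abrupt half-half mean it
keeps the adjusted surface continuous everywhere. Calibrated low-cost values
are clipped at 0, and only those strictly above the 12 µg/m³ annual standard
join the training data (reference records always do); values exactly at the
threshold are excluded.

## SMOTE for high concentrations

Observed totals strictly above 35 µg/m³ and at or below 100 get one
synthetic copy; strictly above 100 get two. A synthetic row is a uniform
convex combination (λ ~ U[0,1]) of the seed row and one of its k = 5 nearest
neighbours, applied to features and target jointly, so targets never leave
the seed-neighbour interval. Neighbours are found in standardized feature
space by default; a geographic mode (x, y distance) is provided because
"nearest" in this setting could equally mean nearest grid cells — the intent
is ambiguous and both are implemented rather than guessed. Synthetic rows
are flagged and excluded from every evaluation metric, and SMOTE runs inside
each CV fold's training split only.

## Forests and evaluation

Both regressors are random forests with 200 trees, √p features per split
and a minimum leaf of 3 (all via `ModelConfig`). Skill on worlds of the
default size is flat beyond a couple of hundred trees, so 200 is the default
rather than a larger forest. R² is the squared Pearson correlation of
observed and predicted (the convention in this literature); 1 − SSE/SST is
reported alongside since the two diverge under bias. Cross-validation is
20-fold; *overall* randomizes rows, *spatial* assigns whole cells to folds,
*temporal* whole days (random days by default; contiguous blocks via a
switch, since blocked temporal folds are the stricter test of seasonal
transport). Aggregation averages observed and predicted within cell-month
and cell-year (synthetic calendar: 30-day months, 360-day years) and
recomputes metrics; with unbiased daily errors this can only help, which the
aggregation property test asserts.

## The synthetic world

The generator emulates the statistical structure of the real inputs at desk
scale; defaults define the package's standard study conditions: 64 × 64 km
at 1 km, 120 days, 60 reference monitors, 150 low-cost monitors, 6 smoke
events, CTM at 8 km (an order-of-magnitude resolution gap in place of the
full 1 km : 12 km ratio, which a 64 km domain cannot support meaningfully).

- **Background**: lognormal spatially correlated field (correlation length
  ~6 cells) around 8 µg/m³, urban bump at the population peak, AR(1) day
  factor and smooth space-time noise; strictly positive by construction.
- **Smoke**: Gaussian puffs (amplitude 40–160 µg/m³ decaying over 2–5 days,
  σ 3–7 km growing ~0.3–1 km/day) whose centers advect with the domain-mean
  daily wind. Puff trajectories are stored, so tests re-evaluate the field
  from first principles.
- **CTM pair**: truth block-averaged to the coarse grid, multiplied by a
  smooth lognormal bias (sd 0.25) shared between runs — both runs share
  model physics — with an extra lognormal bias (sd 0.3) on the smoke term
  (fire emissions are the less constrained input), plus shared additive
  noise, clipped at 0. Sharing bias and noise makes the run difference a
  non-negative but distorted smoke proxy, and makes the two runs identical
  when no fires burn.
- **AOD**: affine in total PM2.5 with *day-varying* slope (lognormal sd 0.3)
  and intercept, an extra day-varying lofting factor (lognormal sd 0.8) on
  the smoke term — elevated plumes inflate column AOD without matching
  surface PM — plus noise; missing under a smooth cloud field thresholded at
  the 40% quantile. These choices reflect why column AOD is a weaker surface
  predictor than a CTM: within a day it ranks cells well, across days the
  relation drifts.
- **Plume polygons**: contours of the true smoke field above 2 µg/m³,
  randomly dilated/eroded (sd 1 km), omitted at rate 0.1, plus ~0.5 spurious
  small polygons per day; duration uniform over the day, density class 1/2/3
  by enclosed mean smoke (≤5 / ≤20 / >20 µg/m³), duration-weighted when
  polygons overlap.
- **Monitors**: placement probability ∝ population^α (α = 1 for reference —
  regulatory networks are urban-biased — and 0.3 for low-cost). Reference
  stations report 24 hourly values of truth plus unbiased noise; low-cost
  stations report two channels inflated by `1 + 0.004·RH` plus noise, with
  2% of station-days corrupted (channel disagreement, spikes, hour dropout)
  to exercise QC. Hourly noise is i.i.d. around the daily truth.

What the generator does *not* emulate: satellite orbital geometry and
retrieval physics, emission inventories, real projections or geodesy,
sensor drift, diurnal chemistry. Passing recovery tests therefore shows the
pipeline's logic is sound and beats its CTM input under plausible error
structure — not that the real-data error statistics are reproduced.

## Numerical and degenerate-input choices

IDW uses the k = 4 nearest coarse centers with power 2 and snaps exactly
onto coincident centers. Gap-filling never alters observed cells; a day with
no observed AOD falls back to a model pooled over all days. Ratio floors,
kernel widening, empty-region errors (hard, named), empty CV folds (merged,
logged) and zero-denominator guards are described at their definitions.
Serialization uses `%.17g` CSV floats and round-trip parsing so a reloaded
world reproduces the pipeline bit for bit. All randomness flows through
per-stage `numpy` SeedSequence streams; identical configs give identical
worlds, byte-for-byte on disk. World directories store each field as one
multi-day `.npy` raster next to `grid.json` rather than one file per day.

## Known limitations

Plume polygon durations are random rather than tied to event age; climate
regions are a Voronoi stand-in; population is year-static (a per-year
multiplier emulates growth in multi-year exposure tables); the quadrant
regionalization is fixed rather than data-driven. The attainment design
value uses a shortened window in the first two years, where a regulatory
calculation would report no value at all.
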