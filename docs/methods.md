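# Methods

## Scope and data model

The package analyses duty-cycled biologger data from soaring migrants: 1 Hz
GPS bursts (default 300 s) with tri-axial accelerometer (milli-g) and
magnetometer (milliGauss) channels, separated by 10–15 min pauses.  The
canonical in-memory track is a pandas DataFrame (`bird_id, timestamp, lon,
lat, altitude_msl, ground_speed[, acc_z, mag_x]`), WGS84 degrees, metres
above sea level, km/h.  Timestamps are treated as UTC; windows defined in
local time (the 06:00–13:00 departure-decision window) apply a configurable
UTC offset, default +2 h (Central European Summer Time), because logger
time bases vary between deployments.

## Behavior sorting

Classification is per burst, mirroring the standard accelerometer/
magnetometer workflow for soaring raptors:

* **Roost filter** — fixes with ground speed below 1 km/h are dropped; the
  boundary value is kept (the rule excludes speeds *lower than* 1 km/h).
* **Burst segmentation** — maximal runs of consecutive 1 s-spaced fixes;
  runs of 10 or fewer points are discarded.
* **Active vs passive** — passive (soaring/gliding) flight requires ≥ 90%
  of acc_z samples inside the 800–1400 mG band *and* a median 10 s windowed
  peak-to-peak below 300 mG.  "Strong oscillation" is not quantified in the
  source workflow; the windowed peak-to-peak with a 300 mG default is this
  package's operationalization, applied to raw 1 Hz samples (not an
  envelope), and both knobs are exposed.  The median (rather than maximum)
  window statistic makes a single spike non-fatal.
* **Soaring vs gliding** — circling rotates the body, so mag_x oscillates
  once per turn; gliding mag_x is smooth.  The oscillation test high-passes
  mag_x by subtracting a centred 31 s moving average (removing slow heading
  wander that survives linear detrending) and scores the maximum normalized
  autocorrelation over lags 2–40 s, the plausible range of circling
  periods.  Soaring requires a score ≥ 0.3 plus ≥ 2 zero crossings per
  minute.  An autocorrelation score was chosen over a single-bin spectral
  peak fraction because circle-and-run (staircase) soaring produces an
  *intermittent* tone whose power spreads across sidebands: on synthetic
  staircase bursts the spectral-peak rule stalled near 50% recall while the
  autocorrelation rule recovers > 99%, and white-noise mag channels stay
  far below the 0.3 threshold (max ACF ≈ 0.2 at n = 300).
* **Climb rate** — (max − min altitude) / elapsed seconds between the two
  extremes, signed positive when the maximum occurs later.  The source
  definition names only the height difference but reports m s⁻¹; dividing
  by the extremum separation (not burst length) is this package's choice.

## Pattern geometry

Headings come from consecutive-fix azimuths; a full turn is emitted each
time the cumulative signed heading change crosses 360°, with the residual
carried into the next turn.  Turn diameter is twice the radius of an
algebraic circle fit in the local tangent plane (equirectangular about the
turn centroid; bursts span ≤ a few km, so distortion is far below GPS
noise).  The fit is the "Hyper" variant of the algebraic circle fit, whose
leading-order noise bias vanishes, followed by a radial-residual-variance
shrinkage `r ← sqrt(r² − s²)`: GPS noise pushes points outward and inflates
the apparent radius by ~σ²/r, which matters exactly in the spiral regime
(radius a few metres, σ ≈ 1 m).  Monte-Carlo checks in the test suite hold
the estimator within 5% for radii 2–50 m at σ = 1 m.  A circle's "diameter"
could equally have been defined as a maximum chord; the circle fit is this
package's documented choice.

Pattern call per soaring segment: no full turns → *s-shape*; otherwise each
turn is classed by its fitted diameter (< 10 m spiral, ≥ 10 m staircase —
the boundary value 10 m goes to staircase since the defining inequalities
leave it open) and the segment takes the more frequent turn class,
staircase on a tie.

## Weather annotation

Winds follow the reanalysis convention: u, v are the eastward/northward
components of the vector the air moves *toward*, so the compass azimuth of
the flow is `atan2(u, v)`.  Wind support is `|w|·cos α` with α the angle
between flow azimuth and travel azimuth (negative = headwind); side wind is
reported as the magnitude `|w|·|sin α|`, and the two satisfy
tailwind² + sidewind² = |w|² identically.  ΔT = T_surface − T_air at flight
level; positive values proxy thermal uplift.  Travel azimuth defaults to
the route-level bearing (first to last fix per bird), matching the
crossing-leg definition; a per-fix override is accepted.

Interpolation: wind bilinear in lon/lat and linear between the bracketing
hours; temperature, cloud and precipitation nearest-neighbour in space and
time (temporal linearity for wind is this package's choice; the source
workflow specifies only the spatial methods).  Pressure level per fix:
925 hPa over land or when the bird's mean altitude exceeds 400 m, 1000 hPa
otherwise, with a per-bird override for individuals flying anomalously
high.  `isa_altitude_m` gives the International Standard Atmosphere height
of a level (925 hPa → ≈ 760 m).  ISA places 1000 hPa near 110 m rather
than the ~150 m sometimes quoted from reanalysis geopotential; the package
does not attempt to reproduce geopotential heights.

## Crossings and the departure dataset

A crossing is the maximal run of consecutive over-water fixes, kept when
its summed great-circle length exceeds 20 km (coastal loops are an order of
magnitude shorter than real ~190 km transits; the threshold is
configurable).  Route length is the sum of the over-water legs; mean speed
is route length over duration, an identity preserved by construction.
Distance to shore is the great-circle distance to the nearest point of the
land-polygon boundary (any shore, not specifically the departure coast),
evaluated against a boundary densified to ~0.002° so the error is well
under the 10 km threshold it serves.

Departure records: for each crossing preceded by at least 2 days of coastal
staging (configurable), hourly-averaged records in the 06:00–13:00 local
window — resting days flagged 0, the crossing day flagged 1 from 06:00
until the first fix beyond 10 km offshore.  Birds that poke a few km out
to sea and return on a resting morning therefore stay labeled 0.

## The mixed-model workflow

Predictors are standardized (mean 0, SD 1, n−1 denominator) so
coefficients are comparable; pairs with |Pearson r| ≥ 0.6 are screened,
dropping the lower-priority member (default priority: wind support, ΔT,
side wind, precipitation, cloud — so e.g. a cloud ~ ΔT correlation of 0.83
removes cloud).  1 Hz behavioural series are thinned to one record per
non-overlapping 30 s block (response at the block's first fix, covariates
block-averaged, incomplete blocks dropped) to tame residual
autocorrelation; a test verifies the lag-1 Pearson-residual autocorrelation
actually drops.

The binomial logit GLMM with a per-individual random intercept is fitted by
maximizing the exact marginal likelihood, integrating the intercept with
25-point Gauss–Hermite quadrature (a random-intercept-only model has one
1-D integral per individual, so quadrature is fast and strictly more
accurate than a Laplace approximation; the fit matches `lme4::glmer` at
nAGQ = 25 on shared data, which the test suite checks through Rscript).
Standard errors come from the numerically differentiated observed
information; without a grouping factor the model reduces to ordinary
logistic regression (statsmodels GLM).  Quadratic wind-support terms use
the R `poly()` convention (orthonormal, intercept-orthogonal, positive
linear leading sign), with a raw-polynomial option.

All fixed-term subsets respecting marginality are fitted (interactions only
with both mains present; polynomial pairs as a unit — whether the original
workflow kept them together is unstated, and keeping them together is the
conservative reading); models within 2 criterion units of the best are
averaged with Akaike weights.  AICc is intended for the small-n departure
family, AIC for the high-frequency soaring families; pattern models can be
fitted without the random intercept.  Averaging is *full* (a term absent
from a model contributes zero), because the reference workflow reports a
z and p for every term; conditional averaging is available as an option.
Unconditional SEs follow `Σ w_m sqrt(se_m² + (b_m − b̄)²)`.

Predictive accuracy is 10-fold cross-validated proportion-correct at a 0.5
probability cutoff with response-stratified row folds and fold assignment
seeded; held-out rows are predicted at random effect 0 (new-individual
prediction).  The upstream "performance accuracy" measure is not precisely
defined for binomial mixed models, so the 0.5-cutoff proportion-correct is
this package's stated operationalization.  R²m / R²c are the
variance-partition (latent-scale) quantities for logit models:
`R²m = σ²_fixed / (σ²_fixed + σ²_RE + π²/3)`, with σ²_RE joining the
numerator for R²c.  Group-metric comparisons use Shapiro–Wilk,
two-sided Mann–Whitney U, and the classic (uncorrected) chi-square.

## The synthetic generator

The generator defines the study conditions: 4 sensor birds, 300 s bursts,
10–15 min gaps, per-burst winds, GPS σ = 1 m, altimeter σ = 1 m, passive
acc_z ~ N(1100, 30) mG, flapping acc_z ~ N(1100, 300) mG (wingbeats are
3–6 Hz, far above the 1 Hz sampling, so they alias into high-variance
noise rather than resolved cycles), mag_x = 400·cos(heading + phase) +
N(0, 20) mGauss driven by the *true* kinematic heading (the sensor reads
body orientation, not the GPS-noise-corrupted ground track).  Mode
kinematics in a local tangent plane, back-projected per burst:

* flapping — near-straight, level, airspeed 10–14 m/s;
* gliding — straight descent at 0.8–1.3 m/s sink, 12–18 m/s;
* spiral — ground-track circles of radius 2.5–4 m, period 5–8 s, climbing
  0.3–1.5 m/s, centre drifting with the wind but capped at 20% of the
  circling speed so the loops stay closed in the ground frame (a circle
  diameter below 10 m is only a meaningful ground-track statement while
  loops exist).  The period keeps the per-second chord near 3 m — resolvable
  against metre-level GPS noise yet under the 180°/s aliasing limit;
* staircase — circles of radius 8–18 m lasting 2–3 turns at soaring
  airspeed (8–12 m/s), alternating with 8–15 s straight runs on the
  migration heading; climb while circling, slight sink on runs;
* s-shape — heading oscillation of amplitude 50–80° (always < 180°, so no
  full turn can accumulate), period 15–25 s, with net climb.

Airspeeds are free parameters plausible for a ~950 g kite; no aerodynamic
force model or thermal field is simulated — thermals enter only through ΔT
covariates and prescribed climb rates.  Decision datasets draw standardized
covariates directly (standard normal), with default soaring-logit slopes
(1.51, 1.65, 1.97, 1.65) for wind support, |side wind|, ΔT and the
wind-support × ΔT interaction, a per-bird random intercept of SD 0.5, and a
departure rule logistic in wind support (slope 0.99).  Identical seeds give
bit-identical output.

What passing on these data does *not* show: real magnetometer calibration
drift, GPS multipath, mixed-behavior bursts, spatially structured weather,
or route choice are not emulated, so recovery rates here are upper bounds
on field performance; the generator's labels are by construction cleanly
separated in sensor space.

## Numerical choices and problem sizes

Circle fits reject < 3 or collinear points; degenerate turns are skipped
when computing a segment's median diameter.  GLMM optimization is BFGS on
(β, log σ) from a GLM start; a non-invertible observed information flags
the fit non-convergent and excludes it from ranking and averaging.  The
acceptance study uses 600 bursts for classifier recovery, 150 segments per
noise level for pattern recovery, 10⁵ draws for the wind identity, and
100 replicates × 2000 points × 10 birds for GLMM recovery and null
calibration — sizes chosen so the whole recomputation completes in about a
minute on one CPU while keeping Monte-Carlo error near one percentage
point.  With 10 groups the *intercept's* 2-SE coverage sits below nominal
(the realized mean of 10 random intercepts is not absorbed by the fixed-
effect SE); slope coverage is nominal, and the recovery criteria concern
the slopes.

## Known limitations

* Tight spirals (diameter < 10 m) at realistic soaring airspeeds imply
  sub-2 s turn periods that alias at 1 Hz; the generator instead uses slow
  ground-frame circling, which reproduces the *geometry* the classifier
  sees but not the aerodynamics behind it.
* The land/sea mask distance is vertex-sampled (error bounded by the
  densification spacing, ~100 m), adequate for 10–20 km thresholds, not
  for fine coastal work.
* Only a single random intercept is supported — no crossed or nested
  random effects, no spatial autocorrelation structure beyond thinning.
* Weather grids must be rectilinear in lon/lat/time; no support for
  reduced Gaussian grids or model-level data.
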