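# Methods

This note documents the models implemented in vegdyn, the conventions and
numerical choices behind them, what the synthetic scenes do and do not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Raster model and geometry

A `Grid` is a 2-D array with row 0 at the northern edge, an affine transform
with pixel-center registration, and a boolean nodata mask. All layers of an
analysis are expected on one master geometry (the reference workflow is
250 m cells); `align_resample` brings foreign layers onto it with nearest
neighbour (mandatory for categorical layers — it can never invent labels)
or bilinear interpolation (a convex combination of the four surrounding
cell centers, refused for categorical layers). Point climate records are
gridded with inverse-distance weighting (default power 2, 12 neighbours —
common GIS defaults, both exposed); a cell coincident with a sample returns
the sample value exactly.

Nodata propagates: any derived cell that touches a masked input cell is
masked. Cell area is nominal (`dx × dy`); no geodesic or projection-aware
area correction is applied, so area tables inherit whatever distortion the
input projection carries.

GeoTIFF I/O is implemented over `tifffile` with the ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags; a plain-text CSV grid dialect (header
lines carrying shape/transform/nodata, then rows north→south) exists so
test fixtures stay diffable. Floats are stored at float64, so round-trips
are exact to well below 1e-6.

Slope and aspect come from the Horn 3×3 finite-difference operator with
edge replication. Aspect is reported as the compass direction the surface
faces (degrees clockwise from north, i.e. the downslope azimuth); cells
with slope below 0.5° are coded −1 ("flat"), matching the flat class of
the aspect stratification scheme.

## FVC estimation

The dimidiate pixel model treats each pixel's EVI as a linear mixture of a
pure-soil and a pure-vegetation endmember. Endmembers are the 0.5 % and
99.5 % linear-interpolated empirical quantiles of the unmasked EVI values
(percentiles configurable); estimation warns below 200 unmasked cells and
refuses degenerate (constant) distributions. FVC is clipped to [0, 1]
because pixels beyond the percentile endmembers would otherwise leave the
unit interval.

Two aggregation conventions exist in practice for "annual EVI": the mean of
monthly maximum-value composites, and the annual maximum. The package
defaults to the monthly-MVC-mean (`annual_mean_evi`) and also provides
`annual_max_evi`; the choice is a config switch, not a hidden assumption.
Similarly, endmembers are estimated per-year from that year's annual grid
by default; pooling across the record is a one-line change (pass a pooled
grid), since which scope a given published workflow used is often
unstated.

Grading uses lower-edge-inclusive bins at 0.2/0.4/0.6/0.8 with 1.0 assigned
to the top class — interval labels like "0.00–0.20 / 0.20–0.40" are
otherwise ambiguous at the shared edge.

## Trend and stability

The Theil–Sen estimator is the median of all n(n−1)/2 pairwise slopes
(even counts average the two central order statistics); pixels with fewer
than 3 unmasked years are masked. Mann–Kendall uses the printed-form
variance n(n−1)(2n+5)/18 by default; a tie-corrected mode subtracting
Σt(t−1)(2t+5)/18 over tie groups is provided because FVC rasters can carry
ties. Z applies the ±1 continuity correction, which maps |S| ≤ 1 to Z = 0.

The five-class typology uses ρ thresholds ±0.0005/a and |Z| = 1.96. The
rule table leaves one cell undefined (|ρ| < 0.0005 with |Z| ≥ 1.96, e.g. a
tiny but extremely regular drift); it is assigned to stabilization, since
the magnitude threshold is the ecologically meaningful one.

CV is the sample standard deviation (ddof = 1) over the mean, masked where
the mean is ≤ 1e-12; fluctuation classes are lower-edge-inclusive above
0.07. Lagged correlation maps use per-pixel Pearson r between FVC(year)
and driver(year − lag) with two-sided t p-values (n − 2 df) and require at
least 5 overlapping pairs. No multiple-testing correction is applied
across pixels, matching standard practice in this literature.

## Transition accounting

`s_ij` is the area (pixel count × nominal cell area) moving from class i to
class j; pixels masked in either epoch are excluded, so successive-epoch
grand totals agree on a fixed mask. Net change is column total minus row
total; outflow/inflow shares exclude the diagonal and sum to 100 %;
changed area is the off-diagonal sum. Matrices can be built directly from
printed tables (`TransitionMatrix.from_table`, and
`vegdyn.datasets.load_transition` for the shipped worked-example tables),
so published accounting can be re-derived without rasters. Because
published cells are printed to 2 decimals, margins recomputed from cells
can differ from printed margins by ~0.01 km²; the package always reports
recomputed values. For the shipped 2001→2022 matrix the off-diagonal sum
is 10 850.91 km², which is what the package reports as changed area for
that table.

## Terrain dominance

Fixed schemes: elevation belts <3500 / 3500–3800 / 3800–4200 / >4200 m;
slope classes 0–3 / 3–7 / 7–12 / 12–18 / >18°; aspect sectors shaded
[0,67.5)∪[337.5,360), semishaded [67.5,112.5)∪[292.5,337.5), semipositive
[112.5,157.5)∪[247.5,292.5), sunny [157.5,247.5), plus flat (−1). All
interval bins are lower-edge inclusive; the aspect sectors are symmetric
45°/90° windows so they exactly tile the circle.

K = (S_ie/S_e)/(S_i/S). All four areas are computed on the joint unmasked
support, which makes the S_e/S-weighted mean of K over strata exactly 1
for every change type — an identity the tests assert. Strata or change
types with zero area yield NaN rather than a fabricated K.

`jenks_breaks` is the exact Fisher–Jenks dynamic program (O(k n²))
minimising within-class sum of squared deviations; interior breaks are
reported as the smallest member of each upper class so that
lower-edge-inclusive classification reproduces the optimal partition.
`discretize` runs Jenks on an evenly spaced order-statistic subsample
above 2000 values (deterministic; quantile/equal-interval methods are
exact at any size).

## Geodetector

q = 1 − SSW/SST computed via sums of squared deviations (the N's of the
variance form cancel). Singleton strata contribute zero to SSW and are
flagged. Refining a stratification can never decrease q, which is why the
product overlay of the interaction detector satisfies
q_nm ≥ max(q_n, q_m); the full five-type table (nonlinear/uni-variable
weaken, bivariable/nonlinear enhanced, independent) is nevertheless
implemented, with a 1e-9 relative tie tolerance and exact equality to
q_n + q_m mapping to "independent".

Significance: the q statistic is a monotone transform of the one-way ANOVA
F statistic (F = [(N−L)/(L−1)]·q/(1−q)), so the default `p_value` is the
central-F ANOVA p, which is exactly calibrated under a normal null — the
acceptance suite measures its empirical type-I error at the 5 % level.
The geodetector-software convention of referencing the same F to a
noncentral F with a plug-in noncentrality is also computed and reported as
`p_value_ncf`; because the plug-in noncentrality is estimated from the
observed stratum means it is strictly positive even under the null, which
makes that reference extremely conservative (its null rejection rate is
near zero). A seeded permutation test (`permutation_p`) is available for
tiny strata. The number of strata for continuous drivers defaults to 5
with Jenks breaks, both exposed in config.

## PLS path modeling

All blocks are reflective (mode A); indicators are z-standardized
(ddof = 1) after listwise deletion of incomplete rows (count recorded).
Outer weights start at 1, are updated as covariances between indicators
and the standardized inner estimate, and are renormalised so each
composite has unit variance; iteration stops when the largest absolute
weight change falls below 1e-6 (max 300 iterations; non-convergence
returns a flagged fit). The inner estimate uses the centroid scheme by
default (sign of score correlations over adjacent latents), with factor
and path schemes switchable; an isolated block uses its own score, making
the iteration a power method onto its first principal direction. Sign
indeterminacy is fixed per block by making the dominant loading positive;
during iteration the update is additionally orientation-aligned to the
previous weights to prevent sign flapping.

Path coefficients are OLS of each endogenous latent's scores on its
parents' scores (standardized coefficients, solved from the score
correlation matrix). Loadings are indicator–score correlations;
communality = loading², AVE = block-mean communality,
GOF = √(mean communality over all indicators × mean R² over endogenous
latents). Effects accumulate powers of the coefficient matrix (exact on a
DAG): direct = edge coefficient, total = sum over all directed paths of
coefficient products, indirect = total − direct.

The bootstrap resamples observations with replacement, refits, aligns each
block's sign to the full-sample fit via the outer-weight inner product,
and reports the resample sd as the standard error, a normal-reference
p-value on the t-ratio, the percentile p, and the 2.5/97.5 percentile CI.
More than 10 % failed resamples aborts with diagnostics. VIF screening
regresses each standardized variable on its peers (VIF = 1/(1 − R²);
perfect collinearity reported as ∞ with a warning).

The shipped default structural model for basin applications (Top→Climate,
Top→Human, Climate→Soil, and Top/Climate/Soil/Human→FVC, with FVC a
single-indicator latent) is an interpretation of the common "climate
dominance, topography regulation" causal narrative, supplied via config
and easily replaced; it is not claimed as ground truth.

## Synthetic scenes

`generate_scene` emulates a closed mountain basin: a DEM that is a smoothed
Gaussian field over a northwest-high ramp clipped to 3173–5279 m;
temperature T₀ − lapse·elevation (+ shared year effects + pixel noise;
defaults 23.5 °C sea-level intercept and 0.006 °C/m so basin means sit
near 0–1 °C); precipitation linear (optionally quadratic) in elevation,
floored at 0 (defaults give ~350–500 mm across the relief); spatially
autocorrelated land-use and soil label fields (smoothed noise cut at
quantiles, so class shares are near-equal); and continuous pressure layers
(SOC declining with elevation, grazing, population density). Monthly EVI is
baseline (land-use class offsets) + seasonal harmonic (peak July) +
planted per-pixel linear trend (improving west strip at +0.002/a,
degrading southeast block at −0.002/a) + coefficients times standardized
climate anomalies + white noise (sd 0.02), clipped to [0, 1]. A
16-day mode duplicates each month into two periods with independent noise
so MVC compositing is exercised. All randomness derives from
`(seed, stream)` pairs, so a fixed config reproduces every layer exactly.

Default amplitudes (seasonal 0.2, class-offset sd 0.05, baseline 0.45) are
chosen so the noiseless signal stays strictly inside [0, 1]: the
generator's contract that a planted τ appears as an exact linear trend in
annual means holds only while nothing saturates at the index bounds.

Two deliberate properties matter when scoring recovery. First, the shared
interannual climate year-effects induce the same apparent trend component
at every pixel (its expected magnitude is c·σ_slope of a standardized
22-point series, ~0.0007/a per coefficient), so planted-trend recovery is
scored on the difference between the planted block and the zero-trend
region — exactly as a paired design removes a common shock. Second, the
land-use field drives the spatial pattern of mean EVI, so it should (and
in the acceptance runs does) take the top geodetector q rank against the
other scene drivers.

`generate_pls_dataset` draws indicator tables from a composite population
model: latents are exact unit-variance composites of their indicators,
within-block correlations are set so each indicator has the requested
composite loading, and cross-block indicator covariances follow the
path-implied latent correlations. PLS path modeling is a consistent
estimator in this population, which is what makes ±0.05 recovery at
n = 2000 a meaningful check; a common-factor generating model would
instead attenuate PLS paths by the composite reliabilities.

What the scenes do not emulate: cloud/gap structure, sensor noise
autocorrelation, mixed pixels at class boundaries, realistic land-use
change over time (categorical fields are static), geodesic cell-area
variation, and any radiative-transfer realism. Passing the recovery suite
therefore shows the estimators are correct under the stated statistical
structure, not that real MODIS products satisfy that structure.

## Problem sizes and runtimes

The test and acceptance workloads use 100×100-pixel scenes over 22 years
(20 seeds in the acceptance test, 10 in the script), 2000 null instances
(n = 500, L = 5) for geodetector calibration, 100–200 replicates of a
100-resample bootstrap for PLS null calibration, and n = 2000 tables for
PLS recovery — sizes at which every Monte-Carlo tolerance stated in the
tests is comfortably resolved while the whole suite stays in the
one-minute range on a single CPU. Larger rasters scale linearly in pixels
for every per-pixel engine (the pairwise-slope kernel is O(n²) in years,
vectorized over pixels).

## Known limitations

* No reprojection between CRSs; all layers must arrive in one projected
  frame, and the CRS is carried as an opaque tag.
* Mann–Kendall significance assumes serial independence; no prewhitening
  or seasonal variant is provided.
* The geodetector factor significance treats pixels as independent
  observations; spatial autocorrelation inflates the effective sample size
  and the ANOVA p-values are optimistic on strongly autocorrelated rasters
  (the q values themselves are unaffected).
* PLS-SEM here is composite-based; it is not a covariance-based ML SEM and
  offers no formative blocks or higher-order latents.
* The rasters input mode expects pre-co-registered layers; it performs no
  automatic resampling.
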