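# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want explained.

## Problem setting

The package studies how canopy structure relates to drought-induced tree
mortality in a mixed-conifer mountain forest. Two structural axes are
analyzed: individual tree size (height) and neighborhood canopy structure
(competition indices). The proposed mechanism is radiative sheltering:
trees overtopped by taller neighbors sit in their shade, carry a smaller
sunlit leaf fraction, transpire less, and therefore face less hydraulic
stress when water is scarce.

## Synthetic scene generator

The generator produces scenes with the statistical structure the analysis
assumes, plus a known mortality process so parameter recovery is testable.

**Terrain.** Gaussian-filtered white noise rescaled to the configured relief
(default 730–2650 m, matching a southern Sierra Nevada elevation span). The
filter length scale (default 120 m) keeps slopes gentle at 1-m resolution.
Note that the full default relief over a small test scene produces
unrealistically steep slopes; small-scene configurations in the tests and
examples use a few hundred metres of relief instead.

**Stems.** A Thomas cluster process (parents Poisson, offspring Gaussian
around each parent; plain Poisson available) with default intensity
120 trees/ha, mean cluster size 8 and cluster spread 8 m. Parents are
simulated in a buffered window so the realized intensity is unbiased at
scene edges. Forests are clustered; a homogeneous Poisson forest would
understate the local competition variance the analysis depends on.

**Genera.** Four genera with Gaussian elevation niches, normalized at every
elevation (softmax): *Abies* centred highest (2250 m), then *Cedrus*
(1750 m), *Pinus* (1300 m), *Quercus* (950 m), reproducing the altitudinal
ordering of the emulated landscape.

**Heights and crowns.** Per-genus Weibull heights truncated at genus caps by
inverse-CDF sampling; the oak cap is 24 m (the tallest oak observed in the
emulated study area), conifer caps 55–70 m. The source study reports no
height distributions, so the Weibull shapes/scales are package defaults
chosen to yield realistic canopy cover; they are exposed in `SceneConfig`.
Crown radius follows `0.6·h^0.7`; conifer crowns are vertical cones with
base at `0.4·h`, oak crowns are spheres fitted to the crown depth.

**Mortality process.** Logit-linear:

    logit P(dead) = β₀ + piecewise(h; k₁, k₂, s₁..s₃) + β_c·CCTH
                    + γ·(elev_km − c)² + ε,  ε ~ N(0, σ²)

with defaults β₀ = −0.5, knots (14, 39) m, slopes (−0.08, +0.05, −0.07)
logit/m, β_c = −0.02 logit per % CCTH, a mild elevation U-shape and
σ = 0.3. These encode the qualitative relationships the analysis targets
(negative-positive-negative height response; consistently negative
competition effect) with effect sizes that give a realistic ~4–5 %/yr
4-year mortality rate. Dead crowns draw their dead-pixel fraction from
Beta(5, 2.2) (mean ≈ 0.69) and live crowns from Beta(1.2, 12) (mean
≈ 0.09); the overlap of these two laws is what makes the apparent rate
respond to the call threshold. A 2 % pre-drought dead probability feeds the
exclusion rule.

**Rendering.** CHM pixel = max over overlapping crown surfaces, ground 0,
quantized to 0.01 m; a ground-truth crown-ownership label raster is kept.
Land-cover classes: crown pixels are green-tree, with each dead tree's
dead fraction of pixels repainted dead-tree; ground splits into
grass/bare/artificial/water patches from smoothed noise quantiles so all
six classes occur. Five per-pixel spectral features have class-separable
means plus Gaussian noise (sd 0.05 default) — enough structure for a
classifier stage, with no pretence of radiometric realism.

**What passing tests do not show.** The generator has no lidar point-cloud
artifacts, no species-classification error, no co-registration error
between imagery and CHM, no spatial autocorrelation in the mortality noise,
and crowns are ideal solids. Parameter recovery here demonstrates that the
estimators are correct, not that the real-data effect sizes are.

## Terrain derivatives

Slope/aspect use the Horn 3×3 kernel with odd-reflection border padding
(preserves plane gradients at edges); aspect is downslope, clockwise from
north, nodata on flats. Flow routing is D8 (steepest descent of eight
neighbors, diagonal distance √2): the simplest defensible reading of
"upstream contributing area". Single-cell pits are filled to their lowest
neighbor; remaining flats are routed toward the nearest draining cell
(breadth-first, i.e. a distance-to-lower-edge tie-break) with a warning.
Accumulation is in area units (upslope cell count × cell area, each cell
counting itself). TWI = ln(a / tan β) with specific catchment area
a = accumulation / cell width and tan β floored at 0.001.

Solar position uses the standard declination formula
δ = 23.45°·sin(360·(284+n)/365) and hour angle ω = 15°·(t−12) in local
solar time throughout — no longitude/equation-of-time correction, since the
emulated protocol specifies clock times only. The clear-sky surface sums,
over the requested hours (default 10:00–14:00 inclusive, five values),
direct beam S₀·τ^(1/sin h)·cos(incidence) on the tilted surface (clamped at
0) plus an isotropic diffuse term with fraction 0.15 and sky-view factor
(1+cos s)/2. Transmittance τ = 0.7 and the diffuse fraction are
configurable; the GIS tool this stands in for is proprietary, so the model
is deliberately simple and documented. No topographic horizon shading.

## Crown segmentation

Markers are local maxima of the Gaussian-smoothed CHM (σ = 1 px) above the
minimum height, with non-maximum suppression over a 2 m radius; the
watershed floods the inverted smoothed CHM from the markers, masked to
pixels at or above the minimum height. Segments with apex height < 5 m are
removed — the strict reading of the removal rule, so a 5.0 m apex
survives. The manual-correction step used on real imagery is replaced by a
greedy matcher (apex distance ≤ 3 m, height difference ≤ 3 m, nearest
first) reporting recall/precision/F against synthetic truth. Segmentation
recall on dense synthetic stands is limited by understory stems invisible
in a surface model — the same limitation as in real CHM-based inventories.

## Competition indices

CCTH and CC66 are pixel-count fractions of a circular neighborhood (pixel
centre in circle, default radius 15 m): the percent of buffer pixels whose
CHM value strictly exceeds 100 % (resp. 66 %) of the subject's height.
The subject's own segment pixels are excluded from the numerator but kept
in the denominator: the index measures cover of *other* taller canopy over
total neighborhood area. The source description is ambiguous on this
point; the choice is exposed as `exclude_own_segment`. Strict inequality
means ties do not count as "taller". CVTH is 100·sd/mean of all neighbor
stem heights (sample sd, centre excluded), undefined (NaN) with fewer than
two neighbors. Records are flagged when more than half the buffer falls
outside the raster.

## Crown shadow ratio

Crown surfaces are sampled uniformly (cone: lateral face with density
linear in distance from apex; sphere: full surface), 200 points by default,
fixed per tree by a seeded generator. For each of 23 half-hour steps
(07:00, 07:30, …, 18:00 — the step count is taken as authoritative over
the printed end time, which would give 24; the end time is configurable) on
the reference date (2016-08-01, latitude 37.42°), a point is shaded if the
ray toward the sun intersects any neighbor crown solid within 15 m (stem
distance, matching the competition buffer). Ray–solid tests are closed-form
quadratics for the sphere and finite cone (including the base disk).
Steps with the sun below the horizon are excluded from the daytime mean.
Terrain is ignored in the ray tests: within a 15-m neighborhood trees are
assumed to share a datum. Sampling the crown *surface* (not volume)
reflects reading "percentage of crown in shadow" as envelope shading.

## Two-leaf transpiration response

The canopy splits into sunlit fraction f and shaded fraction 1−f, with
per-leaf transpiration following a saturating light response
e(Q) = Q/(Q+Q_half) at relative irradiances Q_sun = 1.0 (direct+diffuse)
and Q_shade = 0.15 (diffuse only), Q_half = 0.3. Relative ET is the
f-weighted rate normalized by the zero-shadow reference. The shadow→f
mapping is a piecewise-linear table (73 %→0.17 … 91 %→0.05, extrapolated
linearly outside), exposed in `TwoLeafParams` because the tabulated grids
in the emulated protocol have mismatched lengths unless the shadow grid
ends at 91 %. This is a reduced qualitative model: only the sign and
monotonicity of the ET response are meaningful, not its magnitude, which in
a full biosphere model depends on parameterization this package does not
attempt.

## Dead-tree calling and rates

A tree is dead iff its crown dead-pixel fraction strictly exceeds the
threshold (default 0.35, "over 35 %"); the sweep covers 0.30–0.50 in 0.05
steps, and the apparent rate is non-increasing in the threshold by
construction. Pre-drought dead trees leave both numerator and denominator.
Rates are 100·n_dead/n_trees/years with years = 4 (forced by the published
arithmetic 180,765/1,050,960/4 = 4.3 %/yr), per stand or per axis-aligned
grid cell anchored at the raster origin, per genus and pooled. The
land-cover classifier is a random forest on the five spectral features with
a stratified, seeded 50/50 train/test split; held-out accuracy, confusion
matrix and per-class scores are reported.

## Statistical layer

**Binning.** Within each statistical unit, trees are binned along the
attribute (2 m height, 2 % CCTH/CC66, 0.1 CVTH); each (unit, bin) cell
contributes one rate observation weighted by its tree count. A second
weighted binning collapses these into the plotted/fitted series with
weighted means and unweighted quartiles; empty bins are dropped.

**Weighted fits.** WLS via statsmodels; weighted R² = 1 − SSE_w/SST_w about
the weighted mean; slope p-values from two-tailed t-tests. "Stepwise"
piecewise fitting is operationalized as an exhaustive grid search over
interior bin centers for 0/1/2 breakpoints (each segment ≥ 3 bins),
continuous hinge basis, selected by weighted BIC
n·ln(SSE_w/n) + k·ln(n); the search falls back with a warning when the
series is too short. The SSE is floored at numerical noise
(n·(10⁻¹⁰·scale)²) so exactly-linear data select zero breaks. Per-segment
slopes are cumulative sums of hinge coefficients with p-values from the
weighted covariance. An enumeration oracle verifies the search exactly on
short series.

**Beta regression.** y ~ Beta(μφ, (1−μ)φ), logit(μ) = b₀ + b₁x, fit by
weighted maximum likelihood (weights multiply the per-observation
log-likelihood; Nelder–Mead then BFGS polish; standard errors from the
inverse observed information). Boundary rates are pulled inside (0,1) with
y′ = (y(n−1)+0.5)/n. With unit weights the fit matches statsmodels'
independent beta-regression implementation, which serves as a cross-check
in the tests, not as the implementation.

**Mixed model.** Random-intercept model rate ~ CCTH + (1 | height group)
with tercile height groups, fit by maximum likelihood so the
likelihood-ratio test against the ordinary regression is valid. The LRT
uses a χ²(1) reference — conservative at the variance boundary, which is
acceptable here because the test is only used to flag whether the height
grouping matters. Singular fits report zero variance with a warning.

**Mediation.** a from mediator ~ exposure, b and c′ from
outcome ~ exposure + mediator (all weighted), indirect = a·b with a seeded
percentile bootstrap over units; total = c′ + a·b holds identically for
these linear models. No additional paths or covariates are modelled — the
analysis validates one hypothesized pathway, not a full latent-variable
structural model.

**Random forest.** Regression forest with ntree = 500, mtry = 3 on the
five drivers (height, CCTH, elevation, TWI, radiation; bin intervals 5 m,
5 %, 250 m, 0.5, 200 Wh/m²). Importance is the percent increase in MSE
under seeded feature permutation; partial dependence is evaluated on fixed
grids at the binning interval; an environment-only forest quantifies what
the structure features add (in-sample and OOB R² reported). No
multiple-testing correction anywhere: per-fit p-values are reported as is.

## Reproducibility

One global seed drives everything: stage seeds derive from
SHA-256(global_seed, stage name) mod 2³¹, and every stochastic component
(generator, classifier split, surface sampling, bootstrap, forests) takes
an explicit seed. `run_all` writes a manifest (config hash, stage seeds,
record counts, no timestamps) and reruns byte-identically.

## Problem sizes

The test suite and the acceptance script run on deliberately modest
problem sizes — scenes of 100–300 m a side (a few hundred to ~1,300
trees), 30–50 recovery replicates, 199–499 bootstrap draws — chosen so the
full chain, including ray tracing, runs in seconds to a couple of minutes
per stage while leaving every estimator's behaviour observable. All sizes
scale through configuration.

## Known limitations

Real-data ingestion is by schema (CSV/.asc/GeoJSON); no LAS/LAZ or GeoTIFF
readers. D8 (not D∞/MFD) routing; no horizon shading in the radiation
model; crowns as ideal solids without within-crown gap fraction; mediation
is a single-pathway check; the two-leaf ET magnitude is qualitative; the
segmentation harness cannot recover understory trees, mirroring the
physical limitation of surface models.
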