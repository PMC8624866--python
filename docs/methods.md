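# Methods

This note documents the models, the defaults and the reasoning behind the
genuinely open design choices. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and distances

Surveys arrive as WGS84 longitude/latitude and are projected to UTM zone
51N (transverse Mercator, k₀ = 0.9996, false easting 500 km) before any
spatial computation; all distances are planar Euclidean in metres. For an
island roughly 40 km across, the distortion of a single UTM zone is far
below the GPS uncertainty of the station coordinates, and planar distances
are what desktop-GIS interpolation uses. The projection is the Krüger
flattening series to fourth order in the third flattening (sub-millimetre
inside the zone); the working CRS is this package's choice — the motivating
survey never states one.

Three station pairs of the packaged 36-station geometry sit within 10 m of
each other (two are printed with bit-identical coordinates). Exact
interpolators (RBF, zero-nugget kriging) require distinct support points,
so coincident stations are averaged per parameter (tolerance 10 m) before
fitting; without this the kriging matrix is singular.

## Screening

- Skewness is the adjusted Fisher–Pearson statistic
  g₁·√(n(n−1))/(n−2) and kurtosis the bias-corrected excess kurtosis —
  the conventions of SPSS, which produced the summary tables this module
  mirrors. Both need n ≥ 4; constant samples get NaN markers.
- CV% = 100·s/x̄ with classes low (≤ 15), intermediate (15–35), high
  (≥ 35); both printed boundaries follow the source convention (15 → low,
  35 → high).
- Normality uses the one-sample K-S statistic with sample-estimated mean
  and sd. Because estimating parameters invalidates the naive K-S null
  distribution, the default is the Lilliefors-corrected p-value
  (`statsmodels`); the naive variant remains available via
  `variant="ks"` since the original workflow's exact setting is unknown.
- Correlation strength bins are on |r|: negligible < 0.10 ≤ weak ≤ 0.39 <
  moderate ≤ 0.69 < strong ≤ 0.89 < very strong. The printed scheme leaves
  gaps (e.g. 0.89–0.90); values inside a gap are assigned to the stronger
  bin and every bin's lower printed edge is inclusive. Significance is the
  two-tailed t-test on r ("\*\*" at 0.01, "\*" at 0.05), pairwise-complete
  over missing values.
- Guideline flags compare each parameter's mean against the PNSDW 2017 and
  WHO limits (range membership for pH, ceilings otherwise) and count the
  individual stations outside the limit.

## Interpolators

**IDW** — weighted mean over the k = 15 nearest stations with weights
d⁻ᵖ, p = 2 by default (the source reports no neighbourhood settings;
these are the common desktop-GIS defaults). Targets within 1 nm of a
station return the station value, making the method exact.

**GPI** — ordinary least squares polynomial trend (degree 1–3) on
centred/scaled coordinates, with an explicit rank check that suggests a
lower degree for degenerate geometries.

**LPI / KS** — at each target, weighted least squares with Gaussian kernel
w = exp(−(d/b)²); default bandwidth b is half the survey bounding-box
diagonal. Kernel smoothing is the same fit with a ridge penalty δ added to
the normal matrix (default 10⁻⁴; a leave-one-out search over a log grid
10⁻⁶…1 is available), which is how the barrier-capable smoother in desktop
GIS avoids the uncertainty of near-singular local fits. With barriers, the
distance is the shortest polyline-avoiding path, computed exactly on the
visibility graph over the two endpoints and all barrier vertices.

**RBF** — exact interpolation with polynomial drift via
`scipy.interpolate.RBFInterpolator`; default kernel is the thin-plate
spline φ(r) = r² log r (the minimum-curvature surface). Scale-dependent
kernels default to a shape parameter of one over the mean nearest-neighbour
spacing.

**Kriging** — the variogram γ(h) is estimated by the Matheron estimator in
12 equal-width bins up to half the maximum pairwise distance and fitted by
weighted least squares with Cressie weights N(h)/γ_model(h)² over the
spherical, exponential and Gaussian families (three starts per family; the
family with minimal weighted SSE wins). Fitted Gaussian models get a nugget
floor of 0.1% of the sill: a zero-nugget Gaussian variogram makes the
kriging matrix catastrophically ill-conditioned (the same reason Gaussian
process implementations always jitter the covariance diagonal), and fits on
very smooth data — densified surveys especially — otherwise drive the
nugget to zero. OK solves the standard augmented
system with the sum-to-one constraint; UK adds {1, x, y} drift columns
(centred/scaled for conditioning — predictions are invariant to that
affine reparametrisation). Neighbourhoods are global: with a few dozen
stations there is no reason to window. At-station predictions return the
measured value even with a positive nugget (the exact-interpolator
convention of desktop GIS); `exact_at_stations=False` switches to
nugget-filtered smoothing.

**EBK (simplified)** — fit a base variogram; K times, draw an unconditional
Gaussian realisation at the station locations from the current model and
refit a variogram to the realisation; predict as the equal-weight mixture
of the OK solutions over the surviving ensemble, with the between-member
spread of predictions added to the mixture variance. This propagates
variogram-estimation uncertainty, which single-model kriging ignores. The
proprietary original subsets data locally and weights members by
likelihood; this implementation uses a single subset (n ≤ 50 here) and
equal weights — a documented simplification. K = 1 reduces exactly to OK
with the base model.

## The network and its training

One hidden layer of tansig units, tansig output, minimum-maximum scaling of
inputs to [−1, 1] and of targets to [−0.9, 0.9] — the margin keeps extreme
training targets strictly inside the output activation's range. Data are
partitioned 70/15/15 (train/validation/test) uniformly at random given a
seed; validation/test sizes are ⌊0.15 n⌋ each, the remainder trains (36
stations → 26/5/5).

Levenberg–Marquardt minimises the training sum of squares in scaled units:
residual Jacobian by backpropagation, damping λ ×10 on a rejected step and
÷10 on acceptance, stopping on a gradient below 10⁻⁷, an iteration cap, or
six consecutive validation-MSE increases; the retained weights are the
best-validation ones, which by construction lie on the monotone
training-descent path.

PSO searches the flattened (W₁, b₁, W₂, b₂) vector inside [−2, 2] with the
canonical update and Clerc–Kennedy constriction-equivalent coefficients
(w = 0.729, c₁ = c₂ = 1.49445), velocity clamped at half the box; the
original work reports swarm sizes (1–10 particles, 2000 iterations) but no
coefficients, so the standard values are used and swarm size stays
configurable. Fitness is the training-partition MSE only, keeping
validation untouched for early stopping. The staging is search-then-learn:
the swarm's global best initialises LM. With zero PSO iterations the
trainer reduces exactly to LM from a random initialisation.

## The hybrid mechanism

"Network-informed interpolation" is implemented as survey densification:
the network learns target ← (x, y, temp, pH, EC, TDS) at the measured
wells, predicts the target at auxiliary sites that carry covariate values,
and the interpolator runs on the original stations plus the pseudo-stations
(flagged `is_pseudo`). This follows the sampling-density motivation of the
approach — interpolators improve when support points are added, and a
cheap-covariate surrogate is how a sparse survey can be densified without
new laboratory work. The exact wiring of the original hybrid is not
printed, so an alternative residual mode (interpolate network residuals,
add the trend back) is provided behind `residual_mode=True`; densification
is the default. Pseudo-points can be downweighted (λ_pseudo) where the
interpolator is weight-aware (LPI/KS); kriging treats them as ordinary
data.

Covariates default to x, y plus the four physicochemical parameters for
heavy-metal targets, and to x, y alone for physicochemical targets (their
natural covariates would be their own siblings — circular).

## Cross-validation

LOOCV iterates over measured (never pseudo) stations. In hybrid mode the
entire pipeline — network training and pseudo-point generation — is refit
inside each fold from the remaining stations, so no held-out value leaks
through the network; a documented `fast` mode reuses the full-data network
for exploratory work. Method selection is min MAE with ties (within 10⁻¹²)
broken by max R; MAE is primary because the published summary tables are
consistent with that ordering.

## Synthetic surveys

The generator draws a latent Gaussian random field with a spherical
variogram (defaults: nugget 0.1, partial sill 1.0, range 3000 m — a
mid-island correlation length) at the 36 fixed stations plus the raster
cells, by exact dense-covariance factorisation (capped at 2500 points;
desk-scale simplicity beats spectral scalability here). Station
measurements add iid noise (sd 0.05); covariates are linear links
coef·latent + noise (default coefficients 0.6–0.9, noise sd 0.3, i.e.
target–covariate correlations roughly 0.8–0.95), with an optional monotone
tanh link to exercise the network's nonlinear advantage. Zero link
coefficients give the uninformative-covariate control under which hybrids
are *not* expected to win.

What the generator does not emulate: the real survey's unknown spatial
trend, seasonal dynamics, censored detection limits, non-Gaussian
concentration distributions (real heavy metals are heavily right-skewed),
and measurement error heteroscedasticity. Passing tests therefore
demonstrate the machinery is correct under the model's own assumptions, not
that the hybrid wins on any particular real aquifer.

## Problem sizes and numerics

The test suite and acceptance script run the hybrid comparison at a reduced
budget — 10 particles × 200 PSO iterations, 3 hidden units, LM capped at 40
iterations per fold, 100 auxiliary sites, EBK ensembles of 8 inside CV —
sizes chosen to keep full LOOCV-with-refitting tractable at desk scale
while preserving the qualitative behaviour; the full-scale defaults
(hidden 20–30, 2000 iterations, K = 100) remain the library defaults. In
that configuration the surrogate's inputs are the four physicochemical
covariates without x/y: with ~25 training rows, coordinate inputs cannot
recover the spatial field (a random field is not a smooth learnable
function of position at that n) and act purely as overfitting fuel — a
network with them generalises measurably worse to auxiliary sites than one
without, and worse than a linear fit. At larger n the full covariate set
including location is the sensible default and remains so in the library.
Numerical tie-breaks and degeneracies: variogram fits are bounded (nugget
and sill by the empirical maximum, range by twice the max lag); kriging
matrices are LU-factorised once per configuration and duplicate stations
raise with the offending pair named; LPI targets with no effectively
weighted neighbour return nodata with a warning; IDW at a station returns
the station value; PSO resamples non-finite initial positions up to 100
times.

## Known limitations

- EBK is an equal-weight, single-subset simplification (no likelihood
  weighting, no local model blending).
- Anisotropy is not modelled anywhere (isotropic kernels, variograms and
  neighbourhoods) — the source reports no anisotropy settings.
- Barrier distances are exact only for polyline barriers; raster
  cost-surface (diffusion-kernel) interpolation is out of scope.
- The network input set for the original per-parameter models is unknown;
  the covariate default here is one defensible reading.
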