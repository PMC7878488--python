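# Methods

This note documents the models implemented in `grazecap`, the parameter
choices that matter, what the synthetic county does and does not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The accounting model

The unit of account is the **sheep unit** (SU): the forage demand of one
standard sheep, 4.0 kg/day here. Other herbivores are expressed as
multiples — cattle 4.5, horses 6 (configurable; only sheep = 1 is fixed by
definition), kiang 6, Tibetan gazelle 0.3 SU per animal.

Per grazing-management parcel of area *S* (km²):

| quantity | definition | meaning |
|---|---|---|
| *C*_tp | *Y*·*E*·*U* / (*I*·*T*) | theoretical capacity per unit area from grass yield *Y* |
| *C*_w | Σᵢ *D*ᵢ·*S*ᵢ·*K*ᵢ | wildlife forage demand (density × area × conversion) |
| *C*_t | *C*_tp·*S* − *C*_w | ecological capacity once wildlife is fed |
| RCC | *C*_t − actual | residual capacity; < 0 ⇒ overloaded |

Defaults: edible forage ratio *E* = 0.85, grazing utilisation rate
*U* = 0.65 (the conservative end of the 0.65–0.70 range reported for alpine
steppe/meadow), intake *I* = 4.0 kg/SU/day, *T* = 365 grazing days. The
ledger identities *C*_t + *C*_w = *C*_tp·*S* and RCC + actual = *C*_t are
exact subtractions and are asserted to 1e-9 SU in tests, as is conservation
of every county total under the parcel partition.

**Tie rule.** RCC = 0 is "at capacity", not overloaded; only strictly
negative values raise the overload flag.

**Negative *C*_t** (wildlife demand exceeding forage) is permitted and
flagged, not clamped.

## Grass yield

Peak-season NDVI layers are reduced cellwise by the **maximal-value
composite** (a cell is nodata only if nodata in every layer), then converted
by the fixed affine model *Y* = −47.021 + 440.21·*X*. NDVI below ≈ 0.1068
gives negative *Y*, which is clamped to 0 by default with the clamp count
logged — bare ground grows no forage.

**Units.** The source of the affine model does not pin down *Y*'s units, so
they are explicit configuration carried through every total. The default is
g/m² (≡ t/km²): with realistic alpine-steppe NDVI of ~0.2–0.3 this puts the
synthetic county's annual yield near 1.3 million tonnes, the right order of
magnitude for a ~25,600 km² county; reading the same numbers as kg/ha would
put it an order of magnitude lower. Conversions among g/m², t/km², kg/ha,
t/ha and kg/km² are exact and round-trip to 1e-12.

## Transect densities

Counts become densities with the strip-transect estimator
SAD = count / (2·*w*·*L*), with a single configurable effective half-width
(*w* = 0.5 km by default) and the line midpoint as the support point for
interpolation. No distance-sampling detection function is fitted — the
survey protocol behind the discovery rates is not specified, so the simplest
defensible estimator is used and isolated behind one parameter. Seasonal
densities at the same routes are merged by the arithmetic mean by default
(max and per-season passthrough are available); the identity
discovery rate × 2·*w* = effort-weighted mean SAD is asserted on random
tables.

## Ordinary kriging

- Empirical semivariogram: Matheron estimator, distance-binned, empty bins
  omitted; verified against an O(n²) pair-enumeration oracle.
- Model fit: weighted least squares (weights = pair count / lag²) over
  (nugget, partial sill, range) with bound constraints and three range
  starts; spherical by default, exponential and gaussian available. A
  pure-nugget flag is raised when the partial sill is negligible or the
  range runs to its bound (white-noise data have no identifiable range).
- Prediction: moving neighbourhood of the 16 nearest points (all points
  when fewer), covariance-form system C(h) = sill − γ(h) with a Lagrange
  multiplier enforcing Σλ = 1. Covariance and variogram forms give
  identical weights; the tests assert both against a directly assembled
  dense augmented system to 1e-10. A singular system gets one tiny
  diagonal jitter retry, then errors.
- Grid registration: cell centres, row-major from the north-west corner,
  5 km spacing (cell area 25 km²).
- Negative predictions are clamped to 0 with a logged count — densities
  cannot be negative. Kriging variances are checked non-negative to −1e-9
  before a final clamp.
- Leave-one-out cross-validation (RMSE, mean error) accompanies every
  pipeline fit.

## Maxent-style range model

Features are linear + quadratic terms of each covariate, standardised over
the background (every county cell); aspect, being circular, enters as
(sin, cos). The model is the Gibbs distribution p(cell) ∝ exp(w·f)
maximising the L1-penalised mean presence log-likelihood — a convex
problem. The penalty weight is β/√(n presences) with β = 0.5 by default,
the usual MaxEnt scaling that tracks the standard error of the presence
feature means; β = 0 gives exact moment matching (fitted feature
expectations equal presence means, verified against a coefficient-grid
oracle), very large β gives the uniform model. The solver is L-BFGS-B on
the standard non-negative splitting w = u − v; its line search makes the
objective trace monotone, and the Gibbs normalisation error is tracked at
every evaluation (asserted < 1e-9).

The suitability score is a logistic transform of the centred linear
predictor — monotone in w·f, so threshold rules are unaffected by the
choice of transform. The default binarisation keeps cells at least as
suitable as the **10th percentile of the presence cells** (ties inclusive),
a common presence-threshold convention; by construction ≥ 90 % of presences
fall inside the mask. The mask **clips** the kriged density (outside → 0,
inside unchanged, no renormalisation), and population totals are computed
after masking, with the removed total logged.

**Known bias.** Clipping without renormalisation, combined with the
10th-percentile rule, systematically discards mass: roughly the bottom
decile of presence-weighted density, plus whatever the kriging smoother
spreads across the hard range edge before the mask zeroes it. On the
synthetic county this makes masked population totals run ~10 % (large,
widespread species) to ~15 % (smaller-ranged species) below the latent
truth on average. This is a property of the estimator chain, not of the
synthetic data; users comparing masked totals to independent population
estimates should expect it.

## Synthetic county

What it emulates, with defaults chosen once as study conditions:

- **Geometry** — a 160 × 160 km county (25,600 km², the order of the real
  ~25,300 km² county) tiled exactly by 27 Voronoi parcels of random seeds,
  mimicking irregular grazing-management boundaries. Planar km coordinates
  throughout; the 5 km grid is planar in effect, and geodesy would buy
  nothing but inexact tests.
- **Covariates** — smooth Gaussian random fields for elevation
  (4500 ± 180 m), derived slope/aspect, and two climate surfaces with weak
  latitudinal trends around −3.8 °C and 304 mm.
- **Wildlife truth** — per species, a logistic suitability in the
  standardised covariates binarised at probability 0.5, times a
  log-Gaussian density field (log-sd 0.6–0.7, correlation 15 km), scaled so
  the county-mean density equals the configured target exactly.
- **Surveys** — 250 fixed routes of 10 km traversed in each of two seasons
  (500 transect-records per species); midpoints drawn from the extent
  buffered by half a transect length so survey effort is uniform over the
  county after clipping (no edge bias). Counts are Poisson with mean =
  line-mean density × 2·*w*·detection × length; per-season density surfaces
  are i.i.d. mean-one lognormal perturbations of the truth (CV 0.15). No
  detection model beyond a single probability is assumed.
- **Calibration** — the species' mean densities are set from the target
  discovery rates (1.33 and 0.49 animals/km/season) via
  density = rate / (2·*w*·detection), so the printed rates are reproduced
  in expectation by construction. With the default strip geometry this
  implies latent populations of ~34k and ~12.5k animals — the discovery
  rates, not the published population estimates (which are analysis
  outputs), are the generator's conditions, and the real survey's strip
  geometry is unknown. One consequence: the default synthetic county is
  overall overloaded (negative county RCC), unlike the real one.
- **NDVI** — a clean greenness field tracking precipitation (mean 0.22,
  sd 0.06) degraded per date by random multiplicative cloud dips, so the
  maximal-value composite approximately recovers the clean field and the
  county yield lands near 1.3 Mt.
- **Livestock** — the configured county herd (338,159 SU, 73/24/3 %
  cattle/sheep/horse) allocated over parcels proportionally to area with
  gamma weights; cattle/horse heads are rounded and the sheep column
  absorbs the residual, so each parcel's SU total is within 0.5 SU of its
  allocation.

What it does **not** emulate: realistic plateau topography, multi-species
interactions, observer- or group-size-dependent detection, MODIS artefact
structure, or the real parcel boundaries. Passing recovery tests therefore
show the estimator chain is implemented correctly and behaves sensibly
under idealised sampling — not that its accuracy transfers to the real
survey design.

## Numerical conventions and degenerate inputs

- γ(0) = 0 exactly; the nugget applies for h > 0. C(0) = sill.
- Zonal statistics assign each cell to the first parcel whose polygon
  covers its centre (interiors are disjoint, so this is unambiguous up to
  boundary ties); round-off orphans go to the nearest parcel. Parcel
  integrals therefore sum to the county integral exactly; no area-weighting
  of boundary cells at 5 km resolution.
- A parcel containing no cell centre is flagged with null zonal values and
  contributes zero to totals.
- A species never observed on any transect gets an empty range mask and a
  zero masked density (no estimable range), not an error.
- All generators and the pipeline are pure functions of (config, seed);
  identical seeds give byte-identical CSV outputs.
- Standardisation guards: constant covariates are dropped from the feature
  space with a warning; constant fields short-circuit to zero z-scores.

## Problem sizes

The default configuration — a 32 × 32 grid of 5 km cells, 250 transect
lines × 2 seasons, 2 species, 27 parcels — runs the full pipeline in a few
seconds on one core, and is the size at which the recovery checks in the
test suite are run.

## Known limitations

- Whether the yield model's output is fresh or dry mass is inherited,
  unresolved, from its source; only the unit basis is configurable.
- The seasonal merge rule (mean) and the strip half-width are conventions,
  not reconstructions of the original survey analysis.
- Kriging assumes isotropy and a single global variogram per species;
  zero-inflated density fields violate stationarity near range edges, which
  is one driver of the masking bias described above.
- The published suitable-area figures depend on the real covariates and
  presence records and are not reproducible from synthetic data; the
  habitat model is validated by rank-recovery of known suitability instead.
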