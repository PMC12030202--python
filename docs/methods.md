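# Methods

This note records the models implemented in `ricenni`, the assumptions
behind them, the design of the synthetic trial generator, and the
numerical choices made where the procedure left room.

## Critical-N dilution curve and NNI

The dilution curve `Nc = a · DM⁻ᵇ` expresses that, as a crop accumulates
structural biomass, the N concentration needed for unrestricted growth
falls (self-shading and the rising share of low-N structural tissue).
`a` is the critical concentration (%) at 1 t/ha of shoot dry matter; `b`
(dimensionless, in (0, 1)) is the dilution rate.

Construction follows the classical grouping-and-intersection procedure,
per sampling date:

1. **Grouping.** One-way ANOVA on shoot dry matter across N rates,
   followed by pairwise least-significant-difference t-tests between
   adjacent rates, both at α = 0.05. A treatment is *N-limited* iff it is
   the zero-N control or its dry matter is significantly above the
   previous rate's; the rest form the *non-limited* group (biomass
   saturated, N concentration still rising). The ANOVA/LSD statistics are
   computed from the standard sums-of-squares formulas with scipy's F and
   t distributions; zero within-group variance (exactly replicated
   synthetic data) is handled by a relative tolerance rather than an
   infinite F. Dates with no significant structure, or where the
   intersection falls at a non-positive concentration, are skipped with a
   logged warning.
2. **Intersection.** A straight line (the oblique) is fitted by ordinary
   least squares to the N-limited points in the N%-vs-DM plane — the
   concentration axis, consistent with reading the critical value off the
   ordinate — and intersected with the vertical at the non-limited
   group's mean dry matter. That ordinate is one critical point.
3. **Allometric fit.** `log Nc = log a − b · log DM` by linear least
   squares, which is exact on power-law input; R² is reported in the
   original concentration space. Standard errors for `b` and `log a`
   come from the usual simple-regression formulas. Dry weights are
   stored in kg/ha; curve fitting and the validity range use t/ha; plant
   N accumulation multiplies kg/ha by %/100, giving kg N/ha.

`NNI = Na/Nc` at the plot's own dry matter; above 1 the crop holds
surplus N, below 1 it is deficient. Evaluating the curve outside its
fitted dry-matter range warns but does not fail, since in-season
diagnosis routinely extrapolates a little.

## Vegetation indices and gray relational screening

Nine two- and three-band indices are computed from the 450/560/650/730/
840 nm reflectance fractions. Two dialect decisions:

- **NDRE** is offered in two forms: `as_printed` (default), which uses
  the red band and is therefore identical to NDVI — kept for fidelity to
  the index table this package mirrors — and `red_edge`,
  (NIR−RE)/(NIR+RE), the conventional definition.
- **PSNDc** is the normalized NIR/blue difference (NIR−B)/(NIR+B).

Zero denominators yield NaN markers instead of exceptions; the inversion
stage refuses NaN features by name so silent imputation cannot occur.
Soil background is removed by an NDVI cut (default 0.3, a common
canopy/soil boundary; configurable). Plot-level reflectance from an
image stack is the *mean* of masked pixels (median available upstream if
desired); the raster helper takes plain (5, rows, cols) arrays or
multi-band TIFFs with pixel-coordinate plot rectangles — georeferencing
is out of scope.

Gray relational analysis uses Deng's formulation: sequences are first
non-dimensionalised (division by the series mean by default;
initial-value normalisation by flag — the choice matters because Δmin
and Δmax depend on it), the coefficient at each point is
`(Δmin + ρΔmax)/(Δ(k) + ρΔmax)` with Δmin/Δmax taken globally over all
comparison series, ρ = 0.5, and the degree is the arithmetic mean of a
series' coefficients. If every comparison series equals the reference
(Δmax = 0) the coefficients are defined as 1. Indices whose degree
exceeds 0.7 in *every* growth stage are selected, ranked by mean degree
with ties broken by the fixed table order. Degrees are computed per
stage (and per cultivar when both are present) rather than pooled.

## Random-forest NNI inversion

`RandomForestRegressor` with 100 trees and maximum depth, minimum
samples split and minimum samples leaf all equal to 2. The depth is
deliberately shallow — the selected indices are strongly collinear and
the target has few effective levels per stage — and can be overridden in
the model spec. The 70/30 train/test split is stratified by growth
stage and fully determined by its seed. Metrics: RMSE; R² as 1−SSE/SST;
"accuracy" defined here as 1 − mean(|pred − meas|/meas) (one minus the
mean relative error — stated explicitly because the label is used
loosely in the literature); and k, the through-origin least-squares
slope of predicted on measured, so k ≈ 1 means an unbiased 1:1 fit.

## Linear plateau and N balance

The plateau model is fitted by grid search over candidate breakpoints:
every observed NNI value is a candidate (points at or above it belong to
the plateau); below the candidate a line is fitted by least squares,
above it the plateau is the group mean; the candidate with minimal total
SSE wins, ties going to the smallest breakpoint. Because the SSE is
piecewise constant in the breakpoint between data values, restricting
candidates to the data is exact. By default the two pieces are *not*
constrained to meet: the reference japonica parameters
(1.088, 0.08, 1.01, 1.01) are themselves discontinuous by ~0.009 at the
breakpoint, so a continuity constraint could not reproduce them; a
`continuous=True` flag imposes `c = a·NNI_max − b` when a joined model
is wanted. At the breakpoint itself the plateau value applies
(`NNI ≥ NNI_max → c`).

The balance chain multiplies the attainable yield by the predicted
relative yield, converts to grain N demand via APGN (kg N per 100 kg
grain), subtracts the soil supply Ns (N uptake of the unfertilised
control), divides by NUE = 0.426 and subtracts N already applied.
Negative requirements are clamped to zero and flagged (a surplus soil
needs no topdressing). The remainder after the basal dose is split
proportionally to the stage ratios (default 2:1 across jointing and
heading; the stages and ratios are configurable because the two
cultivars' schedules differ). Amounts are held at full precision and
rounded to 2 decimals only when written.

One policy switch, `saturated_ry`, controls what relative yield a
plateau-saturated crop is credited with: `plateau_c` (default) uses the
fitted plateau value; `unity` credits the full historical maximum
(RY = 1). Both appear in published recommendation tables — the indica
reference totals are only reproducible with `unity` while the japonica
ones need `plateau_c` — so the choice is explicit per cultivar rather
than hidden.

## Synthetic trial generator

The generator emulates a 2-cultivar × 5-N-rate (0/60/120/160/200 kg/ha)
× 4-stage (TR/JT/HD/FL) replicated field trial; the default 4 plots per
rate gives 80 records per cultivar, matching the data volume the
inversion stage assumes. Its defaults are the study conditions:
japonica curve (2.24, 0.35), plateau (1.088, 0.08, 1.01, 1.01),
Ymax = 10 573.3 kg/ha, APGN = 1.97; the indica counterparts are (2.78,
0.46), (2.266, 0.86, 0.82, 0.99), 9 505.8 and 2.13.

Structure, chosen so the analysis chain is *exact* on noise-free data:

- **Biomass.** Non-limited shoot dry matter follows a stage ladder
  (1, 3, 6, 9 t/ha), spanning most of the curves' stated validity
  ranges (≈0.34–12.5 t/ha). The N-rate effect is a saturating ramp
  `m(rate) = 0.55 + 0.45·min(rate, 120)/120`: a piecewise-linear link
  rather than a logistic, because a logistic never exactly reaches its
  plateau and the recovery invariants require the top rates to sit
  exactly on it. The ramp saturates at the middle rate, so the two
  highest rates share identical biomass and differ only in N
  concentration — exactly the structure the grouping step must detect.
- **N concentration.** For rates up to saturation,
  `NNI(m) = m^b · (1 + c·(m−1))` with c = 0.45 the oblique strength;
  algebraically this places the limited points exactly on a straight
  line through the critical point `(DM_max, a·DM_max⁻ᵇ)`, so the
  intersection step is exact by construction (the saturation rate lands
  on NNI = 1). Rates beyond saturation take a plateau NNI of 1.05 —
  above the yield breakpoint, i.e. luxury uptake. Organ partitioning
  uses stage-dependent leaf/stem/panicle fractions with leaf N enriched
  1.4× and panicle 1.1× relative to the shoot mean; the stem ratio is
  solved so the weighted mean equals the plant value exactly.
- **Yield.** Final-stage rows carry `Ymax · plateau(NNI)`.
- **Reflectance.** NIR rises and red falls linearly with NNI (green,
  blue and red edge move weakly), an empirical monotone surrogate — not
  a radiative-transfer model — sufficient to make NDVI-family indices
  co-monotone with N status. Noise: multiplicative lognormal (median 1)
  for dry matter, N% and yield, preserving positivity; additive Gaussian
  truncated into [0, 1] for reflectance (with a 1e-4 floor so ratio
  indices stay defined under heavy noise). Defaults: 5 % DM, 3 % N%,
  0.02 reflectance, 4 % yield — typical plot-level agronomic noise.
  All randomness comes from numpy `SeedSequence` substreams of one seed;
  generation is bit-reproducible.

What passing tests on this generator do *not* show: real canopies
saturate NDVI at high biomass, mix soil and water background into plot
means, and decouple reflectance from N status under disease or lodging;
real N-rate designs rarely give the clean biomass plateau the generator
guarantees. Field performance of the inversion therefore cannot be
inferred from the synthetic recovery results — only the correctness of
the arithmetic and the fitting procedures can.

## Problem sizes and tolerances

Noise-free recovery is asserted to 1e-6 (observed: machine precision).
Simulation-based checks use 200 replicates for the dilution-curve and
plateau noise studies (5 % multiplicative and 0.02 additive noise
respectively) and 10 repeated trials per reflectance-noise level
(SDs 0.05/0.01/0.001) for the inversion convergence ladder — sizes at
which the Monte-Carlo error is comfortably below the asserted margins
while the whole suite runs in seconds. Pairwise LSD and ANOVA use
α = 0.05 throughout. The soil-mask default is NDVI ≥ 0.3.

## Known limitations

- The reflectance–NNI link is a monotone surrogate; no attempt is made
  to emulate band physics, view geometry or calibration error.
- The grouping rule needs ≥ 2 replicates and ≥ 3 rates; unreplicated
  trials cannot be classified.
- Gray-relational degrees depend on the normalisation choice; both
  supported choices are documented and selectable, but results are not
  comparable across them.
- The recommendation table's per-treatment errors summarise replicate
  spread of the inverted NNI only; they carry no model-form uncertainty.
- No economic optimisation: the calculator targets the agronomic
  requirement, not an economically optimal N rate.
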