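# Methods

## Model and estimation

The response is the natural log of weekly gravimetric-equivalent PM2.5
(μg/m³) or weekly BC filter absorbance (10⁻⁵ m⁻¹) on its natural scale.
The mean structure is linear in standardized predictors; site and
week-of-year enter as crossed (not nested) random intercepts, absorbing
repeated-measure correlation at the year-long fixed sites and shared weekly
meteorology across sites. Estimation is restricted maximum likelihood. The
two variance ratios γ_site = σ²_site/σ²_ε and γ_week = σ²_week/σ²_ε are
profiled: for given ratios, the GLS coefficients, the residual variance and
the REML criterion are computed through a Woodbury identity on the stacked
site/week indicator matrix, so one evaluation costs O(q³) with
q = n_sites + n_weeks (≈ 200) instead of O(n³). The criterion is minimised
by Nelder–Mead in log-ratio space from several starts, including
boundary-like starts, and ratios below 10⁻⁸ are reported as exact zeros.
Wald inference uses the normal reference (z), as no degrees-of-freedom
method is canonical for crossed designs. Tests cross-check the fit against
closed-form OLS (noise-free and boundary cases), the balanced one-way ANOVA
estimator, and statsmodels `MixedLM` with crossed variance components.

## Variable selection

Stage one computes Pearson correlations between every realized candidate
column and the response, keeps the single buffer radius with the largest
|r| per variable (ties break toward the smaller radius, then name), and
removes candidates whose correlation sign contradicts the a-priori sign
registry. Month-of-year indicators travel as one block candidate with a
joint Wald χ² p-value, mirroring how calendar-month terms enter final
models together.

Stage two is supervised forward selection. Each step evaluates every
remaining candidate against the current model and accepts the qualifying
candidate with the largest adjusted-R² gain; because a first step's gain is
its squared correlation, the procedure starts from the highest-|r|
candidate. A candidate qualifies when (a) it adds at least
`delta_adj_r2 = 0.01` (absolute) to the fixed-effects adjusted R², (b) its
coefficient (or block) is significant at `alpha = 0.05`, (c) no variance
inflation factor exceeds `vif_max = 3`, and (d) its fitted sign matches
expectation. Accepted variables are never removed; when no candidate
qualifies, every rejected candidate is retried once against the final model
in its original order. A strict rank-order stepping variant
(`SelectionConfig(order="rank")`) is retained for comparison.

Two internals deserve a note, both consequences of the extreme row
imbalance of the design (10 fixed sites contribute ~80 % of rows):

- **Selection metric.** The Δ-adjusted-R² gate uses an auxiliary
  fixed-effects-only OLS refit, which is monotone in added columns. The
  squared correlation between the observed response and the *GLS* fixed
  predictor (also exposed, as `fixed_effects_adj_r2`, and used for
  reporting) is not monotone under this imbalance and can decrease when a
  genuinely informative variable is added.
- **VIF.** Inside selection, VIF is derived from the fitted model's
  coefficient covariance (the quantity R's `car::vif` reports for a mixed
  model): the inverse-correlation diagonal of the non-intercept covariance
  block. Raw row-design VIF massively overstates collinearity here, because
  repeating a site's covariates 35× mechanically reweights the correlation
  structure that the GLS fit, via its random intercepts, does not see. The
  plain auxiliary-regression `vif(X)` is kept for design matrices.

## Quality control and gap filling

A weekly sample is retained when the sampler ran ≥ 75 % of the 7-day window
and held its mean flow within ±10 % of 1 l/min (both bounds closed; the
flow comparison carries a 10⁻⁹ relative slack so a deviation of exactly the
tolerance passes in binary floating point). Failed gravimetric samples with
a co-located continuous weekly mean are replaced by CF × continuous, where
the correction factor CF is the ratio of summed gravimetric to summed
continuous values over all QC-passing co-located pairs (per-site CFs with a
pooled fallback are available). Rows with neither source are flagged
excluded; rows are never deleted. Negative continuous readings are treated
as missing rather than clipped to zero. One absorbance unit converts to
1.67 μg/m³ elemental carbon.

## Spatial statistics

All geometry lives in one projected metric frame; coordinates that look
geographic (inside ±180° × ±90°) are rejected. Buffers are closed disks
(boundary inclusive), realized as 384-gon polygons (radial error
< 2×10⁻⁴ r). Raster statistics use cell-centre containment; population
density uses exact area-weighted polygon intersection with gaps counting as
zero; inverse distance is clamped at 1 m; elevation is sampled at the site
cell (no buffer). Enumeration-area means use cell-centre containment with a
containing-cell fallback for EAs smaller than one grid cell (area-weighted
intersection is available and agrees within 5 % on EAs spanning ≥ 10
cells). Wind direction is excluded from the default registry (circular
variable); a sine/cosine pair is available via configuration.

## The synthetic metropolis and campaign

The generator emulates the *conditions* of a one-year West African urban
campaign, not any particular city's geography. Defaults (12 × 12 km,
centre at 6 km):

- **Roads**: eight multi-lane arterial corridors (major; five parallel
  carriageways, lane spread 50–110 m) at offsets from the centre, 24
  connector chords and the two inner rings (secondary), outer rings plus 60
  centre-biased local streets (minor). The urban core is denser in local
  streets; arterial corridors are deliberately offset so that road-length
  and distance-to-road fields are not mere centrality proxies.
- **NDVI** (30 m): 0.10 at the core rising to 0.42 at the periphery plus a
  smooth noise field (sd 0.22, correlation length ~900 m), clipped to
  [−1, 1].
- **Land use** (20 m): a development-intensity score (0.3 × radial fraction
  + a high-frequency noise field) thresholded at its 12 % / 35 % / 68 %
  quantiles into commercial-business-industrial, informal-residential,
  formal-residential and open classes.
- **Population** (1 km zones): 25 000 people/km² at the core decaying
  radially (scale 0.45 rmax) times a spatially smooth lognormal field
  (log-sd 1.0, correlation length ~1 km). Smoothness at the buffer scale
  makes the 50–500 m buffered densities near-equivalent, as census-based
  density surfaces are in practice.
- **Amenities**: bus stops/terminals, restaurants, shopping centres with a
  mild centre bias in areal density; **rivers**: eight high-frequency
  sinusoids; **elevation** (90 m): relief-dominated (sd 40 m) over a gentle
  tilt; **airport**: a single point near the extent edge.

Weekly meteorology follows two regimes: harmattan (Nov–Feb, ≈ 17 of 52
nominal ISO weeks) with no rainfall, lower relative humidity (60 vs 80 %),
lower wind speed (1.8 vs 3.2 m/s), shallower mixing layers and
north-easterly winds; and the rest of the year. The sampling design places
10 fixed (all 52 weeks) and 136 rotating sites (one week each, uniformly
assigned) by stratified random sampling over peri-urban / CBI / low-density
/ high-density strata defined from the land-use raster and distance to the
centre.

Ground-truth log-PM2.5 uses standardized effects patterned on what
published LUR models of this kind report: NDVI (100 m) −0.12, population
density (50 m) +0.12, major-road length (500 m) +0.07, an additive seasonal
shift of log 4 (a 4-fold harmattan elevation of the mean), and variance
components σ²_site = 0, σ²_week = 0.004, σ²_ε = 0.032, giving a
fixed-effects R² ≈ 0.5. The residual is dominated by per-sample noise
(weekly gravimetric measurement and micro-environment variability) rather
than by shared site- or week-level components: with 35 repeated rows per
fixed site, even a small site-level residual variance inflates the chance
gains of the row-level selection statistics roughly threefold and makes
exact support recovery unattainable at the stated thresholds, so the
generator emulates the spatially well-specified regime. BC absorbance is
linear on its natural scale (floored at 0) with major/secondary road and
NDVI effects and a +5.7 shift doubling the harmattan mean. QC metadata is
simulated with a ~4 % runtime-failure and ~2 % flow-failure rate, and the
continuous monitor reads low by a factor 1.25 (the generating CF).

Synthetic enumeration areas tile the urban core with 200 m squares carrying
~775 residents each; SES (median log equivalized household consumption)
rises with distance from the core and greenness and falls with local
population density (−0.7 per log-density sd), i.e. it is negatively coupled
to the generating exposure field; the post-secondary education share is a
logistic transform of SES.

### What the generator does *not* emulate

Real road topology and census geometry; traffic volumes; unpaved-road and
trash-burning sources; instrument drift and filter artefacts beyond a
lognormal error and a constant continuous-monitor bias; lockdown-style
interruptions; spatially correlated residual concentration structure beyond
the site intercept. Consequently, passing tests demonstrate that the
pipeline's estimators and selection machinery behave correctly under the
stated generating model — not that a three-to-five-variable LUR suffices
for any particular real city.

## Recovery experiments

Two seeded simulation experiments back the headline claims
(`lurmap.pipeline`):

1. **Parameter recovery** — 20 replicates of the full pipeline on the
   146-site design; the selection runs on the non-harmattan subset over the
   spatial candidate inventory, excluding the two distance transforms of
   the major-road lines (deterministic monotone transforms of the road
   truth within 500 m; exact support recovery against them is ill-posed for
   any marginal-correlation ranking). Support recovery is scored at the
   variable level, since buffer radii of one variable correlate 0.7–1.0 and
   the max-|r| pick may land on a neighbouring radius; CI coverage compares
   each recovered coefficient with the generating value, pooled over
   replicates. Measured at build time: 29/30 seeds recover the exact
   variable set; pooled coverage 0.94.
2. **Inequality recovery** — 20 replicates on a compact 6 km scene: fit the
   non-harmattan PM2.5 model on the true support, predict the 100 m
   seasonal surface, overlay synthetic EAs, and test SES-quintile
   differences. The poorest-quintile mean exceeded the wealthiest with
   ANOVA p < 0.05 in 20/20 seeds at build time.

Problem sizes (146 sites for recovery, a 6 km scene and 100 m grid for the
inequality runs, 20 replicates each) were chosen so both experiments
complete in a few minutes on a single CPU while leaving the conclusions
stable across seeds.

## Numerical choices and conventions

- Tie-breaks: buffer pick ties toward the smaller radius, then name;
  greedy-step ties toward larger |r|.
- Fold assignment: sample-level by default (matching "a random 90 % of
  samples"); whole-site grouping available because the fixed sites'
  52 correlated records otherwise leak across folds (documented caveat).
- Exponentiation without smearing correction, by construction of the
  evaluation contract.
- Moran's I defaults: row-standardized inverse-distance weights among site
  centroids on per-site mean residuals, 999 permutations with recorded
  seed, two-sided permutation p around the null expectation −1/(n−1).
- WHO-threshold population shares use strict ">" (switchable).
- Annual surfaces weight seasonal means by campaign week counts (35/17),
  i.e. the mean of weekly values, not the mean of two seasonal means.
- Quintile 1 is the poorest; quintiles are rank-based with stable ea_id
  tie-breaking.
- Zero-variance candidate columns (e.g. an amenity count that is zero in
  every 50 m buffer) are pruned before standardization;
  `standardize_columns` itself raises on a degenerate column it is asked to
  scale.
- Serialized interchange formats are plain text: GeoJSON for vector layers,
  ESRI ASCII grids for rasters, CSV for tables, JSON for models and traces.

## Known limitations

- The normal-reference Wald p-values ignore variance-component uncertainty;
  for the small harmattan subsets (≈ 125 rows, 26 sites) they are mildly
  anti-conservative.
- Forward selection with a no-removal rule is order-dependent by design;
  the re-inclusion pass mitigates but does not eliminate path dependence.
- The cell-centre EA aggregation biases means for EAs far smaller than one
  grid cell (the single-cell fallback makes the value exact only when the
  EA sits inside one cell).
- Moran's I values depend on the (unstandardised in the field) weight
  specification; only the oracle identity, sign behaviour and permutation
  calibration are asserted.
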