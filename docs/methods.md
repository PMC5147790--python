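# Methods

This package reconstructs settlement-era forest structure and composition
from Public Land Survey (PLSS) witness-tree records and compares it against
modern fixed-radius inventory (FIA-style) data, at desk scale, on synthetic
inputs whose truth is known. This note records the models, the defaults and
why, the numerical choices, and what the synthetic generators do and do not
emulate.

## Stem density: the Morisita two-tree estimator

At each survey corner the two closest bearing trees give distances r1, r2
(m). The per-point plotless estimate is

    λ_M = 2 / (π (r1² + r2²))        [stems m⁻²]

For a homogeneous Poisson process of intensity λ sampled *point-halves*
(nearest tree in each 180° semicircle), the squared nearest-tree distance in
a sector of angle 2π/k is exponential with rate λπ/k; the sum of the two
squares is Gamma(2, rate λπ/2), whose inverse has mean λπ/2, so E[λ_M] = λ
exactly. The same argument gives E = λ for the k-sector form
k(k−1)/(π Σr²) with one tree per equal sector, and E = λ/2 for the
*interior-half* design (both quadrants on one side of the travel line,
rate λπ/4 each) — the analytic basis of the κ = 2 design constant. These
identities are what the calibration tests and the acceptance script verify
by simulation.

The per-point estimator is heavy-tailed: 1/Gamma(2) has a log-divergent
second moment, so occasional corners with two very close trees dominate
naive means. Three mechanisms in the pipeline address this, all mirroring
how the historical records and their cleaning actually behave: distances
are recorded in whole links (a tree inside half a link records distance 0
and is screened by the zero-distance rule), corners with multiple large
trees at exactly 1 link are screened as transcription-suspect, and gridded
summaries report trimmed variants (below).

## Surveyor-bias corrections

Corrected density is the product λ_corr = κ·θ·ζ·φ·λ_M, with factors
estimated separately per stratum (design, year band, internal/external
line, section/quarter-section corner, region — any columns on the points
table) and reported to 3 decimals; products use full precision. Strata with
fewer than `min_points` (default 100) corners inherit the pooled factors
with a `fallback` flag.

* **κ (design constant).** point_quarter and point_halves 1, two nearest
  quadrants 0.857, interior half 2. The 0.857 value is the standard
  empirical constant for that geometry and is taken as given, not
  re-derived; the κ = 1 and κ = 2 cases are verified by simulation.
* **θ (sector bias) = 180 / effective sector span.** The span is estimated
  from the empirical *pair angles* (angle between the two bearings at a
  corner) by minimum Cramér–von Mises distance over a 90–360° integer grid
  of candidate spans. The generative model: each tree's bearing is uniform
  on a span-s sector centered on its own semicircle midline. At s = 180
  this reproduces the exact point-halves pair-angle law f(a) = a/16200 on
  [0, 180]; wider/narrower spans shift mass away from/toward 180°. A
  zero-spread (degenerate) pair-angle sample pins to the grid's lower bound
  and is flagged rather than fitted. Note the corner validity rule "two
  trees in different quadrants" censors small pair angles in *kept* data;
  span estimates from heavily widened designs are therefore conservative
  (biased toward 180). The analytic θ values for given spans
  (180/253 = 0.71, 180/141 = 1.28 at full precision) do not depend on the
  fit.
* **ζ (azimuthal censoring) = p/α**, the proportion of trees in the allowed
  region over the fraction of the circle it occupies, floored at 1. With
  complete elimination of ±w around each cardinal, ζ = 360/(360 − 8w):
  72° total censored gives 1.25, 10° gives 1.03. The censored halfwidth is
  estimated from recorded compass azimuths as the smallest observed angular
  gap to any cardinal — the uniform-support MLE under the
  complete-elimination model. Uncensored data give w ≈ 0 and ζ ≈ 1;
  *partial* avoidance (surveyors sometimes taking cardinal-adjacent trees)
  reads as no censoring, a deliberate conservative choice.
* **φ (diameter limit)** is the fraction of recorded trees at or above
  8 in (20.32 cm). Corrected densities refer to trees ≥ that limit. Values
  outside the empirically typical 0.6–0.95 are flagged, not rejected. φ
  multiplies density only; the two recorded trees are *not* re-filtered
  when computing basal area and biomass.

Corners with one tree and one "No Tree" record contribute density 0 by
default (`mixed_policy="zero"`), consistent with treating open vegetation
as zero-density; `"exclude"` drops them instead. Water corners never enter
density averages.

## Basal area and biomass

Tree biomass is m = exp(β0 + β1 ln dbh) (dbh cm, m kg) using eight
national species-group coefficient pairs; the genus→group table ships as
`data/allometry.csv`. All maples go to the generic Mixed Hardwood group
because the survey taxa are genus-level while separate soft/hard maple
curves exist. Four taxa not named in the coefficient table's membership
lists (Locust, Sycamore, Chestnut, Tupelo) are assigned to Mixed Hardwood
as generic hardwoods. Per corner, the mean stem basal area π(dbh/200)²
(m²) or mean tree biomass over the two records — sentinels contributing 0
to the mean, not dropped from the denominator — is multiplied by point
density and unit-converted to m² ha⁻¹ / Mg ha⁻¹.

## Gridding

Points bin into 64 km² (8 × 8 km) cells with half-open intervals from a
configurable origin. Cell composition is computed on two bases: stem
counts and summed basal area (the analog analysis uses the basal-area
basis). Structural summaries come in a *full* and a *reported* variant;
the reported variant excludes points above the global 97.5th percentile of
point density, because plotless point estimates are heavy-tailed near-tree
artifacts. Trimming is global across points, not per cell (per-cell is
available behind a flag). Cover classes: prairie < 0.5, savanna 0.5–47
(inclusive upper bound), forest > 47 stems ha⁻¹.

Inventory plots expand to per-hectare values over their sampled area of
four 7.2 m radius subplots (4π·7.2² ≈ 651 m²; a single qualifying tree is
15.35 stems ha⁻¹), counting live trees above the 20.32 cm limit; cell
values are plot means. The density:biomass ratio is reported as density
over biomass (high = dense small-stem stands) with the orientation stated
in the column name and zero-biomass cells flagged rather than dropped.

## Analog analysis and novelty

Bray–Curtis dissimilarity d = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on proportional
composition. Minimum-dissimilarity matching is brute force over the full
matrix, ties broken to the lowest cell id; within-era matches exclude
self. Thresholds from within-era minima use linear-interpolation
percentiles (type-7): *novel* modern cells exceed the 95th percentile of
within-historical minima; *remnant* modern cells fall at or below the
25th; *lost* historical cells exceed the 95th percentile of within-modern
minima (the symmetric reading of the lost rule; the percentile is
configurable). Forest types come from k-medoids (PAM build + swap,
implemented here on the precomputed dissimilarity matrix) with k = 5 by
default, labeled by the medoid's taxa with share ≥ 10 % (up to four).

The novelty model is a binomial GLM of the novel flag on distance (km) to
the nearest remnant cell, fit per forest type; d50 = −intercept/slope is
reported only for positive slopes, and types with fewer than 20 cells or a
single class are flagged (an all-novel type is "saturated"). The
permutation null reshuffles the between-era minimum dissimilarities across
cells without replacement — preserving their multiset exactly — and
recomputes flags, distances and d50 per permutation (default n = 100),
reporting the null min/max and quartiles. Both the observed point estimate
and the null range are labeled as such; no single "min/max" convention is
claimed for the observed fit.

Transect β diversity is the mean Bray–Curtis between adjacent cells along
an ordered path; Δβ = mean(modern) − mean(historical) with a paired t-test
over shared pairs. Moran's I uses queen contiguity on the grid (rook and
other schemes configurable), row-standardized, with a one-sided
permutation p-value (999 shuffles, seeded).

## Synthetic generators

* **Stands** are marked point patterns: homogeneous Poisson or a Thomas
  cluster process (Poisson parents, Gaussian offspring, default parent
  intensity λ/40 and σ = 15 m) with the same expected intensity. Genus
  marks are i.i.d. from a mixedwood composition; dbh is lognormal with
  median 25 cm and log-sd 0.5, truncated at 2.5 cm so a realistic mass
  sits below the 8-inch limit and φ is exercised. The calibration
  condition used throughout is 200 stems ha⁻¹ on 4 km², surveyed at ≥3000
  corners.
* **The virtual surveyor** walks a rectangular corner grid placed ≥ 50 m
  inside the stand so nearest-tree searches never truncate at the edge
  (stands are generated with that buffer in mind). It realizes the four
  named designs, records whole links/inches, quadrant bearings, and
  emulates the three biases: sector widening/narrowing (each sector window
  rescaled by effective_sector/180), censor arcs around cardinals, and
  small-tree sub-sampling below the diameter limit. Travel-line
  orientation defaults to N–S and is configurable; a tree is recorded at
  most once per corner. Empty sectors record "No Tree".
* **Inventory plots** place the four-subplot cluster uniformly (or at
  user-supplied centers, validated against the extent) and record every
  tree above 12.7 cm within any subplot.
* **Paired landscapes** draw era-1 cells from k Dirichlet-centered
  archetypes in spatially coherent zones (concentration 75). A
  `remnant_fraction` (default 0.25) of cells, grown as patches around the
  zone centers, is identical in era 2. Other cells are perturbed toward a
  homogenized composition dominated by taxa absent from the archetypes
  (Poplar/Ash), with probability expit(b0 + slope·d) where d is distance
  to the nearest remnant and b0 is solved so the expected perturbed
  fraction equals `turnover`; unperturbed non-remnant cells receive a
  small Dirichlet drift (concentration 300) because real unchanged forests
  are not compositionally frozen — without drift every unperturbed cell is
  a perfect analog and distance-to-remnant degenerates to one cell step.
  turnover = 0 returns identical eras; turnover = 1 perturbs everything.

What the generators do *not* emulate: real geography and edaphic
gradients, temporal change in surveyor instructions within one survey,
transcription error beyond the screened patterns, species-level identity
below genus, FIA's forested-condition plot selection bias, and spatial
autocorrelation of dbh marks. Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated sampling
models, not fidelity of any particular historical map.

## Numerical choices and degenerate inputs

Seeds enter every stochastic component explicitly; identical seeds give
identical outputs. Percentiles are linear-interpolation throughout. The
sector-fit grid is 90–360° in 1° steps; censor-halfwidth search caps at
40°. ζ is floored at 1 and θ(180°) = 1 exactly. Empty batches yield
flagged NaNs (kept fraction, compositions) rather than exceptions where a
summary is still meaningful; truly undefined quantities (Bray–Curtis of
two zero vectors, Moran's I of constants, distance with no remnants)
reject or return flagged NaN. GLM separation is detected via non-finite
standard errors or runaway coefficients and flagged instead of reporting a
d50.

## Known limitations

* κ = 0.857 for the two-nearest-quadrants design is adopted as a constant;
  its exact value depends on the precise geometry convention and is not
  asserted as a simulation invariant.
* The sector-span estimator assumes the two-tree halves geometry; spans
  estimated from kept corners are compressed toward 180° by the
  different-quadrant validity rule.
* The within-era and between-era dissimilarities share one composition
  basis (relative basal area by default); stem-count composition is
  available for sensitivity checks.
* Interior-half calibration ratios computed from ~3000 corners carry a
  few-percent finite-sample skew because the per-point estimator's sample
  mean converges slowly (heavy tail); the tests bound this with
  Monte-Carlo standard errors rather than fixed tolerances.
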