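# Methods

## The model

`urbantol` treats urban tolerance as a species-level trait estimated from
effort-corrected, presence-only occurrence data. The observation unit is a
square grid cell (default 0.25 × 0.25 mile = 402.336 m) over an 11-year
study window (2011–2021). After spatiotemporal thinning (at most one
presence per species × cell × year), a species' data in a cell is a
binomial draw:

    k_i ~ Binomial(E_i, p_i),   logit(p_i) = α + β · PC1_i

where `E_i` is the *detection-group effort* — the number of years in which
any retained species of the same higher-order group was recorded in cell
`i` — and `PC1_i` is the composite urban intensity. The slope β is the
Urban Association Index (UAI). The key identifying assumptions are:

* **Detection-group substitutability.** A record of one group member
  indexes search effort for all members (a birder's sparrow record speaks
  to the non-detection of other birds, not of spiders). Groups are chosen,
  and species excluded, by expert curation flags supplied as an input
  table; the package applies the flags but does not attempt to replicate
  the expert judgment.
* **Exchangeable years.** Presence is treated as independent across years
  given the cell's urban intensity; there is no occupancy persistence or
  trend term. The synthetic generator makes the same assumption, redrawing
  presence each year.
* **Logit-linearity in a single covariate.** No spatial autocorrelation
  terms, additional covariates, or trait effects.

The Community Urban Tolerance Index (CUTI) for a cell and group is the
k-weighted mean UAI of the group's scored species detected there (weights
1–11 presence-years), rebinned to a reversed 5-point scale with left-closed
interior intervals:

    (-inf,-0.5)→5  [-0.5,-0.25)→4  [-0.25,0)→3  [0,0.25)→2  [0.25,0.5)→1  [0.5,inf)→0

Published descriptions of the scale use "a to b" interval notation that is
silent about exact breakpoints; this package fixes the left-closed
convention above (a raw score of exactly −0.5 bins to 4). All worked
examples and acceptance probes sit away from breakpoints, so the choice is
documentation, not tuning.

## Pipeline order and its rationale

quality → geoprivacy → subspecies reclassification → curation.

* The per-species obscured share is computed over the species' records
  *after* the quality filter but *before* any obscured record is removed —
  computing it afterwards would always give 0. The threshold is strict:
  exactly 60% obscured survives, more than 60% removes the species wholly.
* Subspecies are lifted to species before curation so flags attach at
  species rank.
* Effort grids are built from post-filter records only: species removed by
  geoprivacy or curation do not mark effort. Whether excluded species
  should still mark effort is genuinely open; post-filter was chosen
  because effort is defined over "retained species of the group", and the
  synthetic recovery tests confirm the estimator is calibrated under this
  definition.
* Region containment is boundary-inclusive, on point coordinates.
* A species' own records count toward its group's effort (self-effort is
  not excluded).

## Urban intensity

Layers aligned to the analysis grid (mean-aggregation for finer sources,
nearest/bilinear sampling otherwise) are z-scored per layer (population
sd, ddof = 0) before PCA, i.e. the decomposition is of the correlation
matrix. The inputs carry incommensurate units (radiance, percent, dB), so
covariance PCA would let an arbitrary unit choice dominate the axis.
Complete-case cells only; cells missing any layer carry NaN scores and are
excluded downstream rather than imputed. PC1 is oriented to correlate
non-negatively with a configurable reference layer (default: the
impervious-surface slot), making "larger = more urban" a convention, and a
retention check warns — deliberately does not fail — when PC1 explains
≤ 70% of total variance. Implementation is an SVD of the standardized
stack; the test suite verifies it against an explicit
correlation-eigendecomposition oracle at 1e-8.

## UAI fitting

Maximum likelihood via iteratively reweighted least squares (binomial GLM,
logit link, statsmodels), no regularization. A fit is attempted only when
the species' summed thinned occurrences Σk ≥ 25 (strict; Σk = 24 is
`insufficient_data`). Complete separation (all k = 0 or all k = E),
non-convergence, or |β̂| > 20 yields status `degenerate`; such species are
excluded from CUTI with no imputation (no Firth correction — degenerate
fits are reported, not repaired). Cells with missing PC1 are dropped from
the fit with a count kept.

## CUTI aggregation

Binning happens per cell per group *before* any averaging; composite
per-cell scores and citywide summaries are means of integer bins (which is
why citywide binned values are non-integer). Two citywide composite
averaging paths are provided because the choice is genuinely ambiguous:
`group-first` (default — each group's citywide mean gets one vote,
optionally cell-count-weighted) and `cell-first` (mean over the per-cell
composite grid). The ANOVA factor is the per-cell composite binned score
rounded to the nearest integer; levels with fewer than two cells are
excluded, and at least two usable levels are required. The one-way ANOVA
is computed from explicit sums of squares so degenerate designs have
defined behavior: identical responses give F = 0, zero within-group
variance with non-zero between-group variance flags F = ∞. Tukey HSD uses
statsmodels' studentized-range implementation.

## Synthetic study system

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as a realistic desk-scale study:

* **Grid**: 60 × 60 quarter-mile cells (≈ 24 × 24 km), nominally centered
  on an urban core; 3 detection groups × 30 species; 11 years.
* **Environment**: three layers sharing a latent urbanness surface (dense
  core, smooth texture) with pairwise correlation ≈ 0.85 — comparable to
  real co-registered urbanization proxies, whose PC1 typically explains
  80–90% of variance.
* **True slopes**: uniform on (−2.93, 0.62), the span observed across a
  real multi-taxon urban gradient; intercepts uniform on (−2.5, −0.5) so
  typical per-cell-year occurrence probabilities fall in the 7–40% range.
* **Observer process**: events per cell-year ~ Poisson with mean from a
  group-specific effort surface (default mean 1.5 events/cell-year,
  log-linear association with urban intensity, weight 0.5); each event
  detects each present species independently with per-species
  detectability uniform on (0.2, 0.6); 95% of records are research-grade.
  The Poisson choice is the simplest law consistent with
  "years-with-at-least-one-record" effort semantics; the analysis never
  models the observer process, only corrects for it.
* **Filter victims**: deterministic minimum counts per group of
  heavily-obscured (obscured fraction 0.65–0.95), non-native,
  non-terrestrial, non-proxy and otherwise-excluded species, plus
  subspecies aliases, so every filtering rule is exercised.
* **Geoprivacy**: obscured records are flagged but their coordinates are
  *not* offset by default (they are dropped downstream regardless); a
  coordinate-offset option up to 22 km exists for studying the filter
  itself. Duplicate same-day records per observer are allowed — thinning
  removes them regardless.

What the generator does **not** emulate: observer identity and site
fidelity, weekend/seasonal pulses, taxonomic misidentification, spatial
autocorrelation of occupancy beyond what urban intensity induces, and
abundance-driven detectability. Passing recovery tests therefore shows the
estimator is correct *under the model's own assumptions*, not that those
assumptions hold for any particular real dataset.

## Numerical and interface choices

* Coordinates: records are WGS84 lon/lat; the grid lives in a local
  equirectangular projection (exact affine, standard parallel at the grid
  center). This is adequate at city-to-region extents; no general CRS
  reprojection is provided, so multi-source rasters must be co-registered
  upstream.
* Rasters: text ESRI ASCII grids with a JSON CRS sidecar; optional GeoTIFF
  export (ModelPixelScale/Tiepoint tags).
* Cell membership: half-open intervals, south/west edges inclusive; row 0
  is the southern row.
* Problem sizes in the validation suite — a 60×60 full-pipeline run, and
  200 replicate species × 1000 cells for slope recovery and 95% Wald
  coverage — were chosen as the smallest sizes at which recovery asymptotics
  are expected to be visibly clean (hundreds of occupied cells per scored
  species), keeping the suite fast enough to run routinely.

## Known limitations

* Wald intervals can undercover for extreme slopes with few occupied
  cells; the package reports `se_beta` and leaves interval construction
  choices to the user.
* The detection-group effort correction handles *relative* effort across
  space but cannot correct a group that is systematically unobserved in a
  habitat type (no records → no trials → cell silently uninformative).
* CUTI inherits UAI estimation noise; cells with one low-k species swing
  whole bins. `n_species` per cell is reported so users can mask thin
  cells.
* The ANOVA treats cells as independent; spatial autocorrelation makes its
  p-values anticonservative on real data, so they are best read as
  descriptive strength-of-gradient summaries.
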