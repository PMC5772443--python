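# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the known limits of what the test suite demonstrates.

## Grid and geometry conventions

All coordinates are WGS84 decimal degrees. Every distance in the package —
IDW neighbourhoods, KDE bandwidths, hull buffers — is **Euclidean in degree
space**; there is no great-circle correction, and 300 km is treated as
equivalent to 3°. Near the equator (the intended study latitudes) the
distortion is a few percent; the package should not be used at high
latitudes without revisiting this convention. Cells are half-open intervals
`[west, west+h) × [south, south+h)` with a lower-left origin and rows
increasing northward; a point on a cell edge belongs to the cell north/east
of it. Grid registration is configuration, never inferred from data.
Rasters are exchanged as ESRI ASCII grids (nodata −9999); reading flips the
file's north-up row order into the in-memory south-up orientation.

## Occurrence cleaning

Step 1 applies deterministic rules in a fixed precedence order (each removed
record gets exactly one reason code): missing longitude, latitude *or
locality text* → latitude exactly equal to longitude (nonzero) → both
coordinates exactly zero → within a snap tolerance of a gazetteer capital or
province centroid → outside the stated country polygon (only when polygons
are supplied). Survivors are deduplicated to one record per (species,
0.5°-cell), keeping the lowest record id. Notes on edge cases: (0, lat≠0)
is a legitimate meridian point and is kept; missing locality removes a
record even when its coordinates are valid, because free-text locality is
the only cross-check against transcription errors.

Step 2 ranks each record by a fixed-bandwidth isotropic Gaussian
kernel-density estimate of the point pattern (sum over all records
including self) and removes records below an empirical quantile of the
per-record densities. The kernel shape is an assumption (nothing in the
procedure pins it down); Gaussian is the default choice. Parameters:

| parameter | default | units | rationale |
|---|---|---|---|
| bandwidth | 1.0 | degrees | ~2 grid cells; small enough to keep regional clusters distinct, large enough that single-cell gaps do not isolate records |
| quantile (narrow species, ≤ 3 regions) | 0.05 | — | restricted ranges tolerate aggressive trimming |
| quantile (wide species, > 3 regions) | 0.01 | — | widely distributed species must not lose whole peripheral clusters |
| gazetteer snap tolerance | 0.05 | degrees | sub-cell radius typical of centroid-assignment artefacts |

The quantile is chosen per species from the number of the six regions
holding at least one record. The filter is applied per species (densities
are computed within a species' own point pattern, never pooled).

## IDW abundance model

`RA = n_i/N` per plot; a cell's estimate is the `w_k = d_k^(−p)`-weighted
mean of the nearest `k_max = 150` plots within `d_max = 3°`, `p = 0.5`
(reciprocal square root of distance — the weights must *decay* with
distance for the estimator to be an interpolation). No neighbour within 3°
predicts absence: in a purely spatial model the range is limited by
dispersal, not climate. Plots closer than 1e-9° to the query point
short-circuit to the mean RA of those coincident plots, making the
interpolator exact at the data. Neighbour counting is over plot records,
not cells: several plots in one cell each contribute. The weighted mean is
normalized by Σw (standard IDW). Binary maps use the strict rule RA > 0,
then exclude naturally non-forested cells.

## MaxEnt (linear + quadratic)

The feature class is deliberately minimal: each climate variable and its
square, min–max scaled over the background sample, with the same affine map
applied to presences (which may therefore leave [0,1]). Variables constant
on the background are dropped. Product, threshold and hinge features are
out of scope by design — with a handful of climate variables the
linear+quadratic class already represents any Gaussian-type response
(log-quadratic in the variable) and keeps the model desk-tractable and
interpretable.

The fit maximizes the L1-penalized presence log-likelihood over the
background Gibbs distribution. The penalty schedule is a single global
multiplier: `β_j = c·s_j/√m` with `s_j` the presence standard deviation of
feature `j`, `m` the presence count, `c = 1` by default. This replaces the
reference program's per-feature-class interpolation tables with one
well-posed, documented knob. The optimizer works on the split
`λ = u − v, u, v ≥ 0`, which turns the nonsmooth L1 objective into a smooth
box-constrained concave problem solved by L-BFGS-B (ftol 1e-7, 500
iterations); the objective trace is recorded and is non-decreasing. With
`c = 0` the fitted distribution satisfies the feature-expectation
constraints `E_q[f_j] =` presence mean exactly (to optimizer tolerance);
as `c → ∞` it collapses to the uniform distribution with entropy log|B|.

Background cells are drawn uniformly without replacement from the
survey-effort (bias) layer — cells holding at least one collection of any
species — 10,000 by default or all of them if fewer. Presences are
deduplicated to cells before fitting (min 5 cells). The logistic output
uses prevalence 0.5: `l(x) = e^H q̃(x)/(1 + e^H q̃(x))`, computed in log
space to avoid overflow far outside the training range. It is strictly
monotone in `q`, so every rank-based statistic is identical between raw and
logistic outputs. The model is fitted on the configured study grid (not a
continental crop); suitability is interpreted only within that grid.

## Range maps

Extent of occurrence = convex hull of the cleaned records in degree space,
buffered by 3° (shapely; degenerate hulls — single points, collinear sets —
buffer naturally to disks/stadiums). The suitability map is binarized at
the 10% training-presence threshold (the largest value `t` with ≥ 90% of
training presences scoring ≥ `t`; prediction is `l ≥ t`) and clipped by the
cell-center-in-polygon test. Area of occupancy is the surviving 1-cell
count. Sensitivity is cell-level: the fraction of cells containing ≥ 1
reference point that the map predicts present; duplicated points in a cell
count once. Thresholds based on specificity are deliberately avoided — the
data contain no absences.

## Validation statistics

*Null-model test.* 99 replicates each fit the identical model configuration
and background to `n` pseudo-presence cells drawn without replacement from
the bias-positive cells (`n` = the species' unique presence cells). The
observed training AUC is ranked among the 100 values, ties taking the
lowest position (equalling a null never helps); significance requires rank
≥ 95. Sampling nulls from surveyed cells rather than the whole grid makes
the test ask "better than random *collecting*?", which is the relevant null
under spatial survey bias; a flag restores whole-grid nulls for comparison.

*GLM.* Binomial logit of the per-cell collection indicator on interpolated
RA over all valid forested cells; two-sided Wald p. Complete separation and
constant predictors are flagged rather than reported as clean fits.

*Spearman / quantile regression.* Each plot is one observation even when
plots share a cell. The response is the plot's **observed** RA (`n_i/N`)
by default: at plot localities an exact-interpolating IDW returns the
plot's own RA anyway, so the observed value is the cleaner reading; a
switch substitutes the IDW value at the plot's cell. The τ = 0.9 quantile
regression is solved **exactly** as a linear program (HiGHS) — the optimum
is a vertex, i.e. a line through two sample points — rather than by
iterative reweighting; the test suite cross-checks the slope against
statsmodels' QuantReg and the check-loss against a pair-enumeration oracle.
The slope's CI and p-value come from a nonparametric pairs bootstrap
(n = 200, percentile interval, sign-based two-sided p); this replaces the
Markov-chain marginal bootstrap, preserving the contract (a slope CI)
without a specialized sampler.

*Collinearity screen.* Pairwise Spearman over valid cells; greedy
elimination of the variable with the most |rho| > 0.7 partners (ties →
larger mean |rho|) until all retained pairs comply. PCA loadings of all
variables are reported as decision support only — the biological-relevance
choice is manual and out of scope.

## Synthetic study system

The generator emulates the *structure* of a basin-wide tree-species study:
six smooth climate fields in [0,1] (two pairs built collinear, |rho| > 0.7,
so the screen has real work), a 3×2 block partition into six regions, a
forest mask with ~8% non-forested blobs, species with Gaussian niches on
1–2 variables times dispersal kernels around population centers (every
third species narrow: one center, tight kernel, envelope shrunk until it
spans ≤ 3 regions), plot censuses as multinomial draws of ~550 stems from
the local true RAs (residual mass = "other species"), and collection
records with intensity ∝ accessibility × RA^γ, γ = 0.5 — collectors
over-represent areas of low abundance, reproducing the weak
collection–abundance relationship that motivates the contrast. Error
injection (rates: 10% missing coordinates, 15% duplicates, 4% capital and
4% centroid snaps, 2% zero coordinates, 2% lat=lon, 3% misidentifications)
labels every corrupted record. Two design constraints make the cleaning
rules exactly scoreable: clean records of a species occupy distinct cells,
and gazetteer points sit near cell corners while records are jittered into
the central half of their cell, so a 0.05° snap can never catch a genuine
record. Everything derives deterministically from the seed.

What the generator does **not** emulate: realistic floristic composition,
taxonomy or name resolution, temporally explicit collecting, spatially
autocorrelated misidentification, non-climate drivers (soil, hydrology),
or the true shape of Amazonia. Passing tests therefore demonstrate the
*mechanics* of the pipeline — exact rules, calibrated tests, recoverable
ground truth under the stated generative assumptions — not performance on
real collections data.

## Problem sizes and reproducibility

The packaged demo study is a 60×60 grid (≈ Amazonia at 0.5°), 15 species,
400 plots, ~120 records per species; the full workflow on it runs in about
half a minute on one core, and the acceptance script uses exactly this
configuration. Statistical calibration checks use 100 replicates of reduced
instances (600-cell feature spaces, 150-cell backgrounds, 99 nulls). All
randomness flows from numpy `SeedSequence`s spawned from a single seed;
identically seeded runs write byte-identical CSV/JSON/raster outputs (PNG
figures embed library metadata and are excluded from that guarantee).

## Known limitations

- Degree-space distances bias high-latitude applications (see above).
- The KDE bandwidth and quantile defaults are assumptions; sensitivity to
  the bandwidth (±50%) mainly shifts how aggressively sparse regional
  clusters are trimmed for narrow species.
- The null-model test refits the same background for every replicate; with
  very small backgrounds its type-I error runs slightly below nominal
  (conservative).
- The L1 path is not followed per feature class; a single regularization
  multiplier is a simplification, and heavily correlated features share
  weight arbitrarily (the collinearity screen mitigates this upstream).
- Cohort summaries on synthetic data are qualitatively, not numerically,
  comparable to any real-data study: effect sizes depend on the generator's
  niche strength and bias settings.
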