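# sdmcontrast

Tools for contrasting two routes to a tree species' geographic range on a
common 0.5-degree grid:

1. a **presence-only species distribution model** — a minimal MaxEnt (Gibbs /
   maximum-entropy) model fitted to cleaned natural-history-collection
   records with linear + quadratic climate features and a survey-effort
   ("target-group") background; and
2. a **plot-based abundance map** — inverse-distance-weighted (IDW)
   interpolation of relative abundances observed in forest inventory plots.

Collection records are noisy: missing or zeroed coordinates, coordinates
snapped to capitals or province centroids, within-cell duplicates, and
misidentified specimens far outside a species' true range. The package ships
the two-step cleaning pipeline that deals with them (deterministic
geo-validation + grid-cell deduplication, then kernel-density spatial-outlier
removal), the statistics used to compare the two kinds of maps, and a fully
synthetic study system with known ground truth so that every stage can be
validated end to end. It is aimed at spatial ecologists and methodologists
who want a transparent, desk-scale implementation of this model contrast
rather than a black-box SDM run.

## The models

**MaxEnt (linear + quadratic features).** Over a background set of cells
`B`, the model is the Gibbs distribution

    q(x) = exp(λ·f(x)) / Z,   Z = Σ_{x∈B} exp(λ·f(x))

where `f(x)` stacks each climate variable and its square, min–max scaled on
the background. λ maximizes the L1-penalized presence log-likelihood

    (1/m) Σ_presences λ·f(x) − log Z − Σ_j β_j |λ_j|,   β_j = c·s_j/√m.

Suitability is reported through the logistic transform
`l(x) = e^H q̃(x) / (1 + e^H q̃(x))` with `H` the entropy of `q`. Binary
range maps use the 10% training-presence threshold, clipped to the convex
hull of the cleaned records buffered by 3°; the surviving cell count is the
predicted area of occupancy. Model significance is assessed against 99
bias-corrected null models (pseudo-presences drawn from surveyed cells): the
observed training AUC must rank ≥ 95 among the 100.

**IDW abundance.** Each plot contributes `RA = n_i / N` (stems of the focal
species over all stems). A cell's value is the weighted mean of the nearest
150 plots within 3°, with weights `w_k = d_k^(−1/2)`; no plot within 3°
means predicted absence. Cells with interpolated `RA > 0` form the binary
range map after removing naturally non-forested cells.

**Comparison statistics.** A binomial GLM of the per-cell collection
indicator on interpolated RA (does abundance raise the chance of being
collected?), Spearman's rho and a linear 90th-percentile quantile regression
between suitability and plot RA at plot localities (slope CI by pairs
bootstrap), sensitivities of each map against the other data source, and
areas of occupancy.

## Worked example

```python
import sdmcontrast as sc
from sdmcontrast.grid import GridSpec

cfg = sc.SyntheticConfig(grid=GridSpec(-80, -20, 0.5, 30, 30),
                         n_species=5, n_plots=150,
                         records_per_species=60, seed=2)
world = sc.generate_world(cfg)
study = sc.Study.from_world(world)
settings = sc.PipelineSettings(seed=3, n_background=800, n_null=99)
rows, results = sc.run_all(study, settings)
print(rows[["species", "n_records_raw", "n_cleaned", "auc", "null_rank",
            "rho", "q_slope", "aoo_maxent", "aoo_idw", "gate"]].round(3))
```

prints

```
  species  n_records_raw  n_cleaned   auc  null_rank   rho  q_slope  aoo_maxent  aoo_idw                       gate
species00             60         32 0.808        100 0.753    0.061       203.0      329
species01             60         28 0.665        100 0.843    0.149       566.0      827
species02             60         31 0.697        100 0.537    0.105       497.0      828
species03             22         13 0.923        100 0.237   -0.000        67.0      158
species04             59         29 0.570         66   NaN      NaN         NaN      828 null model not significant
```

Reading the row for `species00`: 60 raw records shrink to 32 after cleaning
(the generator injected missing/zero/duplicated/misassigned coordinates);
the fitted suitability model separates presences from the survey-effort
background with training AUC 0.81 and beats all 99 null models (rank 100);
suitability and plot relative abundance correlate at rho 0.75; and the
clipped MaxEnt range (203 cells) is smaller than the IDW range (329 cells).
`species04` is excluded from the comparison because its model does not beat
the bias-corrected null (rank 66 < 95) — the same gate the workflow applies
to any species whose records carry no climate signal. `sc.summarize(rows)`
aggregates the cohort (mean rho 0.59, all five GLM slopes significantly
positive, ~48% of records removed).

The same workflow is scriptable from the shell:

```sh
sdmcontrast synth --out world/ --seed 7
sdmcontrast run --input world/ --out results/ --seed 7
```

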