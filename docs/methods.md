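# Methods

This note documents the models, the synthetic world the tests run in, the
numerical choices, and the limits of what a green test establishes.

## Spatial data model

A raster is a 2-D value grid with a boolean nodata mask, a north-west origin
(west edge `origin_x`, north edge `origin_y`, WGS84 degrees treated as
planar), and a square cell size. Cell `(r, c)` covers the half-open box
`[x0 + c·cs, x0 + (c+1)·cs) × (y0 − (r+1)·cs, y0 − r·cs]`: a point on a
shared vertical edge belongs to the cell to its east, a point on a shared
horizontal edge to the cell below it, and the east/south outer edges are
outside the grid. This makes point-to-cell assignment a partition — no point
is counted twice or dropped.

Planar treatment of lon/lat is deliberate: the intended scale is ~1-km cells
over a single administrative division, where meridian convergence distorts
distances by well under the cell size. Reprojection is out of scope.

ESRI ASCII grids are read and written natively (header keys case-insensitive,
lower-left-corner header converted to the north-west origin). The writer
emits 17 significant digits so finite values round-trip bit-exactly, and
switches to a sentinel below the data minimum if any value collides with the
default −9999. Single-band GeoTIFF reading parses the
ModelPixelScale/ModelTiepoint tags via `tifffile`; GeoTIFF writing and CRS
transformation are not supported.

Nearest-neighbour resampling assigns each target cell the value of the
source cell with the nearest centre; exact distance ties break toward the
smaller row, then smaller column index. Target centres outside the source
extent become nodata. Categorical layers (land use, forest class) pass
through the same nearest rule — at coarse targets this picks one source
pixel rather than a majority class, which changes categorical composition;
it is kept because it is the conventional resampler for categorical data and
the documented behaviour of the surrounding toolchain.

## Predictor preparation

Layers are standardized to mean 0 / sample sd 1 (n−1 denominator) over valid
cells; the means/sds are retained and re-applied to scenario stacks so that
regression coefficients fitted on the training period transfer to projected
futures. Constant layers are rejected by name.

Collinearity pruning removes layers until no retained pair has |Pearson r| >
0.9 (pairwise-complete cells, since masks differ per layer). "Which of the
pair to keep" is inherently a judgement call; it is surfaced as an explicit
priority list (earlier = more interesting) rather than hidden in iteration
order, making the result invariant to the stack's layer order. The default
priority prefers quarter-scale precipitation summaries over single-month
ones.

The PCA summary eigen-decomposes the inter-layer correlation matrix over
jointly valid cells; variance fractions are eigenvalue / layer count. Because
correlation is scale-free the summary is identical before and after
standardization (a tested invariant).

## Occurrence dataset

Background points are drawn uniformly over polygon ∩ valid-domain by
rejection sampling (default n = 1,000). Presence points are taken as given;
points falling outside the extent or in nodata cells are excluded and
counted, not imputed. The 80/20 train/test split is stratified by label
(train size floored per class) so both classes appear in the test set even
at small n; stratification is a config knob because the original design does
not state it. Background points may share cells with presences — no thinning
rule is applied.

## The five models

All five are implemented in this package (no model fitting is delegated),
because their tie-breaking, convergence and determinism are part of the
artifact's contract; `statsmodels`/`scikit-learn` serve as independent
cross-checks in the tests instead.

* **Envelope.** Fitted on presence rows only; score as in the README. With
  the `#(≤ x)/n` percentile the score at the exact median of an odd-sized
  training set is `1 − 1/n`, not 1 — the formula, not the folklore value, is
  the contract. An all-constant training layer scores 1 at the common value
  and 0 elsewhere.
* **Binomial GLM.** IRLS/Newton, convergence `max |Δβ| < 1e−8` or 50
  iterations; working weights floored at 1e−10; standard errors from the
  inverse Fisher information, two-sided normal Wald p-values. Slopes
  exceeding |30| on standardized inputs trigger a separation warning and a
  flag in the fit metadata (coefficients are still returned).
* **Gaussian GLM.** OLS of per-cell presence counts (the count in the cell
  containing each training point) with t-based p-values; exact rank
  deficiency raises, naming the collinear columns. Raw predictions are
  counts, so map predictions are min–max normalized to [0, 1] before
  ensembling — a documented convention, not part of the original design,
  which is silent on how a count-scale map enters a probability ensemble.
* **Random forest.** Each tree grows on a bootstrap sample to purity (or
  <2 samples, or no impurity-decreasing split); at each node `mtry` features
  are drawn without replacement; splits maximize Gini decrease over midpoint
  thresholds with ties broken toward the lower feature index then the lower
  threshold; the left child is grown before the right so RNG consumption —
  and therefore the whole forest — is a pure function of the seed. The score
  is the fraction of trees whose leaf votes presence (leaf mean ≥ 0.5).
  Default 500 trees; the demo and tests use fewer (25–100) purely for
  runtime, stated in their configs.
* **Maxent surrogate.** Ridge-penalized presence/background logistic
  regression (penalty λ = 1 by default, intercept unpenalized). λ = 0
  reduces exactly to the binomial GLM; λ → ∞ shrinks slopes to zero. True
  Maxent's feature classes and regularization schedule are deliberately out
  of scope; this surrogate is the standard transparent stand-in, and the
  deviation is intentional.

## Evaluation and consensus

AUC uses the midrank Mann–Whitney formula, which is algebraically identical
to exhaustive pair enumeration with ties counted half (the test suite checks
this equivalence against a brute-force oracle on random instances). The
correlation report is the point-biserial (Pearson) r between score and 0/1
label with a two-sided t test on n−2 df. Evaluation uses held-out test
points only.

Consensus weights are max(AUC − 0.5, 0), normalized — skill above chance —
falling back to equal weights (with a warning) if no model beats chance; the
scheme is switchable to plain equal weights. Cells where only some models
are valid average over the valid subset. The probability histogram uses ten
half-open bins `[k/10, (k+1)/10)` with the last bin closed, so counts sum to
the valid-cell count.

## Incidence machinery

Backward elimination refits after each single-term removal (the term with
the largest p-value above α = 0.05; name order breaks exact ties), never
drops the intercept, and records a replayable removal trace. The fit
statistic is adjusted R² for the Gaussian family and McFadden's pseudo-R²
for the binomial family.

The published equation this machinery mirrors is printed as a *linear*
combination of standardized predictors yet described as a logistic
regression with an adjusted R². Both readings are implemented;
`gaussian_identity` is the default because it is the family whose fit
statistic is an adjusted R², and its linear risk score is clamped to [0, 1]
before population scaling (the logistic family needs no clamp). Human
population enters the regression standardized, like every other predictor,
and the raw (unstandardized) population raster does the scaling. The
regional total is the sum of per-cell risk × population over valid cells —
the only aggregation consistent with reading the incidence map as "people at
risk per cell"; a threshold-based alternative ("population in cells with
risk > cutoff") is available in config. No uncertainty intervals are
attached to totals: the source design provides no variance model, and
inventing one was out of scope.

## Synthetic world

The generators state one world and the tests measure it; none of their
parameters were adjusted to outcomes.

* **Fields.** Gaussian white noise smoothed by an isotropic Gaussian kernel
  (length-scale in cells, wrap boundary), affinely rescaled to target
  mean/sd. Kernel smoothing was chosen over spectral synthesis for
  simplicity; it gives adequate, monotone control of autocorrelation but not
  a calibrated variogram. Pairs can be mixed to a target correlation
  (tested to ±0.02 at 10⁴ cells).
* **Occurrence.** Cell probability `expit(β₀ + βᵀx)`; presences sampled with
  replacement (several cases can share a locality, as in hospital data),
  placed uniformly within their cell. Coefficients in configs are stated on
  the standardized scale and converted internally. This is the package's
  central known-truth chain: the binomial GLM recovers β within 3 standard
  errors on ~5,000 cells, and on a strongly separable truth (low baseline
  prevalence, so presences concentrate in the rare high-suitability tail
  rather than a saturated plateau) the AUC-weighted ensemble exceeds 0.8 on
  held-out points.
* **Case table.** 4,371 records by default; two thirds male among sexed
  records; monthly weights putting 55% of cases in July–October, 33% in
  March–June, 12% in November–February; bite types at 12% cobra, 11% green
  pit viper, 3% krait, 10% other envenoming, 64% non-envenoming (the
  envenoming shares follow the register's reported yearly means; the
  non-envenoming remainder absorbs the rounding so the vector sums to 1);
  ages from a gamma(3, 9) distribution (mean 27 y, matching reported mean
  patient ages); years drawn from the register's 16 recording years.
  Field-wise missingness rates are set so the *expected* usable sub-dataset
  sizes equal the register's printed ones (3,972 with sex, 4,331 dated,
  3,958 geo-referenced, 4,268 with address); a generated table therefore
  matches those counts only within binomial sampling bounds, and the tests
  assert exactly that. What the generator does **not** emulate: real
  geography (districts are a 2×2 partition of the grid), spatio-temporal
  case clustering, age–sex interaction, or climate seasonality coupled to
  bite dates. A green test establishes that the pipeline's statistics
  recover the stated marginals — not that the world resembles south-eastern
  Bangladesh in any finer sense.

## Determinism and the pipeline

Every stage seed is derived from the master seed by hashing the stage name,
so stages are independent and reordering-insensitive. Stages communicate
through text artefacts (ASCII grids, CSV, JSON with sorted keys), and
`run_all` writes a manifest of SHA-256 checksums plus the config hash; two
runs under one config are byte-identical, which is both a test and the
intended audit mechanism. The demo world uses a 60×60 grid and 100 trees so
the full run takes seconds; scaling to real 1-km national rasters is a
memory/time question, not a correctness one, but has not been profiled.

## Known limitations

- No CRS handling beyond a label; inputs must already share WGS84 lon/lat.
- The Gaussian count GLM is trained on the presence/background point rows
  (count attached per point's cell), not on all cells; the alternative is a
  config switch but the original choice is not recoverable from the design.
- The envelope model is presence-only and ignores background entirely.
- Rejection sampling of background points assumes the polygon occupies a
  non-negligible fraction of its bounding box.
- The published equation's coefficients are consumed verbatim
  (`configs/eq1.yaml`); re-deriving them would require the original rasters
  and case geolocations, which are not redistributable.
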