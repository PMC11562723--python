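# Methods

This note records the models, conventions, and design choices behind
`pmwave`, and what the synthetic experiments do and do not demonstrate.

## Grid and resampling conventions

The modeling grid is planar and row-major: cell `(i, j)` of a `GridSpec`
spans `[origin + j·cs, origin + (j+1)·cs)` in x (and analogously in y, row 0
southernmost), with its center at the half-offset. No geodesy is modeled;
coordinates are kilometres. Point-to-cell assignment minimizes distance to
cell centers, with exact ties resolved to the lexicographically smaller
`(row, col)` so results are deterministic.

Three resampling paths move data onto the grid:

* **Nearest-pixel assignment** (`assign_pixels_nearest`) maps each coarse
  satellite AOD pixel to the single nearest fine cell (averaging collisions);
  unclaimed cells stay missing and are exactly the cells that gap-filling
  later predicts. This avoids duplicating one pixel into many cells.
* **Bilinear regridding** (`regrid_bilinear`) uses the tensor-product form
  on the enclosing 2×2 stencil of coarse cell centers. It is exact on fields
  `a + b·w + c·v + d·w·v` and, being a convex combination, cannot produce
  values outside the stencil range. Fine cells beyond the outermost coarse
  *centers* (a half-coarse-cell rim) are clamped onto the outermost stencil,
  i.e. they extrapolate linearly; this preserves affine exactness across the
  whole target grid at the price of the convexity property on the rim only.
* **IDW downscaling** (`idw_downscale`) averages the k nearest non-missing
  source centers with weights `d^(−p)`; defaults `p = 2, k = 4` are common
  practice and configurable. A target coinciding with a source returns the
  source value exactly (the `d = 0` rule).

Monitor records are merged per cell and hour: reference-grade (regulatory)
records take absolute precedence — any low-cost record sharing a cell with a
reference record is discarded — and duplicates within the surviving source
are averaged. The merged cell index serves as the monitor identity for
spatial cross-validation (two sensors in one cell are one effective
monitor).

## Wavelet machinery

Daubechies filters of order 1–10 are built by spectral factorization of the
Bezout polynomial, keeping the root of each reciprocal pair inside the unit
circle (minimum phase), and normalized to `Σh = √2`. The highpass is the
quadrature mirror `g[k] = (−1)^k h[L−1−k]`. This reproduces the standard
published coefficients to machine precision; order 1 reduces to Haar.

Decomposition is the Mallat pyramid: extend, correlate with the analysis
pair, downsample by two, recurse on the approximation. Two extension modes
are supported and both admit perfect reconstruction:

* `symmetric` (default): half-point reflection, `floor((n+L−1)/2)`
  coefficients per band. The common toolbox default; mildly redundant.
* `periodic`: periodic wrapping with odd-length padding, `ceil(n/2)`
  coefficients. This is the orthonormal variant: coefficient energy equals
  signal energy (Parseval) exactly for even lengths at every level.

The additive multiresolution components are obtained by zeroing all other
bands and inverting the pyramid; additivity (`l_J + Σh_j = S`) then holds by
linearity of the synthesis bank, and is asserted to 1e-8 relative error in
the tests. The maximum level is `floor(log2(n/(L−1)))` — for the full
493,561-cell application grid with a length-10 filter this gives 15, which
is also why fields are decomposed as **1-D row-major flattened signals**
rather than with a 2-D transform: the reported maximum level pins down the
1-D reading. A consequence worth keeping in mind is that "low frequency"
means smoothness along the row-major scan; vertical neighbors are `n_cols`
samples apart, so l_J is much smoother in x than in y.

The default analysis level is J = 5 (configurable, validated against the
maximum); at level 5 the detail bands are smooth enough to represent
plume-scale structure while the approximation keeps the regional trend.

## Ensembles

Both stages use bagged regression trees (scikit-learn random forests)
behind one `ForestConfig`: 500 trees, 4 candidate split variables
(`m_try`), minimum leaf size 5 (the customary regression leaf size of the R
implementation this family of models is usually fitted with). Out-of-bag
predictions are assembled per row from the trees whose bootstrap excluded
that row; rows in-bag everywhere report NaN and are excluded from metrics.

Variable importance for pruning is **permutation importance measured on OOB
rows**: each column is shuffled once, OOB predictions recomputed tree by
tree, and the increase in OOB MSE (floored at zero) normalized to sum to
one. This avoids the optimism of in-bag permutation. Impurity importances
are also exposed (they are cheap and adequate for a summary table).
`prune_by_importance` drops components below a normalized threshold
(default ε = 0.005), never drops the best feature, and rejects a threshold
that no feature clears.

The default predictor set (20 columns) is: all six AOD components
(`l_5, h_1..h_5`); `l_5` only for longwave flux, u-wind, surface pressure,
boundary-layer height and specific humidity; `h_1, h_3, l_5` for upward
shortwave flux; raw values for 2 m temperature, v-wind, downward shortwave
flux and relative humidity; plus the planar cell-center coordinates.
Upward and downward shortwave flux are carried as distinct fields so the
specification can address either. Ground PM2.5 never appears as a
predictor.

## Oversampling the high-concentration tail

Rows with target ≥ 35 µg/m³ (a standard short-term regulatory benchmark;
configurable) form the minority class. Synthetic rows are drawn uniformly on
the segment between a minority row and one of its five nearest minority
neighbors — jointly in predictors and target, so each synthetic row is a
convex combination of two real high-PM2.5 rows and synthetic targets can
never exceed the observed maximum. Neighbor search runs in z-scored
predictor space to avoid unit dominance. Synthesis continues until the
minority fraction reaches 0.2 (default). Crucially, oversampling happens
*inside* each cross-validation training fold, never before splitting, and
synthetic rows are excluded from every metric (OOB and CV) — both guards
are asserted at run time.

## Validation

R² is the coefficient of determination `1 − SSres/SStot` (not squared
correlation) and is reported as undefined for constant observations. Pooled
CV metrics are computed over the concatenation of all test-fold
predictions, which makes pooled RMSE² the count-weighted mean of per-fold
MSEs (asserted numerically). Random CV partitions rows into near-equal
folds; spatial CV partitions monitors, so all rows of a held-out monitor
leave the training set together. Spatial *clustering* CV is deliberately
not implemented: with a strongly non-uniform monitor network, cluster folds
degenerate (some clusters have almost no data), so the leave-monitors-out
scheme is the supported probe of generalization to unmonitored places.

## The synthetic scene generator

The generator is the package's study-condition definition, not a fixture.
Per hour it produces, on one grid:

* ten meteorological fields: Gaussian-filtered white noise (kernel 8 cells)
  scaled to realistic ranges, with AR(1) hour-to-hour persistence (ρ = 0.8)
  and a crude diurnal cycle in solar-driven variables;
* a true AOD: smooth background + a few elongated Gaussian plumes that
  drift across hours + a small relative-humidity term (so meteorology is
  genuinely informative about AOD);
* a background-model AOD: the truth block-averaged 5× coarser, bilinearly
  regridded back, plus small smooth perturbations — correlated with the
  truth (r > 0.5 asserted) but wrong cell by cell, like a coarse reanalysis;
* cloud gaps: a smooth random field thresholded at the requested quantile,
  giving contiguous blobs whose realized fraction tracks the request;
* a PM2.5 truth `b0 + b_aod·A + b_temp·(T−288)/6 + b_mix·M + b_int·A·M + ε`,
  where `A` is the level-5 db5 approximation of the AOD field and
  `M = exp(−PBLH/1000 m)`. Because the truth is driven by the *smoothed*
  AOD, the wavelet `l_5` feature is informative by construction and the
  raw-vs-wavelet ablation has a known expected sign.

Default coefficients are `(5, 60, 1, 3, 3)`: variance is dominated by the
smooth AOD term, with temperature and boundary-layer mixing contributing
secondary structure — mirroring the empirical finding that the
low-frequency AOD component is the leading predictor of PM2.5. With these
coefficients the response is smooth enough that an ensemble trained on
~5,000 monitor rows recovers it to within a few percent of the noise
ceiling, which is what the recovery benchmark requires.

The generator reports `theoretical_r2 = Var(signal)/(Var(signal)+σ²)` on
the realized scene; `target_r2` solves for σ to hit a requested ceiling
exactly. The benchmark configuration (`benchmark_scene_config`) is a
100×100 km scene over 30 hours with 20 reference and 150 low-cost monitors
(~5,100 rows) at a 0.85 ceiling.

**What passing these experiments shows — and what it does not.** The scenes
have smooth Gaussian textures, additive noise, perfectly calibrated
sensors (bias optional, default zero), and a response the model family can
represent. Success demonstrates that the pipeline's plumbing is correct
(no leakage, no lost cells, exact preservation of retrievals), that the
wavelet features carry the information they should, and that the validation
machinery measures what it claims. It does not demonstrate skill on real
retrieval error structure, sensor drift, emission chemistry, or terrain
effects, all of which are absent by design.

## Numerical choices and degenerate inputs

* Filter construction is double precision; moment sums at high order
  (db10, m = 9) hit the cancellation floor of the arithmetic rather than
  any construction error.
* Decomposition rejects signals with missing values and levels beyond the
  maximum; constant fields decompose to zero details exactly.
* A constant training target is fitted but flagged; its OOB R² is reported
  as undefined rather than a number.
* Gap-fill hours with zero retrievals are skipped and logged; rows with a
  missing predictor are dropped and counted.
* Tree-ensemble predictions are bounded by the training-target range — both
  the filled AOD and the PM2.5 surfaces inherit this (no negative
  concentrations, no invented extremes).
* All randomness flows from explicit integer seeds: scene, sites,
  observations, masks, forests, fold assignment and oversampling each take
  one, and the pipeline log records them.

## Problem sizes used in the shipped experiments

The shipped tests exercise the default 100×100 scene for gap-fill recovery
(one hour, 500 trees), the full benchmark for CV recovery (10 folds × 500
trees, both schemes), and ten 80×80 replicate scenes (12 hours, 136
monitors, 200 trees, 5 folds) for the wavelet-vs-raw ablation; unit tests
run on 40–60-cell-wide scenes. These sizes were chosen so the whole suite
runs comfortably on a single CPU while leaving each experiment's conclusion
unchanged at larger sizes.

## Known limitations

* The 1-D row-major decomposition makes the smoothness of `l_5` anisotropic
  (much smoother along x than y); a 2-D transform would remove the
  anisotropy but would not match the level-15 maximum that fixes the 1-D
  convention.
* GeoTIFF I/O is not provided; gridded exchange is classic NetCDF with the
  grid geometry in global attributes. Coordinates are planar, with no CRS.
* The GWR calibration of low-cost sensors is out of scope; the generator
  emits already-calibrated low-cost records (an optional site-level bias is
  available for sensitivity studies).
* Hours without any satellite retrieval cannot be gap-filled and are
  excluded, so temporal coverage follows retrieval coverage.
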