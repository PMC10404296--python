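# Methods

This note documents the models, the synthetic test-bed, the numerical
choices and the limitations of `carbonflux`. It describes what the code
computes; every number quoted here is produced by the test suite or
`scripts/acceptance.py`, not asserted independently.

## Flux model

Net above-ground carbon flux Δz (Mg C ha⁻¹, signed; sequestration positive)
over an accounting period is predicted per 100 m pixel by a stacked
ensemble:

- **Base learners.** Bagged regression trees
  (`sklearn.RandomForestRegressor`), gradient-boosted trees
  (`xgboost.XGBRegressor`, hist method) and an RBF support-vector regressor
  with internal standardisation and a median-heuristic kernel width scaled
  by a tunable multiplier. Hyperparameters are grid-searched by 5-fold CV
  RMSE (weighted fits, unweighted scoring, first-in-grid tie-break). The
  default grids are small published-style grids (trees 250/500, candidate
  features √p / p/3; boosting depth 3/6/9, learning rate 0.05/0.1; SVR cost
  1/10, width ×{0.5, 1, 2}); `default_learner_specs(fast=True)` collapses
  them to one sensible combination for demos.
- **Stacking.** One random 5-fold partition per master seed serves three
  purposes, nested so the meta learner never sees in-fold base predictions:
  base learners trained on 4/5 folds produce out-of-fold (OOF) predictions;
  the meta learner is fitted on the 3-column OOF matrix; evaluation of fold
  f uses a meta learner refitted without fold f. Deployment base learners
  are refitted on all plots.
- **Case weights.** Plot weights w_i = (1/σ²_i)/mean(1/σ²) enter every base
  learner as observation weights. The meta learner is fitted
  **unweighted**: its inputs already reflect the weighting through the
  weighted base fits, and weighting the combiner again double-counts the
  preference — under the heteroscedastic variance model the weights span
  ~10³, which collapsed the effective stacking sample (≈190 of ~1000
  plots) and measurably degraded meta CV RMSE relative to the best base
  learner. With the unweighted meta, stacking is non-degrading (meta CV
  RMSE ≤ 1.05× best base, 3-seed median, verified in the suite).
- **Prediction intervals.** The meta learner is a quantile regression
  forest: each tree's leaf membership of a query point selects training
  responses, weighted by 1/(leaf size × number of trees) (Meinshausen's
  estimator), and the 5th/95th weighted quantiles form a 90% interval.
  Node size 5 is used: fully-grown leaves gave marginally better point
  RMSE but under-covered the 90% interval (≈0.84 empirical coverage versus
  ≈0.90 at node size 5 on the reference landscape).

## Evaluation and importance

RMSE, ME (observed − predicted) and R² are computed per fold and reported
mean ± SD across folds; R² uses the fold-local observation mean, and
metrics are unweighted (weights affect fitting only). Permutation
importance shuffles each covariate (a categorical covariate's indicator
block jointly) in the held-out fold of each base learner, one seeded
shuffle per covariate-fold (repetitions configurable), averages the RMSE
increase over folds, then averages over base learners weighted by the meta
learner's own permutation importance of each base-prediction column;
scores are rescaled to 0–100 with the maximum at 100. Category shares
group covariates by data source; the supercategory roll-up separates
global biomass-map products from other dynamic inputs and static terrain /
climate / management layers.

## Feature-space coverage

Only continuous covariates enter the dissimilarity index (Euclidean
distance on one-hot codes would dominate the metric). Each covariate is
standardised by the training mean/SD and multiplied by its normalised
importance; DI(pixel) is the distance to the nearest training plot divided
by the mean pairwise distance among plots. The under-sampling threshold is
Q3 + 1.5·IQR of the training plots' cross-validated DI (distance to the
nearest plot outside the plot's own fold). Fractions of flagged pixels are
reported over all valid vegetated pixels and per UNSEEA class (empty
classes report NaN, not 0).

## Uncertainty aggregation

- **Interval → SD.** Default ("corrected") conversion uses the Gaussian
  identity for a central 90% interval, SD = (q95 − q05)/(2 × 1.645). The
  multiplicative form SD = ((q95 − q05)/2) × 1.64 appears in some
  reporting; it inflates SD ≈2.7× and is preserved behind
  `mode="literal"` for comparability only.
- **Variogram.** Standardized residuals (z − ẑ)/SD at plot cells enter a
  Matheron semivariance estimator on equal-width distance bins (default 15
  bins to half the domain diagonal; zero-distance pairs excluded, empty
  bins omitted). An exponential (default) or spherical model is fitted by
  least squares weighted by pair counts, with the range bounded by the
  largest observed lag (longer ranges are not identifiable) ; a fitted
  effective range below the first lag is folded into the nugget, since
  sub-resolution structure is indistinguishable from nugget. Effective
  range is 3× the exponential range parameter. Non-convergence falls back
  to a pure-nugget model with a warning.
- **Class variance.** Pixel SDs are converted to per-pixel Mg C by the
  cell area, then Var_c = Σᵢ Σⱼ ρ(hᵢⱼ)·SDᵢ·SDⱼ with ρ the correlogram
  implied by the fitted variogram (ρ(0) = 1, truncated to 0 beyond the
  effective range). The truncation permits an exact windowed
  shift-and-multiply evaluation, O(pixels × offsets), verified against the
  literal O(n²) double loop to 1e-10 relative error. Independent mode
  (Var = Σ SD²) is the default for country-scale classes when fitted
  ranges are short relative to class extents. Closing-stock variance adds
  opening and flux variances (independent errors); results are reported in
  Tg C (1 Tg = 10⁶ Mg).

## Accounts

Land cover is reclassified to the six UNSEEA level-2 vegetated classes via
a configurable code→label table, nearest-neighbour block resampling for
coarser sources, and a plantation overlay that overrides natural-forest
labels. Closing = opening + signed net flux is recomputed when the table
is built, so the identity holds to machine precision per class and in the
totals row. Net emissions/sequestration are the sums of negative/positive
flux pixels; emissions are attributed by the 2010→2018 forest transition
(degradation: forest→forest; conversion: forest→non-forest), with
negative-flux pixels that were not forest in 2010 kept in an explicit
"unattributed" column so the partition stays exhaustive. Sequestration is
not attributed. The totals row adds class SDs in quadrature.

## Synthetic test-bed

The generator emulates the statistical structure the pipeline assumes, not
any real country's geography:

- Covariates: independent stationary Gaussian fields (white noise smoothed
  with a Gaussian kernel whose SD equals the correlation length, wrapped
  boundaries, re-standardised). Default 6 fields, 1000 m correlation
  length on 100 m cells.
- True flux: linear combination with geometrically decaying coefficients
  (8, 4.8, 2.88, …; signal SD ≈ 10 Mg C ha⁻¹) plus a correlated noise
  field of sample SD exactly `noise_sd` (default 5 — i.e. 2:1
  signal-to-noise, 500 m correlation length).
- Land cover: equal-share quantile partition of an independent latent
  field; 2018 flips a configurable fraction (default 0.1) of forest pixels
  to the first non-forest class; plantations are the top-latent 10% of
  2010 forest.
- Plots: uniform (random cells without replacement), systematic (square
  lattice) or clustered (uniform discs around random centres, emulating
  LiDAR footprint campaigns) designs; observed flux adds Gaussian error
  with SD = measurement_cv × max(|true flux|, 1) (default cv 0.2; the
  1 Mg C ha⁻¹ floor keeps inverse-variance weights defined), and the same
  quantity squared fills the variance column.
- Opening stocks: a positive stock surface (mean 60 Mg C ha⁻¹) with a 20%
  relative SD layer standing in for a biomass-map uncertainty product.

What passing tests on this test-bed do **not** show: robustness to sensor
saturation and retrieval bias in real biomass products, plot geolocation
error, land-cover misclassification, non-linear flux–covariate
relationships beyond what tree ensembles capture, or the behaviour of the
variogram under strong nonstationarity. Those belong to the real-data
deployment, not the package's verification.

## Problem sizes and determinism

The test suite runs landscapes up to 200×200 cells with 1000 plots — large
enough for stable CV metrics, interval-coverage estimates and variogram
fits while keeping the suite fast; the acceptance script uses the same
200×200 / 1000-plot reference condition. All randomness flows from one
master seed through named stage seeds (`numpy.random.SeedSequence`);
identical configuration and seed reproduce byte-identical account CSVs.

## Known limitations

- Stage CLI commands recompute upstream stages in memory from the config
  rather than reloading artifacts; cheap by design at package scale, but a
  real national deployment would persist fitted models.
- The variogram is pooled (one model per map), not stratified by class or
  flux magnitude; heteroscedasticity is handled only through the per-pixel
  SD layer used for standardisation.
- Spatially blocked cross-validation for clustered designs is not
  implemented; random folds can flatter clustered samples.
- Only above-ground carbon is accounted; no below-ground or soil pools,
  and no monetary valuation.
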