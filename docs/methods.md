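# Methods

## The problem

Large-scale ecological mapping models (e.g. forest aboveground biomass,
AGB, in Mg ha⁻¹ at 1-km resolution) are trained on point samples and
validated by withholding a random subset — random K-fold cross-validation.
When both the response and the covariates are spatially autocorrelated and
the samples are clustered, a randomly chosen test sample almost always has
training neighbours well inside the autocorrelation range.  The test set
is then not independent of the training set, and the CV statistics
measure the model's ability to *interpolate near its training data*, not
to predict new locations.  `spatialcv` packages the machinery needed to
demonstrate, quantify and avoid this failure mode: a synthetic
geostatistical scenario generator, variogram diagnostics, spatially
blocked K-fold CV, buffered leave-one-out CV (B-LOO), and null /
coordinates-only baseline models.

## Models and procedures

### Gaussian random field simulation (`synthetic`)

Fields are stationary Gaussian processes on planar km coordinates, drawn
by exact dense covariance factorization (Cholesky, with an escalating
relative diagonal jitter of 1e-10…1e-6; failure raises).  Exactness and
simplicity at desk scale (n ≤ `MAX_GRF_N` = 6000 per field) were
preferred over approximate spectral or turning-band methods.  The
exponential model is parameterized by its *practical range*:
γ(h) = nugget + sill·(1 − e^(−3h/a)), so `range_km = a` is the lag where
the variogram reaches ~95 % of the sill — matching how "range of
autocorrelation" is read off empirical variograms.  The spherical model
uses the standard closed form.  Coordinates are abstract planar km; at
the few-hundred-km scales involved, geodesy changes nothing about the
statistical argument.

Clustered layouts emulate inventory-style sampling: cluster centres
uniform over the extent, members isotropic Gaussian offsets
(`cluster_radius_km`), redrawn until inside the extent, with fixed
membership counts for determinism.  The zero-effect ("spurious skill")
scenario defaults — 40 clusters × 50 points on a 1000×1000 km extent,
cluster radius 20 km, five unit-sill predictor fields with 300-km range,
an independent response field with 120-km range, and iid noise with
variance 0.10 × the spatial sill — mirror the structure of a real
central-African AGB data set: dense patches tens of km across inside
surveyed concessions, large unsampled swaths, predictor ranges a few
times the response range.  The response nugget is taken as zero there
because the iid noise term already plays that role; for AGB-like fields
where no small-scale variance estimate exists, `DEFAULT_NUGGET_FRACTION`
(0.3 of the sill) is exposed in the config as an explicit free choice.

### Variogram diagnostics (`variogram`)

The Matheron estimator on half-open bins (default width 10 km; default
maximum lag half the maximum pairwise distance — conventional practice)
gives γ(h) per bin with pair counts; empty bins carry NaN, never 0.
Model fitting is weighted least squares with pair-count weights and
non-negativity bounds on sill and nugget.  The reported *practical range*
is where the fitted curve reaches 95 % of sill + nugget (solved in closed
form for the exponential model, by bracketing for the spherical).  A
fitted partial sill below 1e-3 of the total sill is reported as "no
spatial structure" rather than a number.  Range estimation here is a
diagnostic: empirical ranges read off variograms are approximate by
nature, and recovery within ~25 % of a generating range (verified over
10 seeds) is the accuracy one should expect at these sample sizes.

### Spatial folds (`folds`)

Spatial K-fold blocks are the clusters obtained by cutting a
complete-linkage dendrogram of the pairwise coordinate distances at
height H (default 150 km).  Complete linkage merges clusters by their
maximum inter-point distance, so every fold's diameter is ≤ H by
construction (asserted against brute force in tests).  K emerges from
the data.  H should sit slightly beyond the response's autocorrelation
range; 150 km vs a 120-km range reproduces the canonical setup.  A
degenerate K = 1 outcome is returned flagged, and rejected by the CV
driver.

### Buffered leave-one-out CV (`crossval`)

For each test sample and radius r, the training set is every sample at
distance > r (the closed r-ball around the test point is excluded;
"within distance r" is read inclusively — the boundary choice is
documented because it is not standard anywhere).  Radii default to
0–150 km by 10 (16 values).  Per repetition, `n_test` samples are drawn
without replacement; repetition seeds are `seed + rep`.  R² (squared
Pearson correlation) and RMSPE are computed per (repetition, radius) over
the pooled `n_test` predictions and summarized as mean ± SD over
repetitions.

The extrapolation safeguard removes, per candidate test sample, the
training data at the *largest* radius and rejects the candidate if any
covariate falls outside the training min–max (or a categorical level is
unseen).  The check runs at the largest radius only; the draw budget is
50 × `n_test` candidates, after which the smaller accepted set is used
and the discard count reported.  When several models are audited
together, the safeguard is driven by the covariate model's predictor list
for all of them (`domain_columns`), so every model sees identical test
draws and the curves are directly comparable.

Note one pathology worth knowing: the null model's B-LOO R² at small
radii is ≈ 1, because leave-one-out training means are perfectly
*anti*-correlated with the held-out values and R² squares the
correlation.  Null-model skill is therefore read from RMSPE only.

### Models and metrics (`models`, `metrics`)

`RF_RSE` (covariates), `RF_XY` (coordinates only) and `NULL` (training
mean; sklearn's `DummyRegressor`) are described by a serializable
`ModelSpec`.  Forest defaults follow regression conventions: 500 trees,
variables-per-split ⌈p/3⌉, minimum leaf 5.  R² is the squared Pearson
correlation (not the coefficient of determination) and is NaN — never
silently 0 — for constant vectors; RMSPE is in response units; relative
RMSPE is 100·RMSPE / mean(observed).

The reverse geolocation diagnostic predicts sample coordinates from
covariates with a single multi-output random forest (both coordinates as
joint targets, averaged-variance split criterion), which is closer to a
true multivariate forest than two independent per-axis fits; per-axis
RMSEs are reported alongside the root-mean-squared Euclidean distance.
The no-skill reference is the RMS distance of held-out points from the
training centroid.

### Covariate engineering (`covariates`)

Water availability WA = ΣP/ΣPET; monthly deficit P − PET; dry months are
deficit < 0.  Dry-season runs are circular across the Dec→Jan boundary
(equatorial bimodal climates straddle the calendar year); ties between
equal-length runs break toward greater severity; severities are positive
magnitudes.  MCWD iterates the clamped running balance
WDₙ = min(0, WDₙ₋₁ + Pₙ − PETₙ) circularly to its fixed point (two
cycles suffice whenever some month resets the balance); a climatology in
perpetual annual deficit has no fixed point, and the one-year
accumulation from a saturated start is reported instead, keeping
|MCWD| ≤ ΣPET.  MCWD uses the supplied monthly PET, not a fixed 100-mm
convention.  Seasonality uses the population SD (the 12 months are the
complete climatology), CV = 100·SD/mean, and temperature seasonality is
reported as SD·100 per the bioclim convention.  EVI2 and NDII use the
standard closed forms (EVI2 = 2.5·(NIR−RED)/(NIR+2.4·RED+1);
NDII = (NIR−SWIR)/(NIR+SWIR), SWIR1 by default).  Published AGB covariate
tables list NDII maxima slightly above 1, which the standard normalized
form cannot produce; the standard form is implemented and the band choice
left configurable.

### Pixel filters (`filters`)

The four QC stages run in canonical order — vegetation cover ≥ 89 %
kept, ≥ 3 field plots kept, forest loss > 5 % or any fire removed,
spectral values > 10 SD from the band mean removed — with boundary
semantics read literally from the usual prose formulations.  Outlier
means/SDs come from the stage input in a single pass (no iteration).
Worth noting: a lone outlier among n samples has |z| ≤ (n−1)/√n, so a
10-SD screen can only ever fire for n ≳ several hundred; it is a
big-data filter by construction.  Per-stage removal percentages are
relative to the stage's input set, matching how mapping papers report
their exclusion chains.

## The audit experiments (`audit`)

`spurious_skill_audit` runs the zero-effect scenario end to end.
Desk-scale sizes: n = 2000, a 100-tree half-subsampled
(`max_samples = 0.5`) audit forest, B-LOO with 50 test points × 3
repetitions over radii 0–150 by 30 km, aggregated over 3 master seeds.
The ensemble reduction (vs the 500-tree default) and the coarsened radius
schedule trade precision for wall time; sensitivity checks across
50–100 trees with and without subsampling moved random-CV R² by < 0.02
and changed no qualitative contrast.  `genuine_signal_audit` is the
control: β = 1 on every predictor, noise sized so covariates drive 80 %
of response variance, and spatially blocked CV must still report the real
skill (measured: R² ≈ 0.70–0.81 across seeds).

## What the generator does and does not emulate

It reproduces the *statistical skeleton* of a mapping data set —
autocorrelated response and predictors with realistic ranges, clustered
sampling, a controllable true effect — which is exactly what the leakage
mechanism depends on.  It does not emulate: non-Gaussian or anisotropic
fields, saturating sensor response, measurement error structure in
field-derived AGB, raster-native covariates, or the real data's 36-deep
covariate stack.  Consequences worth keeping in mind when transferring
conclusions to real data:

* With only five predictor fields, covariate combinations alias —
  independent far-away locations often look similar in covariate space —
  so the covariate forest interpolates *worse* than the coordinate forest
  at radius 0, and reverse geolocation from 5 fields is weak (~290 km
  RMSE vs a ~410 km no-skill baseline; measured).  Real stacks are
  deeper: with 25 fields the geolocation RMSE roughly halves, and a real
  36-variable stack over ~28k densely packed pixels localizes to tens of
  km.  The *direction* of every contrast is unaffected; the closeness of
  the coordinate-only and covariate curves at small radii is not fully
  reproduced at 5 predictors.
* Passing audits here show the machinery is sound, not that any
  particular real map is wrong; on real data the audit must be rerun on
  the real coordinates and covariates.

## Numerical choices and degenerate inputs

* GRF jitter escalation 1e-10/1e-8/1e-6 relative to total sill, then an
  explicit error.
* Variogram fits: `scipy.optimize.least_squares` with bounds
  (range ∈ (0, 10·max lag], sill ≥ 0, nugget ≥ 0), start at
  (max-lag/2, mean γ, 0).
* Flat-variogram flag at partial sill < 1e-3 of total; practical range 0
  when the nugget alone exceeds 95 % of the total sill.
* Complete-linkage ties are resolved by scipy's deterministic merge
  order; fold labels are renumbered by first appearance.
* All-identical coordinates → K = 1 spatial fold, flagged and unusable.
* Constant prediction or observation vectors → R² NaN with a defined
  flag.
* Empty training set at any B-LOO radius → error naming the radius.
* CSVs are written at 6 significant digits to make reruns byte-stable.

## Seeding

Every stochastic stage takes a seed.  `run_experiment` fans a master
seed into per-stage seeds as `master·S + offset` (S = number of stages),
so toggling one stage never perturbs another's draws; B-LOO repetition
seeds are `seed + rep`.  Identical configs reproduce byte-identical
outputs (tested).

## Known limitations

* Dense GRF factorization caps a single field at 6000 points.
* The B-LOO driver refits one forest per (test point, radius,
  repetition); cost scales as their product.  The radius schedule and
  `n_test` are the practical levers.
* Directional variograms, kriging prediction, covariate-space blocking
  and nested hyperparameter tuning inside folds are out of scope.
* GeoTIFF ingestion is not provided; inputs are CSV point tables (id,
  x_km, y_km, response, covariates, QC columns).
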