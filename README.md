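# spatialcv

**Spatial cross-validation audits for geospatial prediction models.**

Mapping models — forest biomass, soil properties, species abundance — are
usually trained on point samples and validated with random K-fold
cross-validation.  In a geospatial setting this is subtly broken: when
the response and its covariates are spatially autocorrelated and the
samples are clustered, random test samples sit inside the autocorrelation
range of training samples, so the "independent" validation actually
measures the model's ability to interpolate next to its own training
data.  The reported R² can be high even when the covariates carry **no
information at all** about the response.

`spatialcv` is a toolkit for exposing and avoiding this failure mode,
aimed at ecologists, biostatisticians and remote-sensing modellers:

* **Synthetic geostatistical scenarios** — Gaussian random fields with
  exponential/spherical covariance (practical-range parameterization
  γ(h) = c₀ + c·(1 − e^(−3h/a))), clustered or uniform sampling layouts,
  and a controllable true effect β (including β = 0, the pure-leakage
  regime).
* **Variogram diagnostics** — Matheron estimator
  γ̂(h) = Σ(zᵢ−zⱼ)²/2N(h) on binned lags, weighted model fits, practical
  autocorrelation range.
* **Three CV strategies** — random K-fold; spatial K-fold via
  complete-linkage clustering of the coordinate distance matrix cut at
  height H (every fold diameter ≤ H); and buffered leave-one-out
  (B-LOO), which excludes all training samples within radius r of the
  test sample and sweeps r from 0 past the autocorrelation range.
  B-LOO includes an extrapolation safeguard so that skill decay is
  attributable to lost spatial dependence, not covariate extrapolation.
* **Baselines that make the audit interpretable** — a null model
  (training mean), a coordinates-only random forest (RF_XY, pure spatial
  interpolation), and the covariate random forest under audit (RF_RSE);
  metrics are squared-Pearson R², RMSPE, and relative RMSPE (% of mean
  observed).
* **Pixel QC filters and covariate engineering** for biomass-mapping
  tables: vegetation-cover / plot-count / disturbance / spectral-outlier
  exclusion chain with an audit report, plus derived climate layers (water
  availability, monthly water deficit, dry-season length and severity,
  maximal climatological water deficit, seasonality) and spectral indices
  (EVI2, NDII).

See `docs/methods.md` for the models, assumptions, parameter defaults
and limitations.

## Worked example

A zero-effect landscape: five predictor fields (300-km range) that have
*no* relationship with the response (120-km range, plus iid noise),
sampled in 40 dense clusters of 25 points on a 1000×1000 km extent.

```python
import numpy as np
from spatialcv import (
    ModelSpec, build_scenario, empirical_variogram, estimate_range,
    random_kfold_split, run_kfold_cv, spatial_kfold_split,
    spurious_skill_scenario,
)

scenario = spurious_skill_scenario(seed=7, n_samples=1000)
samples = build_scenario(scenario)

vg = empirical_variogram(samples.response, samples.coords, bin_width=20.0)
rng_est = estimate_range(vg, "exponential")
print(f"estimated autocorrelation range: {rng_est.range_km:.0f} km (true: 120 km)")

model = ModelSpec("RF_RSE", n_trees=100, seed=7)
random_folds = random_kfold_split(len(samples), K=10, seed=7)
spatial_folds = spatial_kfold_split(samples.coords, clustering_height_km=150.0)

random_cv = run_kfold_cv(model, samples, random_folds)
spatial_cv = run_kfold_cv(model, samples, spatial_folds)
print(f"random 10-fold CV:  R2 = {random_cv.metrics.r2:.2f}, "
      f"RMSPE = {random_cv.metrics.rmspe:.2f}")
print(f"spatial {spatial_folds.K}-fold CV: R2 = {spatial_cv.metrics.r2:.2f}, "
      f"RMSPE = {spatial_cv.metrics.rmspe:.2f}")
print(f"response SD (no-skill RMSPE): {np.std(samples.response):.2f}")
```

Output:

```
estimated autocorrelation range: 114 km (true: 120 km)
random 10-fold CV:  R2 = 0.22, RMSPE = 0.83
spatial 29-fold CV: R2 = 0.01, RMSPE = 1.02
response SD (no-skill RMSPE): 0.94
```

The covariates are pure noise with respect to the response, yet random
10-fold CV credits the model with R² = 0.22 and an RMSPE well below the
no-skill level — spatial leakage, nothing else.  Spatially blocked CV
(29 complete-linkage clusters, diameter ≤ 150 km) tells the truth:
R² ≈ 0, RMSPE at the null-model level.  The B-LOO sweep
(`spatialcv.bloo_cv` or the `spatialcv bloo` CLI) resolves the same
story as a continuous function of the training–test distance.

## Command line

Each pipeline stage is also a subcommand:

```bash
spatialcv simulate --seed 7 --out samples.csv
spatialcv variogram --input samples.csv --fit-model exponential --out vg.csv
spatialcv cv --input samples.csv --model RF_RSE --strategy spatial --out cv.csv
spatialcv bloo --input samples.csv --model RF_RSE --n-test 50 --n-reps 3 --out bloo.csv
spatialcv geopredict --input samples.csv
spatialcv run --seed 7 --out audit_out/        # full audit, all artifacts
```

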